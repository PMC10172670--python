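"""End-to-end study replicas on synthetic cohorts.

``run_cross_sectional`` reproduces the cross-sectional arm — three
groups x two emotional cues: simulate epochs, preprocess to ERPs, fit a
shared microstate template on the grand average, backfit every subject x
condition ERP, tabulate the four parameters, and run the 2 x 3 mixed
ANOVA with age/sex covariates per class x parameter plus a demographics
table.  ``run_longitudinal`` reproduces the treatment arm — two
treatment arms x two times x two cues on the clinical group: 2 x 2
mixed ANOVA on scales, 2 x 2 x 2 on microstate parameters, simple
effects for the significant interactions and pre/post difference
correlations.

A single master seed fans out to fixed per-stage child seeds, so any
stage (and any deleted output) is independently reproducible; every
written table carries the config hash in a header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ERP
from .microstate import (MapSet, group_parameter_table, modified_kmeans,
                         select_n_maps)
from .preprocess import preprocess_cell
from .stats import (chi_square_independence, mixed_anova,
                    oneway_anova_from_summary, prepost_difference_correlation,
                    simple_effects)
from .synth import (CohortDesign, longitudinal_design, scaled_down_design,
                    simulate_cohort, simulate_scales)

__all__ = ["RunConfig", "run_cross_sectional", "run_longitudinal", "Bundle"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the master seed
_STAGE_OFFSETS = {"cohort": 1, "scales": 2, "cluster": 3}

# rTMS protocol constants, recorded as run metadata only (never executed):
# 10 Hz over left DLPFC (F3), 100% resting motor threshold, 4500 pulses
# per session in 90 blocks, 5 s trains with 15 s intervals, 5 days/week
# for 4 weeks.
RTMS_PROTOCOL = {
    "target": "left DLPFC (F3)", "frequency_hz": 10,
    "intensity": "100% resting motor threshold",
    "pulses_per_session": 4500, "blocks": 90,
    "train_s": 5, "inter_train_interval_s": 15,
    "schedule": "once daily, 5 days/week, 4 weeks",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a study replica needs, JSON round-trippable."""

    design: CohortDesign = field(default_factory=scaled_down_design)
    seed: int = 0
    out_dir: str | None = None
    # preprocessing
    target_rate: float = 500.0
    # low edge 0: on an epoched drift-free synthetic signal a 0.1 Hz
    # high-pass only removes the per-channel epoch mean, distorting every
    # topography; use (0.1, 30) when filtering continuous real recordings
    band: tuple = (0.0, 30.0)
    apply_bandpass: bool = True
    window_ms: tuple = (-200.0, 1000.0)
    # None: synthetic signals are drift-free and time-locked into the
    # pre-stimulus window, where baseline subtraction would distort
    # topographies; enable (-200, 0) for real recordings
    baseline_ms: tuple | None = None
    ptp_limit: float = 1000.0   # synthetic amplitudes are unit-scale
    # microstate
    k_range: tuple | None = None    # (lo, hi) switches on CV model selection
    gfp_peaks_only: bool = False    # cluster only local-GFP-maximum samples
    iterations: int = 1000
    restarts: int = 20
    # minimum dwell time when backfitting: boundary samples sit in the
    # envelope's low-GFP trough and pick up noise labels; 30 ms is the
    # conventional toolbox floor for microstate segments
    smoothing_ms: float = 30.0
    occurrence_denominator: str = "epoch"
    # stats
    covariates: tuple = ("age", "sex")
    alpha: float = 0.05
    parameters: tuple = ("duration", "coverage", "occurrence")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 10_007 + _STAGE_OFFSETS[stage]) % (2 ** 31)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # execution detail, not part of the experiment
        design = d.pop("design")
        design.pop("layout", None)
        design["cell_targets"] = {
            "|".join(map(str, k)): [list(map(float, v[0])), list(map(float, v[1]))]
            for k, v in design["cell_targets"].items()}
        d["design"] = design
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class Bundle:
    """Outputs of one replica run."""

    parameter_table: pd.DataFrame
    effect_table: pd.DataFrame
    demographics: pd.DataFrame
    scales: pd.DataFrame
    mapset: MapSet
    manifest: dict
    simple_effects: dict = field(default_factory=dict)
    correlations: pd.DataFrame | None = None
    anovas: dict = field(default_factory=dict)


def _fit_template(erps: list[ERP], config: RunConfig):
    """Shared template from the stacked samples of every subject x
    condition ERP, so class indices are comparable across all cells.

    Samples are concatenated rather than averaged pointwise: a pointwise
    grand average cancels topographic structure wherever subjects'
    microstate sequences are not strictly time-locked."""
    grand = np.concatenate([e.data for e in erps], axis=1)
    grand = grand - grand.mean(axis=0, keepdims=True)
    if config.gfp_peaks_only:
        from .microstate import gfp_peaks
        grand = grand[:, gfp_peaks(grand)]
    seed = config.stage_seed("cluster")
    if config.k_range is not None:
        k_star, table = select_n_maps(grand, config.k_range, config.iterations,
                                      config.restarts, seed)
        logger.info("CV selected K=%d", k_star)
    else:
        k_star, table = config.design.n_classes, None
    mapset, _, gev = modified_kmeans(grand, k_star, config.iterations,
                                     config.restarts, seed)
    return mapset, gev, table


def _preprocess_cohort(cohort, config: RunConfig):
    """Average every subject x condition (x time) cell into an ERP."""
    erps, meta = [], []
    for subject_id, group, condition, time, epochs in cohort.iter_cells():
        erp = preprocess_cell(
            epochs, target_rate=config.target_rate, band=config.band,
            window_ms=config.window_ms, baseline_ms=config.baseline_ms,
            ptp_limit=config.ptp_limit, apply_bandpass=config.apply_bandpass)
        erp = dataclasses.replace(erp, subject_id=subject_id, condition=condition)
        erps.append(erp)
        m = {"group": group}
        if time is not None:
            m["time"] = time
        meta.append(m)
    return erps, meta


def _demographics_table(scales: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Group mean +/- SD per scale with one-way F (chi-square for sex)."""
    rows = []
    groups = sorted(scales["group"].unique())
    for col in ("age", "HAMD", "PHQ9"):
        summaries = [(scales.loc[scales.group == g, col].mean(),
                      scales.loc[scales.group == g, col].std(ddof=1),
                      int((scales.group == g).sum())) for g in groups]
        res = oneway_anova_from_summary(summaries)
        row = {"variable": col, "statistic": res["F"].iloc[0], "p": res["p"].iloc[0]}
        for g, (m, s, n) in zip(groups, summaries):
            row[g] = f"{m:.3f} +/- {s:.3f} (n={n})"
        rows.append(row)
    counts = [[int(((scales.group == g) & (scales.sex == s)).sum())
               for s in ("male", "female")] for g in groups]
    chi2, dof, p = chi_square_independence(counts)
    row = {"variable": "sex", "statistic": chi2, "p": p}
    for g, (male, female) in zip(groups, counts):
        row[g] = f"{male}/{female}"
    rows.append(row)
    return pd.DataFrame(rows)


def _effect_summary(anova: pd.DataFrame, effects: dict) -> dict:
    out = {}
    for label, name in effects.items():
        row = anova.loc[anova["effect"] == name]
        if row.empty:
            continue
        out[f"{label}_F"] = float(row["F"].iloc[0])
        out[f"{label}_p"] = float(row["p"].iloc[0])
        out[f"{label}_eta_p2"] = float(row["eta_p2"].iloc[0])
    return out


def _write_bundle(bundle: Bundle, config: RunConfig, extra: dict | None = None):
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.config_hash}\n"
    tables = {
        "parameters.tsv": bundle.parameter_table,
        "effects.tsv": bundle.effect_table,
        "demographics.tsv": bundle.demographics,
        "scales.tsv": bundle.scales,
    }
    if bundle.correlations is not None:
        tables["correlations.tsv"] = bundle.correlations
    for name, frame in (extra or {}).items():
        tables[name] = frame
    for name, frame in tables.items():
        with open(out / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                         lineterminator="\n")
    maps = pd.DataFrame(bundle.mapset.maps.T)
    with open(out / "template_maps.tsv", "w") as fh:
        fh.write(header)
        maps.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                    lineterminator="\n")
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, sort_keys=True, indent=2, default=str))


def _manifest(config: RunConfig, stages: dict) -> dict:
    logger.info("stage timings (s): %s", stages)
    return {
        "taskstates_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_OFFSETS},
        "rtms_protocol": RTMS_PROTOCOL,
    }


def _run_stage(name, fn, timings):
    t0 = _time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    timings[name] = round(_time.perf_counter() - t0, 3)
    return result


def run_cross_sectional(config: RunConfig | None = None) -> Bundle:
    """Simulate, preprocess, segment, backfit and analyze the 2-cue x
    3-group design; returns the bundle and writes it under ``out_dir``."""
    config = config or RunConfig()
    timings: dict = {}
    cohort = _run_stage("simulate", lambda: simulate_cohort(
        config.design, config.stage_seed("cohort")), timings)
    erps, meta = _run_stage("preprocess", lambda: _preprocess_cohort(cohort, config),
                            timings)
    mapset, gev, ktable = _run_stage("template", lambda: _fit_template(erps, config),
                                     timings)
    params = _run_stage("parameters", lambda: group_parameter_table(
        zip(erps, meta), mapset, config.smoothing_ms,
        config.occurrence_denominator), timings)
    scales = _run_stage("scales", lambda: simulate_scales(
        config.design, seed=config.stage_seed("scales")), timings)
    demo = _demographics_table(scales, config)

    cov_cols = scales.set_index("subject")[list(config.covariates)]
    merged = params.merge(cov_cols, left_on="subject", right_index=True)
    rows, anovas, simples = [], {}, {}
    for param in config.parameters:
        for cls in sorted(merged["class"].unique()):
            sub = merged[merged["class"] == cls]
            row = {"parameter": param, "class": cls}
            try:
                res = mixed_anova(sub, param, "subject", within="condition",
                                  between="group",
                                  covariates=list(config.covariates))
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s class %s: %s", param, cls, exc)
                rows.append(row)
                continue
            anovas[(param, cls)] = res
            row.update(_effect_summary(res, {
                "cue": "condition", "group": "group",
                "cue_x_group": "condition:group"}))
            rows.append(row)
            if row.get("cue_x_group_p", 1.0) < config.alpha:
                simples[(param, cls)] = simple_effects(
                    sub, param, "subject", within="condition", between="group",
                    slice_by="condition", covariates=list(config.covariates))
    effect_table = pd.DataFrame(rows)
    manifest = _manifest(config, timings)
    manifest["template_gev"] = gev
    bundle = Bundle(params, effect_table, demo, scales, mapset, manifest,
                    simple_effects=simples, anovas=anovas)
    extra = {"model_selection.tsv": ktable} if ktable is not None else None
    _write_bundle(bundle, config, extra)
    return bundle


def run_longitudinal(config: RunConfig | None = None) -> Bundle:
    """Simulate and analyze the treatment design: 2 arms x 2 times x 2 cues
    on microstate parameters plus 2 arms x 2 times on clinical scales."""
    if config is None:
        config = RunConfig(design=longitudinal_design(
            conditions={"neutral": 30, "negative": 30}))
    if config.design.times is None:
        raise ValueError("longitudinal run needs a design with times")
    timings: dict = {}
    cohort = _run_stage("simulate", lambda: simulate_cohort(
        config.design, config.stage_seed("cohort")), timings)
    erps, meta = _run_stage("preprocess", lambda: _preprocess_cohort(cohort, config),
                            timings)
    mapset, gev, ktable = _run_stage("template", lambda: _fit_template(erps, config),
                                     timings)
    params = _run_stage("parameters", lambda: group_parameter_table(
        zip(erps, meta), mapset, config.smoothing_ms,
        config.occurrence_denominator), timings)
    params = params.rename(columns={"group": "arm"})
    scales = _run_stage("scales", lambda: simulate_scales(
        config.design, seed=config.stage_seed("scales")), timings)

    rows, anovas, simples = [], {}, {}
    # 2 x 2 on the clinical scales
    for scale in ("HAMD", "PHQ9", "NSSI"):
        res = mixed_anova(scales, scale, "subject", within="time", between="arm")
        anovas[("scale", scale)] = res
        row = {"parameter": scale, "class": ""}
        row.update(_effect_summary(res, {
            "time": "time", "group": "arm", "time_x_group": "time:arm"}))
        rows.append(row)
        if row.get("time_x_group_p", 1.0) < config.alpha:
            simples[("scale", scale)] = simple_effects(
                scales, scale, "subject", within="time", between="arm",
                slice_by="time")
    scale_effects = pd.DataFrame(rows)

    # 2 x 2 x 2 on the microstate parameters
    rows = []
    for param in config.parameters:
        for cls in sorted(params["class"].unique()):
            sub = params[params["class"] == cls]
            row = {"parameter": param, "class": cls}
            try:
                res = mixed_anova(sub, param, "subject",
                                  within=["condition", "time"], between="arm")
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s class %s: %s", param, cls, exc)
                rows.append(row)
                continue
            anovas[(param, cls)] = res
            row.update(_effect_summary(res, {
                "cue": "condition", "time": "time", "group": "arm",
                "cue_x_time": "condition:time", "cue_x_group": "condition:arm",
                "time_x_group": "time:arm",
                "cue_x_time_x_group": "condition:time:arm"}))
            rows.append(row)
    effect_table = pd.DataFrame(rows)

    correlations = prepost_difference_correlation(scales, params)
    manifest = _manifest(config, timings)
    manifest["template_gev"] = gev
    bundle = Bundle(params, effect_table, scale_effects, scales, mapset, manifest,
                    simple_effects=simples, correlations=correlations,
                    anovas=anovas)
    extra = {"scale_effects.tsv": scale_effects}
    if ktable is not None:
        extra["model_selection.tsv"] = ktable
    _write_bundle(bundle, config, extra)
    return bundle
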