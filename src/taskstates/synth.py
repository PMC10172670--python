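"""Synthetic microstate-structured ERP cohorts with known ground truth.

The generator emulates a task-EEG study of adolescent depression with
nonsuicidal self-injury (NSSI): three groups (healthy controls n=20,
MDD n=52, MDD+NSSI n=66), two emotional cue conditions (150 neutral /
50 negative trials), 64-channel epochs spanning -200..1000 ms at 500 Hz,
and an optional longitudinal arm (medication n=31 vs medication+rTMS
n=21, before/after treatment).  Each subject x condition cell gets one
planted microstate label sequence; every trial in the cell carries the
same underlying signal (class topography times a half-sine envelope)
plus fresh white noise at a controlled signal-to-noise ratio, so trial
averaging recovers the planted structure.

Clinical-scale tables (HAMD, PHQ-9, NSSI score, age, sex) are drawn from
truncated normal distributions at per-cell means/SDs emulating the
study's demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import EpochArray, time_axis
from .layout import SensorLayout, standard_layout_64
from .microstate import LabelSequence, MapSet

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "Cohort",
    "make_prototype_maps",
    "simulate_epoch",
    "simulate_cohort",
    "simulate_scales",
    "simulate_parameter_table",
    "default_scale_cells",
    "longitudinal_scale_cells",
    "cross_sectional_design",
    "longitudinal_design",
    "paper_scale_design",
    "SCALE_RANGES",
]

N_CLASSES_DEFAULT = 6

# ---------------------------------------------------------------------------
# planted per-cell targets: per-class mean duration (ms) and coverage
# (fractions sum to 1).  MS 3, MS 4 and MS 6 follow the study's reported
# group x cue magnitudes; the unreported classes (1, 2, 5) share the
# remaining coverage evenly at ~100 ms durations.
# ---------------------------------------------------------------------------

def _targets(dur346, cov346):
    d3, d4, d6 = dur346
    c3, c4, c6 = cov346
    rest = (1.0 - c3 - c4 - c6) / 3.0
    duration = np.array([100.0, 110.0, d3, d4, 95.0, d6])
    coverage = np.array([rest, rest, c3, c4, rest, c6])
    return duration, coverage


_CROSS_TARGETS = {
    ("HC", "neutral"): _targets((154.6, 82.0, 102.4), (0.346, 0.082, 0.145)),
    ("HC", "negative"): _targets((152.2, 72.0, 136.6), (0.307, 0.081, 0.202)),
    ("MDD", "neutral"): _targets((191.1, 86.0, 96.5), (0.372, 0.091, 0.144)),
    ("MDD", "negative"): _targets((212.9, 83.0, 95.6), (0.426, 0.064, 0.122)),
    ("MDD+NSSI", "neutral"): _targets((205.4, 88.0, 75.3), (0.413, 0.107, 0.103)),
    ("MDD+NSSI", "negative"): _targets((224.5, 84.0, 85.7), (0.448, 0.098, 0.091)),
}

# longitudinal: MDD+NSSI split into treatment arms; "after" cells move the
# MS 3 / MS 6 targets toward the healthy profile, more so in the combined arm
_LONG_TARGETS = {
    ("medication", "neutral", "before"): _CROSS_TARGETS[("MDD+NSSI", "neutral")],
    ("medication", "negative", "before"): _CROSS_TARGETS[("MDD+NSSI", "negative")],
    ("medication+rTMS", "neutral", "before"): _CROSS_TARGETS[("MDD+NSSI", "neutral")],
    ("medication+rTMS", "negative", "before"): _CROSS_TARGETS[("MDD+NSSI", "negative")],
    ("medication", "neutral", "after"): _targets((160.0, 86.0, 110.0), (0.330, 0.100, 0.180)),
    ("medication", "negative", "after"): _targets((150.1, 84.0, 134.7), (0.321, 0.100, 0.207)),
    ("medication+rTMS", "neutral", "after"): _targets((140.0, 70.0, 120.0), (0.300, 0.060, 0.220)),
    ("medication+rTMS", "negative", "after"): _targets((123.6, 52.0, 126.9), (0.233, 0.041, 0.270)),
}


@dataclass(frozen=True)
class CohortDesign:
    """Sizes, conditions and planted targets of a simulated cohort."""

    groups: dict = field(default_factory=lambda: {"HC": 20, "MDD": 52, "MDD+NSSI": 66})
    conditions: dict = field(default_factory=lambda: {"neutral": 150, "negative": 50})
    times: tuple | None = None              # e.g. ("before", "after")
    rate: float = 500.0
    epoch_window: tuple = (-200.0, 1000.0)
    n_classes: int = N_CLASSES_DEFAULT
    snr: float = 5.0
    duration_subject_sd: float = 0.15       # lognormal sigma of the per-subject
                                            # duration scale, shared across cells
    coverage_concentration: float = 100.0   # Dirichlet concentration of the
                                            # per-cell coverage draw around the
                                            # target (~0.05 SD per class; 0 = off)
    latency_jitter_ms: float = 0.0          # per-trial circular shift SD
    cell_targets: dict = field(default_factory=lambda: dict(_CROSS_TARGETS))
    layout: SensorLayout | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("all group sizes must be >= 1")
        if any(n < 1 for n in self.conditions.values()):
            raise ValueError("all trial counts must be >= 1")
        if not self.epoch_window[0] < 0 < self.epoch_window[1]:
            raise ValueError("epoch window must straddle stimulus onset")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())

    def targets(self, group: str, condition: str, time: str | None = None):
        key = (group, condition) if time is None else (group, condition, time)
        duration, coverage = self.cell_targets[key]
        return np.asarray(duration, float), np.asarray(coverage, float)

    def get_layout(self) -> SensorLayout:
        return self.layout if self.layout is not None else standard_layout_64()


def cross_sectional_design(**overrides) -> CohortDesign:
    """The cross-sectional study design: 3 groups x 2 cue conditions."""
    return CohortDesign(**overrides)


def longitudinal_design(**overrides) -> CohortDesign:
    """The treatment design: 2 arms x 2 times x 2 cues on the NSSI group."""
    kw = dict(groups={"medication": 31, "medication+rTMS": 21},
              times=("before", "after"), cell_targets=dict(_LONG_TARGETS))
    kw.update(overrides)
    return CohortDesign(**kw)


def paper_scale_design() -> CohortDesign:
    """Full study-scale cross-sectional design (138 subjects, 200 trials)."""
    return CohortDesign()


def scaled_down_design(**overrides) -> CohortDesign:
    """A CI-scale cross-sectional design (n = 10/12/15, 30 trials/condition).

    The planted cue x group differentials on MS 3 are boosted relative to
    the study-scale magnitudes so the designed interaction stays
    detectable at the reduced sample size: x4 on duration (whose
    per-cell estimate from a 1.2 s epoch holds only 2-3 runs, so
    segment-count quantization makes it bimodal with SD 80-100 ms) and
    x2 on coverage (quantization-free).  Multipliers come from a
    noncentral-F power calculation against the generator's own
    realization-noise model; see the methods note.
    """
    base = dict(_CROSS_TARGETS)
    boosted = {}
    for (group, cue), (dur, cov) in base.items():
        dur = dur.copy()
        cov = cov.copy()
        if cue == "negative":
            dur_neu, cov_neu = base[(group, "neutral")]
            dur[2] = dur_neu[2] + 4.0 * (dur[2] - dur_neu[2])
            cov[2] = cov_neu[2] + 2.0 * (cov[2] - cov_neu[2])
            cov[:2] = cov[:2] - (cov.sum() - 1.0) / 2.0  # re-balance to sum 1
        boosted[(group, cue)] = (dur, cov)
    kw = dict(groups={"HC": 10, "MDD": 12, "MDD+NSSI": 15},
              conditions={"neutral": 30, "negative": 30},
              duration_subject_sd=0.10, cell_targets=boosted)
    kw.update(overrides)
    return CohortDesign(**kw)


# ---------------------------------------------------------------------------
# prototype maps
# ---------------------------------------------------------------------------

def make_prototype_maps(layout: SensorLayout, k: int, seed: int | None = None,
                        max_corr: float = 0.7, max_tries: int = 2000) -> MapSet:
    """Random smooth dipolar topographies with bounded mutual similarity.

    Each map is a dipole pattern (inner product of sensor positions with a
    random moment) windowed by a Gaussian bump at a random scalp location,
    then zero-meaned and normalized.  Candidates are rejected until every
    pairwise polarity-invariant correlation is at most ``max_corr``.
    """
    if not 1 <= k <= layout.n_channels - 1:
        raise ValueError(f"K must lie in 1..{layout.n_channels - 1}, got {k}")
    rng = np.random.default_rng(seed)
    pos = layout.positions
    maps: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(maps) == k:
            break
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        center = rng.normal(size=3)
        center /= np.linalg.norm(center)
        sigma = rng.uniform(0.8, 1.5)
        m = (pos @ d) * np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * sigma ** 2))
        m = m - m.mean()
        norm = np.linalg.norm(m)
        if norm < 1e-12:
            continue
        m /= norm
        if all(abs(m @ other) <= max_corr for other in maps):
            maps.append(m)
    if len(maps) < k:
        raise RuntimeError(f"could not draw {k} maps below correlation {max_corr}")
    return MapSet(np.array(maps), {"generator": "dipolar", "seed": seed})


# ---------------------------------------------------------------------------
# label sequences and single epochs
# ---------------------------------------------------------------------------

_GAMMA_SHAPE = 4.0  # unimodal dwell-time law; mean = designed duration


def _draw_label_sequence(n_classes, duration_samples, t_total, rng):
    """I.i.d. gamma segment lengths, classes uniform with no immediate repeat."""
    labels = np.empty(t_total, dtype=int)
    pos = 0
    prev = -1
    while pos < t_total:
        choices = [c for c in range(n_classes) if c != prev] or [prev]
        cls = int(rng.choice(choices))
        length = max(1, int(round(rng.gamma(_GAMMA_SHAPE,
                                            duration_samples[cls] / _GAMMA_SHAPE))))
        labels[pos:pos + length] = cls + 1
        pos += length
        prev = cls
    return labels


def _plant_label_sequence(duration_samples, coverage, t_total, rng):
    """Compose a sequence whose per-class sample counts hit the coverage
    targets exactly (to rounding) and whose mean run lengths approximate
    the duration targets."""
    k = len(coverage)
    raw = coverage * t_total
    totals = np.floor(raw).astype(int)
    rem = t_total - totals.sum()
    order = np.argsort(-(raw - totals), kind="stable")
    totals[order[:rem]] += 1
    segments = []  # (class, length)
    for cls in range(k):
        n = totals[cls]
        if n == 0:
            continue
        # segment count by expectation-matched stochastic rounding: with
        # m in {f, f+1}, P(f) is chosen so E[n/m] equals the duration
        # target (a deterministic round() biases realized durations)
        d = max(duration_samples[cls], 1.0)
        f = max(1, int(np.floor(n / d)))
        lo, hi = n / (f + 1), n / f
        if hi <= d:
            m = f
        elif lo >= d:
            m = f + 1
        else:
            p_f = (d - lo) / (hi - lo)
            m = f if rng.random() < p_f else f + 1
        w = rng.gamma(_GAMMA_SHAPE, 1.0, size=m)
        lengths = np.maximum(1, np.round(w / w.sum() * n).astype(int))
        while lengths.sum() > n:
            lengths[np.argmax(lengths)] -= 1
        while lengths.sum() < n:
            lengths[np.argmin(lengths)] += 1
        lengths = lengths[lengths > 0]
        segments.extend((cls + 1, int(ln)) for ln in lengths)
    # arrange segments avoiding same-class adjacency (merged runs would bias
    # realized durations upward): force the majority class whenever it holds
    # at least half of the remaining slots, otherwise draw weighted at random
    by_class: dict[int, list[int]] = {}
    for cls, ln in segments:
        by_class.setdefault(cls, []).append(ln)
    for lens in by_class.values():
        rng.shuffle(lens)
    arranged = []
    last = 0
    remaining = len(segments)
    while remaining:
        counts = {c: len(v) for c, v in by_class.items() if v}
        forced = [c for c, n in counts.items() if 2 * n >= remaining + 1 and c != last]
        eligible = forced or [c for c in counts if c != last] or list(counts)
        weights = np.array([counts[c] for c in eligible], dtype=float)
        cls = int(eligible[rng.choice(len(eligible), p=weights / weights.sum())])
        arranged.append((cls, by_class[cls].pop()))
        last = cls
        remaining -= 1
    labels = np.concatenate([np.full(ln, cls, dtype=int) for cls, ln in arranged])
    return labels[:t_total]


def _signal_from_labels(mapset: MapSet, labels: np.ndarray) -> np.ndarray:
    """Class topography scaled by a half-sine envelope within each run."""
    c = mapset.n_channels
    t = len(labels)
    out = np.zeros((c, t))
    i = 0
    while i < t:
        j = i
        while j < t and labels[j] == labels[i]:
            j += 1
        if labels[i] > 0:
            env = np.sin(np.pi * (np.arange(j - i) + 0.5) / (j - i))
            out[:, i:j] = np.outer(mapset.maps[labels[i] - 1], env)
        i = j
    return out


def _add_noise(signal, snr, rng):
    if np.isinf(snr):
        return signal.copy()
    if snr <= 0:
        raise ValueError("snr must be positive (np.inf disables noise)")
    sig_gfp = signal.std(axis=0, ddof=0).mean()
    sigma = sig_gfp / snr
    return signal + rng.normal(scale=sigma, size=signal.shape)


def simulate_epoch(mapset: MapSet, duration_means_ms, epoch_window=(-200.0, 1000.0),
                   rate: float = 500.0, snr: float = np.inf,
                   seed: int | None = None, layout: SensorLayout | None = None):
    """One microstate-structured trial plus its generating label sequence.

    The trial is a concatenation of segments; within each segment every
    sample is the class topography scaled by a smooth positive half-sine
    envelope.  Segment lengths are i.i.d. gamma (shape 4) with the given
    per-class means; white noise is added so that mean signal GFP over
    mean noise GFP equals ``snr`` (``np.inf`` = noise off).
    """
    duration_means_ms = np.asarray(duration_means_ms, dtype=float)
    if np.any(duration_means_ms <= 0):
        raise ValueError("duration means must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(duration_means_ms) != mapset.n_maps:
        raise ValueError("one duration mean per class required")
    rng = np.random.default_rng(seed)
    times = time_axis(epoch_window, rate)
    dur_samples = duration_means_ms * rate / 1000.0
    labels = _draw_label_sequence(mapset.n_maps, dur_samples, len(times), rng)
    signal = _signal_from_labels(mapset, labels)
    data = _add_noise(signal, snr, rng)
    if layout is None:
        layout = standard_layout_64()
        if layout.n_channels != mapset.n_channels:
            raise ValueError("provide a layout matching the mapset channel count")
    epochs = EpochArray("synthetic", "single", data[None], rate, times, layout)
    return epochs, LabelSequence(labels, rate, mapset.n_maps)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: map set, per-cell labels and parameters."""

    mapset: MapSet
    cells: dict          # key (subject, condition[, time]) -> cell dict
    snr: float
    seed: int

    def labels(self, subject, condition, time=None) -> LabelSequence:
        return self.cells[self._key(subject, condition, time)]["labels"]

    def planted(self, subject, condition, time=None):
        cell = self.cells[self._key(subject, condition, time)]
        return cell["duration_ms"], cell["coverage"], cell["occurrence"]

    def _key(self, subject, condition, time):
        return (subject, condition) if time is None else (subject, condition, time)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, cell in self.cells.items():
            subject, condition = key[0], key[1]
            time = key[2] if len(key) > 2 else ""
            for k in range(self.mapset.n_maps):
                rows.append({
                    "subject": subject, "group": cell["group"],
                    "condition": condition, "time": time, "class": k + 1,
                    "duration": cell["duration_ms"][k],
                    "coverage": cell["coverage"][k],
                    "occurrence": cell["occurrence"][k],
                })
        return pd.DataFrame(rows)


class Cohort:
    """A simulated cohort; epochs are generated lazily and deterministically."""

    def __init__(self, design: CohortDesign, ground_truth: GroundTruth, seed: int):
        self.design = design
        self.ground_truth = ground_truth
        self.seed = seed
        self._layout = design.get_layout()
        self.subjects = []  # (subject_id, group)
        for group, size in design.groups.items():
            for i in range(size):
                self.subjects.append((f"{group}-{i + 1:03d}", group))

    def epochs(self, subject_id: str, condition: str, time: str | None = None) -> EpochArray:
        """All trials of one subject x condition (x time) cell."""
        key = self.ground_truth._key(subject_id, condition, time)
        cell = self.ground_truth.cells[key]
        labels = cell["labels"].labels
        n_trials = self.design.conditions[condition]
        signal = _signal_from_labels(self.ground_truth.mapset, labels)
        rng = np.random.default_rng(cell["noise_seed"])
        times = time_axis(self.design.epoch_window, self.design.rate)
        trials = np.empty((n_trials, signal.shape[0], signal.shape[1]))
        jitter_samples = self.design.latency_jitter_ms * self.design.rate / 1000.0
        for tr in range(n_trials):
            sig = signal
            if jitter_samples > 0:
                shift = int(round(rng.normal(scale=jitter_samples)))
                sig = np.roll(signal, shift, axis=1)
            trials[tr] = _add_noise(sig, self.design.snr, rng)
        name = condition if time is None else f"{condition}/{time}"
        return EpochArray(subject_id, name, trials, self.design.rate, times, self._layout)

    def iter_cells(self):
        """Yield (subject_id, group, condition, time, EpochArray) lazily."""
        times = self.design.times or (None,)
        for subject_id, group in self.subjects:
            for condition in self.design.conditions:
                for time in times:
                    yield subject_id, group, condition, time, \
                        self.epochs(subject_id, condition, time)


def simulate_cohort(design: CohortDesign | None = None, seed: int = 0,
                    mapset: MapSet | None = None) -> Cohort:
    """Simulate a full cohort of microstate-structured epochs.

    Per subject x condition (x time) cell, one label sequence is planted
    by composition so the cell's empirical class coverages match the
    design targets to sample rounding; per-subject duration scales are
    lognormal with sigma ``design.duration_subject_sd``, shared across a
    subject's cells so that within-subject conditions stay correlated.
    """
    design = design or CohortDesign()
    layout = design.get_layout()
    ss = np.random.SeedSequence([seed, 2024])
    map_seed, cell_root = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    if mapset is None:
        mapset = make_prototype_maps(layout, design.n_classes, map_seed)
    times = design.times or (None,)
    t_total = len(time_axis(design.epoch_window, design.rate))
    cells = {}
    subj_idx = 0
    for group, size in design.groups.items():
        for i in range(size):
            subject_id = f"{group}-{i + 1:03d}"
            subj_ss = np.random.SeedSequence([cell_root, subj_idx])
            subj_rng = np.random.default_rng(subj_ss)
            scale = float(np.exp(subj_rng.normal(0.0, design.duration_subject_sd)))
            cell_i = 0
            for condition in design.conditions:
                for time in times:
                    duration, coverage = design.targets(group, condition, time)
                    duration = duration * scale
                    cell_rng = np.random.default_rng(
                        np.random.SeedSequence([cell_root, subj_idx, cell_i]))
                    if design.coverage_concentration > 0:
                        coverage = cell_rng.dirichlet(
                            design.coverage_concentration * coverage)
                        coverage = np.maximum(coverage, 1e-6)
                        coverage /= coverage.sum()
                    dur_samples = duration * design.rate / 1000.0
                    labels = _plant_label_sequence(dur_samples, coverage,
                                                   t_total, cell_rng)
                    key = (subject_id, condition) if time is None \
                        else (subject_id, condition, time)
                    cells[key] = {
                        "group": group,
                        "labels": LabelSequence(labels, design.rate, design.n_classes),
                        "duration_ms": duration,
                        "coverage": coverage,
                        "occurrence": coverage / (duration / 1000.0),
                        "noise_seed": np.random.SeedSequence(
                            [cell_root, subj_idx, cell_i, 7]),
                    }
                    cell_i += 1
            subj_idx += 1
    truth = GroundTruth(mapset, cells, design.snr, seed)
    return Cohort(design, truth, seed)


# ---------------------------------------------------------------------------
# clinical scales
# ---------------------------------------------------------------------------

SCALE_RANGES = {"HAMD": (0.0, 52.0), "PHQ9": (0.0, 27.0), "NSSI": (0.0, np.inf),
                "age": (12.0, 17.0)}

# Baseline demographics: (mean, sd) per group, plus male fraction
_BASELINE_CELLS = {
    "HC": {"HAMD": (1.30, 1.809), "PHQ9": (1.50, 2.115), "age": (15.45, 2.282),
           "male_fraction": 8 / 20},
    "MDD": {"HAMD": (22.62, 3.448), "PHQ9": (19.60, 3.610), "age": (15.31, 1.449),
            "male_fraction": 20 / 52},
    "MDD+NSSI": {"HAMD": (23.14, 4.220), "PHQ9": (20.14, 3.586), "age": (14.33, 1.601),
                 "male_fraction": 12 / 66},
}

# Treatment-arm scale trajectories (before/after)
_LONG_SCALE_CELLS = {
    ("medication", "before"): {"HAMD": (23.612, 4.248), "PHQ9": (20.290, 3.175),
                               "NSSI": (2.065, 0.250)},
    ("medication", "after"): {"HAMD": (12.936, 3.829), "PHQ9": (11.968, 4.167),
                              "NSSI": (0.871, 0.718)},
    ("medication+rTMS", "before"): {"HAMD": (23.000, 4.336), "PHQ9": (19.905, 3.780),
                                    "NSSI": (2.143, 0.359)},
    ("medication+rTMS", "after"): {"HAMD": (8.381, 5.084), "PHQ9": (7.667, 5.713),
                                   "NSSI": (0.238, 0.539)},
}


def default_scale_cells() -> dict:
    """Baseline (cross-sectional) per-group scale means/SDs."""
    return {g: dict(v) for g, v in _BASELINE_CELLS.items()}


def longitudinal_scale_cells() -> dict:
    """Per arm x time scale means/SDs for the treatment design."""
    return {k: dict(v) for k, v in _LONG_SCALE_CELLS.items()}


def _truncnorm_draw(mean, sd, lo, hi, size, rng):
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside instrument range [{lo}, {hi}]")
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_scales(design: CohortDesign | None = None, means_sds: dict | None = None,
                    seed: int = 0, prepost_correlation: float = 0.5) -> pd.DataFrame:
    """Clinical-scale records for a cohort design.

    Cross-sectional designs (no ``times``) draw HAMD/PHQ-9/age per group
    from truncated normals and sex from the group's male fraction.
    Longitudinal designs draw before/after pairs per arm with correlation
    ``prepost_correlation`` between a subject's two time points (scores
    at stable individual levels plus occasion noise), truncated to the
    instrument ranges.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 811]))
    rows = []
    if design.times is None:
        cells = means_sds or default_scale_cells()
        for group, size in design.groups.items():
            cell = cells[group]
            draws = {}
            for scale in ("HAMD", "PHQ9", "age"):
                mean, sd = cell[scale]
                lo, hi = SCALE_RANGES[scale]
                draws[scale] = _truncnorm_draw(mean, sd, lo, hi, size, rng)
            sex = rng.random(size) < cell.get("male_fraction", 0.5)
            for i in range(size):
                rows.append({
                    "subject": f"{group}-{i + 1:03d}", "group": group,
                    "time": "baseline", "arm": "",
                    "HAMD": draws["HAMD"][i], "PHQ9": draws["PHQ9"][i],
                    "NSSI": 0.0, "age": draws["age"][i],
                    "sex": "male" if sex[i] else "female",
                })
        return pd.DataFrame(rows)

    cells = means_sds or longitudinal_scale_cells()
    rho = prepost_correlation
    base = _BASELINE_CELLS["MDD+NSSI"]
    for arm, size in design.groups.items():
        age = _truncnorm_draw(*base["age"], *SCALE_RANGES["age"], size, rng)
        sex = rng.random(size) < base["male_fraction"]
        # correlated pre/post scores: shared subject level + occasion noise
        for i in range(size):
            rec = {t: {} for t in design.times}
            for scale in ("HAMD", "PHQ9", "NSSI"):
                z_subj = rng.normal()
                for time in design.times:
                    mean, sd = cells[(arm, time)][scale]
                    lo, hi = SCALE_RANGES[scale]
                    z = np.sqrt(rho) * z_subj + np.sqrt(1 - rho) * rng.normal()
                    val = float(np.clip(mean + sd * z, lo, min(hi, 1e9)))
                    rec[time][scale] = val
            for time in design.times:
                rows.append({
                    "subject": f"{arm}-{i + 1:03d}", "group": "MDD+NSSI",
                    "time": time, "arm": arm,
                    "HAMD": rec[time]["HAMD"], "PHQ9": rec[time]["PHQ9"],
                    "NSSI": rec[time]["NSSI"], "age": float(age[i]),
                    "sex": "male" if sex[i] else "female",
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-table simulation (for statistical calibration and power studies)
# ---------------------------------------------------------------------------

def simulate_parameter_table(cell_means: dict, group_sizes: dict, sd: float,
                             within_correlation: float = 0.9,
                             seed: int | None = None,
                             dv: str = "value") -> pd.DataFrame:
    """Subject-level values for a 2-cue x groups design, bypassing the EEG.

    ``cell_means[(group, condition)]`` gives the cell mean; each subject's
    two condition values share a random effect so that the within-subject
    correlation equals ``within_correlation``.  Age/sex covariates are
    drawn from the baseline demographics.  Used for Monte-Carlo
    calibration of the mixed ANOVA without paying for signal synthesis.
    """
    rng = np.random.default_rng(seed)
    rho = within_correlation
    conditions = sorted({c for _, c in cell_means})
    rows = []
    for group, size in group_sizes.items():
        base = _BASELINE_CELLS.get(group, _BASELINE_CELLS["MDD"])
        for i in range(size):
            sid = f"{group}-{i + 1:03d}"
            z_subj = rng.normal()
            age = float(np.clip(rng.normal(*base["age"]), 12, 17))
            sex = "male" if rng.random() < base["male_fraction"] else "female"
            for cond in conditions:
                z = np.sqrt(rho) * z_subj + np.sqrt(1 - rho) * rng.normal()
                rows.append({"subject": sid, "group": group, "condition": cond,
                             dv: cell_means[(group, cond)] + sd * z,
                             "age": age, "sex": sex})
    return pd.DataFrame(rows)
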