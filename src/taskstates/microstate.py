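"""EEG microstate segmentation and parameter extraction.

A microstate is a brief period during which the scalp voltage topography
stays quasi-stable.  The engine here implements the task-EEG variant of
the classical analysis chain:

* polarity-invariant "modified" k-means clustering of topographies, where
  each time sample is assigned to the prototype map with the largest
  squared spatial correlation and each prototype is re-estimated as the
  dominant eigenvector of its assigned samples' outer-product sum;
* model selection over the number of maps K by global explained variance
  (GEV, higher is better) and the predictive-residual cross-validation
  criterion (CV, lower is better);
* backfitting a fixed map set to each subject's ERP; and
* the four per-class parameters: GEV, mean duration (ms), coverage
  (fraction of analyzed time) and occurrence (segments per second).

Polarity is ignored throughout: a topography and its negation denote the
same state, so all similarities are absolute spatial correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ERP

__all__ = [
    "MapSet",
    "LabelSequence",
    "MicrostateParams",
    "gfp",
    "spatial_correlation",
    "modified_kmeans",
    "gev_of_fit",
    "cross_validation_criterion",
    "select_n_maps",
    "backfit",
    "smooth_labels",
    "compute_parameters",
    "group_parameter_table",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSet:
    """K prototype topographies, each zero channel-mean and unit norm."""

    maps: np.ndarray  # (K, n_channels)
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if m.shape[0] > m.shape[1] - 1:
            raise ValueError("need K <= n_channels - 1")
        if not np.allclose(m.mean(axis=1), 0.0, atol=1e-9):
            raise ValueError("maps must have zero channel-mean (tol 1e-9)")
        if not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-9):
            raise ValueError("maps must have unit norm (tol 1e-9)")
        object.__setattr__(self, "maps", m)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample class labels in 1..K; 0 marks an unassigned sample."""

    labels: np.ndarray
    rate: float
    n_classes: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if lab.min(initial=0) < 0 or lab.max(initial=0) > self.n_classes:
            raise ValueError("labels must lie in 0..K")
        object.__setattr__(self, "labels", lab)

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MicrostateParams:
    """Per-class microstate parameters for one subject x condition."""

    gev: np.ndarray          # fraction per class
    duration_ms: np.ndarray  # mean dwell time; NaN for absent classes
    coverage: np.ndarray     # fraction of assigned samples
    occurrence: np.ndarray   # segments per second
    total_gev: float
    epoch_length_s: float

    def to_frame(self) -> pd.DataFrame:
        k = len(self.gev)
        return pd.DataFrame({
            "class": np.arange(1, k + 1),
            "gev": self.gev,
            "duration": self.duration_ms,
            "coverage": self.coverage,
            "occurrence": self.occurrence,
        })


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _as_matrix(data) -> np.ndarray:
    """Accept an ERP, an array (channels x samples), or a list of ERPs."""
    if isinstance(data, ERP):
        return data.data
    if isinstance(data, (list, tuple)):
        return np.concatenate([_as_matrix(d) for d in data], axis=1)
    return np.atleast_2d(np.asarray(data, dtype=float))


def _demean(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=0, keepdims=True)


def gfp(erp) -> np.ndarray:
    """Global field power: the across-channel population SD per sample."""
    v = _as_matrix(erp)
    if v.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return v.std(axis=0, ddof=0)


def gfp_peaks(data) -> np.ndarray:
    """Indices of local GFP maxima, the classical clustering subsample.

    Topographies at GFP peaks have the highest signal-to-noise ratio;
    clustering only these samples is a common alternative to using every
    sample (the default here).
    """
    g = gfp(_as_matrix(data))
    left = np.r_[True, g[1:] > g[:-1]]
    right = np.r_[g[:-1] > g[1:], True]
    return np.flatnonzero(left & right & (g > 0))


def spatial_correlation(a, b, polarity_invariant: bool = True) -> float:
    """Pearson correlation of two topographies across channels.

    With ``polarity_invariant`` (the microstate convention) the absolute
    value is returned, so a map and its negation are identical states.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("topographies must have equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("spatial correlation undefined for a zero-variance topography")
    r = float(a @ b / (na * nb))
    r = float(np.clip(r, -1.0, 1.0))
    return abs(r) if polarity_invariant else r


# --------------------------------------------------------------------------
# fit quality
# --------------------------------------------------------------------------

def _gev_terms(v: np.ndarray, maps: np.ndarray, labels0: np.ndarray):
    """Numerator contribution per sample and the GFP^2 denominator.

    ``labels0`` is 0-based with -1 for unassigned samples.  With
    average-referenced data the GFP-weighted squared correlation of
    sample t with its map a equals (v_t . a)^2 / C, so GEV reduces to
    sum (v.a)^2 / sum ||v||^2.
    """
    v = _demean(v)
    denom = float(np.sum(v * v))
    proj = maps @ v  # (K, T)
    num = np.zeros(v.shape[1])
    ok = labels0 >= 0
    num[ok] = proj[labels0[ok], np.flatnonzero(ok)] ** 2
    return num, denom


def gev_of_fit(data, mapset: MapSet, labels: LabelSequence):
    """Total and per-class global explained variance of a labeling.

    GEV = sum_t [GFP(t) * corr(v_t, map_{label(t)})]^2 / sum_t GFP(t)^2,
    with polarity-invariant correlation; GEV_k keeps only samples
    labeled k in the numerator.
    """
    v = _as_matrix(data)
    lab = np.asarray(labels.labels if isinstance(labels, LabelSequence) else labels, int)
    if lab.shape[0] != v.shape[1]:
        raise ValueError("labels must align with the samples")
    num, denom = _gev_terms(v, mapset.maps, lab - 1)
    if denom == 0.0:
        raise ValueError("GEV undefined for all-zero data")
    per_class = np.array([num[lab == k + 1].sum() for k in range(mapset.n_maps)]) / denom
    return float(num.sum() / denom), per_class


def cross_validation_criterion(data, mapset: MapSet) -> float:
    """Predictive residual-variance criterion for model selection.

    CV = sigma^2 * ((C-1)/(C-1-K))^2 with
    sigma^2 = sum_t (v_t'v_t - (a_{k(t)}'v_t)^2) / (T (C-1)),
    each sample assigned to its best map by squared correlation.
    Lower is better; the penalty grows with the number of maps K.
    """
    v = _demean(_as_matrix(data))
    c, t = v.shape
    k = mapset.n_maps
    if k >= c - 1:
        raise ValueError(
            "CV criterion undefined for K >= C-1: the penalty term (C-1)/(C-1-K) "
            "divides by zero")
    proj = mapset.maps @ v
    best = np.max(proj ** 2, axis=0)
    sigma2 = float(np.sum(v * v) - np.sum(best)) / (t * (c - 1))
    return sigma2 * ((c - 1) / (c - 1 - k)) ** 2


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def _principal_map(vk: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the outer-product sum of assigned samples."""
    # eigh on the channel covariance; samples are zero-mean across channels,
    # so the eigenvector stays zero-mean automatically
    s = vk @ vk.T
    w, u = np.linalg.eigh(s)
    m = u[:, -1]
    return m / np.linalg.norm(m)


def _kmeans_once(v: np.ndarray, k: int, iterations: int, tol: float,
                 rng: np.random.Generator):
    c, t = v.shape
    gfp2 = np.sum(v * v, axis=0)
    denom = float(gfp2.sum())
    idx = rng.choice(np.flatnonzero(gfp2 > 0), size=k, replace=False)
    maps = v[:, idx].T.copy()  # (K, C)
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    prev_gev = -np.inf
    labels = np.zeros(t, dtype=int)
    for _ in range(iterations):
        proj = maps @ v
        labels = np.argmax(proj ** 2, axis=0)
        for j in range(k):
            sel = labels == j
            if not np.any(sel):
                # re-seed an empty class from the worst-explained sample
                explained = np.max(proj ** 2, axis=0) / np.maximum(gfp2, 1e-300)
                worst = int(np.argmin(explained))
                logger.debug("re-seeding empty class %d from sample %d", j + 1, worst)
                m = v[:, worst] - v[:, worst].mean()
                maps[j] = m / np.linalg.norm(m)
                continue
            maps[j] = _principal_map(v[:, sel])
        proj = maps @ v
        labels = np.argmax(proj ** 2, axis=0)
        gev = float(np.sum(proj[labels, np.arange(t)] ** 2) / denom)
        if abs(gev - prev_gev) < tol * max(abs(prev_gev), 1e-12):
            prev_gev = gev
            break
        prev_gev = gev
    return maps, labels, prev_gev


def modified_kmeans(data, k: int, iterations: int = 1000, restarts: int = 50,
                    seed: int | None = None, tol: float = 1e-6):
    """Polarity-invariant k-means segmentation of topographies.

    Samples are assigned to the map maximizing the squared spatial
    correlation; maps are updated as the dominant eigenvector of the
    assigned samples' outer-product sum.  The best of ``restarts``
    seeded initializations by GEV is returned.

    Returns ``(MapSet, LabelSequence, gev)``.  Labels are 1-based.
    """
    v = _demean(_as_matrix(data))
    c, t = v.shape
    if not 1 <= k <= c - 1:
        raise ValueError(f"K must lie in 1..{c - 1}, got {k}")
    if t < k:
        raise ValueError("need at least K samples")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        maps, labels, gev = _kmeans_once(v, k, iterations, tol, rng)
        if best is None or gev > best[2]:
            best = (maps, labels, gev)
    maps, labels, gev = best
    rate = data.rate if isinstance(data, ERP) else 1.0
    provenance = {"iterations": iterations, "restarts": restarts, "seed": seed,
                  "gev": gev}
    if k <= c - 2:
        provenance["cv"] = cross_validation_criterion(v, MapSet(maps))
    mapset = MapSet(maps, provenance)
    return mapset, LabelSequence(labels + 1, rate, k), gev


def select_n_maps(data, k_range=(2, 8), iterations: int = 1000,
                  restarts: int = 50, seed: int | None = None):
    """Fit every K in ``k_range`` (inclusive) and pick the CV minimizer.

    Returns ``(k_star, table)`` where the table lists GEV and CV per K so
    the larger-GEV / smaller-CV judgment can also be applied by eye.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo > hi:
        raise ValueError("empty K range")
    rows = []
    ss = np.random.SeedSequence(seed)
    for k, child in zip(range(lo, hi + 1), ss.spawn(hi - lo + 1)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        mapset, _, gev = modified_kmeans(data, k, iterations, restarts, sub_seed)
        rows.append({"K": k, "gev": gev,
                     "cv": cross_validation_criterion(data, mapset)})
    table = pd.DataFrame(rows)
    k_star = int(table.loc[table["cv"].idxmin(), "K"])
    return k_star, table


# --------------------------------------------------------------------------
# backfitting and parameters
# --------------------------------------------------------------------------

def backfit(erp, mapset: MapSet) -> LabelSequence:
    """Label every sample with its best map by absolute spatial correlation.

    Ties go to the lowest class index; zero-variance samples get label 0.
    """
    v = _demean(_as_matrix(erp))
    if v.shape[0] != mapset.n_channels:
        raise ValueError("channel counts of ERP and maps must match")
    norms = np.linalg.norm(v, axis=0)
    corr2 = (mapset.maps @ v) ** 2  # proportional to squared correlation per sample
    labels = np.argmax(corr2, axis=0) + 1
    dead = norms == 0.0
    if np.any(dead):
        logger.warning("%d zero-variance samples left unassigned", int(dead.sum()))
        labels[dead] = 0
    rate = erp.rate if isinstance(erp, ERP) else 1.0
    return LabelSequence(labels, rate, mapset.n_maps)


def _segments(labels: np.ndarray):
    """Maximal runs as (class, start, length) triples, skipping label 0."""
    out = []
    t = len(labels)
    i = 0
    while i < t:
        j = i
        while j < t and labels[j] == labels[i]:
            j += 1
        if labels[i] != 0:
            out.append((int(labels[i]), i, j - i))
        i = j
    return out


def smooth_labels(labels: LabelSequence, min_duration_ms: float, erp,
                  mapset: MapSet) -> LabelSequence:
    """Absorb segments shorter than ``min_duration_ms`` into their neighbors.

    Each sample of a short interior segment is re-assigned to whichever
    neighboring segment's class correlates better with it; repeated until
    stable.  Off by default in the pipeline (min duration 0 = identity).
    """
    if min_duration_ms < 0:
        raise ValueError("min duration must be nonnegative")
    min_samples = int(np.ceil(min_duration_ms * labels.rate / 1000.0))
    if min_samples <= 1:
        return labels
    v = _demean(_as_matrix(erp))
    proj2 = (mapset.maps @ v) ** 2
    lab = labels.labels.copy()
    for _ in range(labels.n_samples):
        segs = _segments(lab)
        short = [s for s in segs
                 if s[2] < min_samples and s[1] > 0 and s[1] + s[2] < len(lab)]
        if not short:
            break
        changed = False
        for k, start, length in short:
            left = lab[start - 1]
            right = lab[start + length]
            for t in range(start, start + length):
                cand = [c for c in (left, right) if c > 0]
                if not cand:
                    continue
                new = max(cand, key=lambda c: proj2[c - 1, t])
                if new != lab[t]:
                    lab[t] = new
                    changed = True
        if not changed:
            break
    return LabelSequence(lab, labels.rate, labels.n_classes)


def compute_parameters(labels: LabelSequence, erp, mapset: MapSet,
                       occurrence_denominator: str = "epoch") -> MicrostateParams:
    """The four microstate parameters from a labeled ERP.

    Per class k: coverage is the fraction of assigned samples labeled k;
    duration is the mean length (ms) of maximal runs of k, edge-touching
    runs included; occurrence is the number of runs per second of epoch
    (``occurrence_denominator="epoch"``) or per second of assigned time
    (``"assigned"``); GEV comes from :func:`gev_of_fit`.
    """
    if occurrence_denominator not in ("epoch", "assigned"):
        raise ValueError("occurrence_denominator must be 'epoch' or 'assigned'")
    lab = labels.labels
    k = mapset.n_maps
    n_assigned = int(np.sum(lab > 0))
    if n_assigned == 0:
        raise ValueError("all samples unassigned; no parameters to compute")
    total_gev, gev_k = gev_of_fit(erp, mapset, labels)
    segs = _segments(lab)
    epoch_s = labels.n_samples / labels.rate
    denom_s = epoch_s if occurrence_denominator == "epoch" else n_assigned / labels.rate
    coverage = np.zeros(k)
    duration = np.full(k, np.nan)
    occurrence = np.zeros(k)
    for cls in range(1, k + 1):
        n_cls = int(np.sum(lab == cls))
        runs = [s for s in segs if s[0] == cls]
        coverage[cls - 1] = n_cls / n_assigned
        occurrence[cls - 1] = len(runs) / denom_s
        if runs:
            duration[cls - 1] = float(np.mean([r[2] for r in runs])) * 1000.0 / labels.rate
    return MicrostateParams(gev_k, duration, coverage, occurrence,
                            total_gev, epoch_s)


def group_parameter_table(erps, mapset: MapSet, smoothing_ms: float = 0.0,
                          occurrence_denominator: str = "epoch") -> pd.DataFrame:
    """Backfit a cohort of ERPs and tabulate parameters in long format.

    ``erps`` is an iterable of ``(erp, meta)`` pairs where ``meta`` maps
    factor names (group, time, arm, ...) to levels; subject and condition
    come from the ERP itself.  One row per subject x condition x class.
    """
    rows = []
    for erp, meta in erps:
        try:
            lab = backfit(erp, mapset)
            if smoothing_ms > 0:
                lab = smooth_labels(lab, smoothing_ms, erp, mapset)
            par = compute_parameters(lab, erp, mapset, occurrence_denominator)
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", erp.subject_id, erp.condition, exc)
            continue
        frame = par.to_frame()
        frame.insert(0, "subject", erp.subject_id)
        frame.insert(1, "condition", erp.condition)
        for key, val in meta.items():
            frame[key] = val
        frame["total_gev"] = par.total_gev
        rows.append(frame)
    if not rows:
        raise ValueError("no ERPs produced parameters")
    return pd.concat(rows, ignore_index=True)
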