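"""Statistical designs for microstate and clinical-scale tables.

Implements the study-style analysis set: one-way ANOVA reconstructed
from published group summaries, Pearson chi-square for count tables,
split-plot (mixed) repeated-measures ANOVA with one between-subject
factor, one or two within-subject factors and optional covariates,
Greenhouse-Geisser sphericity correction, simple-effects follow-ups with
Holm-adjusted pairwise comparisons, and pre/post difference correlations.

Effect tables are returned as pandas DataFrames with one row per effect
and columns::

    effect, ss, df1, df2, F, p_uncorrected, eps, df1_gg, df2_gg, p, eta_p2

``p`` carries the Greenhouse-Geisser-corrected value for within-subject
effects (identical to ``p_uncorrected`` for two-level factors, where the
single contrast forces eps = 1) and the ordinary value elsewhere.

Sums of squares are Type III: each effect is adjusted for all others via
sum-to-zero coding and model comparison.  Covariates are mean-centered
and carried in every error stratum, matching the general-linear-model
convention of mainstream commercial packages, whose repeated-measures
denominator df with N subjects, g groups, c covariates and an L-level
within factor is (N - g - c)(L - 1).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "oneway_anova_from_summary",
    "chi_square_independence",
    "mixed_anova",
    "greenhouse_geisser_epsilon",
    "simple_effects",
    "holm_bonferroni",
    "prepost_difference_correlation",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# summary-statistic tests
# ---------------------------------------------------------------------------

def oneway_anova_from_summary(groups) -> pd.DataFrame:
    """One-way ANOVA from per-group (mean, sd, n) summaries.

    Between- and within-group sums of squares are reconstructed from the
    summaries; with inputs rounded to 2-3 decimals the achievable
    agreement with published F values is about 1% for small effects.
    """
    groups = [(float(m), float(s), int(n)) for m, s, n in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 2 for _, _, n in groups):
        raise ValueError("every group needs n >= 2")
    if any(s < 0 for _, s, _ in groups):
        raise ValueError("standard deviations must be nonnegative")
    ns = np.array([n for _, _, n in groups], dtype=float)
    means = np.array([m for m, _, _ in groups])
    sds = np.array([s for _, s, _ in groups])
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sstats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta = ss_between / (ss_between + ss_within) if ss_between + ss_within > 0 else 0.0
    return pd.DataFrame([{
        "effect": "group", "ss": ss_between, "df1": df1, "df2": df2, "F": f,
        "p_uncorrected": p, "eps": 1.0, "df1_gg": float(df1), "df2_gg": float(df2),
        "p": p, "eta_p2": eta,
    }])


def chi_square_independence(table):
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.min() < 0:
        raise ValueError("need a nonnegative 2-d count table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total; drop empty rows/columns")
    res = sstats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be positive")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def holm_bonferroni(pvalues):
    """Step-down Holm adjustment; monotone, capped at 1, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels, levels-1) matrix with orthonormal columns orthogonal to 1."""
    a = np.column_stack([np.ones(levels), np.eye(levels)[:, :-1]])
    q, _ = np.linalg.qr(a)
    return q[:, 1:]


def _sum_coding(values: pd.Series):
    """Sum-to-zero (effect) coding; returns (matrix, level list)."""
    levels = sorted(pd.unique(values))
    g = len(levels)
    idx = values.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    x = np.zeros((len(values), g - 1))
    for j in range(g - 1):
        x[idx == j, j] = 1.0
    x[idx == g - 1, :] = -1.0
    return x, levels


def _covariate_column(values: pd.Series, name: str) -> np.ndarray:
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(values))
        if len(levels) != 2:
            raise ValueError(f"non-numeric covariate {name!r} must have 2 levels")
        v = values.map({levels[0]: 0.0, levels[1]: 1.0}).to_numpy()
    else:
        v = values.to_numpy(dtype=float)
    return v - v.mean()


def _type3_ss(z: np.ndarray, x: np.ndarray, term_cols: dict):
    """Type III sums of squares by model comparison, summed over the
    columns of the (possibly multivariate) response ``z``."""
    z = np.atleast_2d(z.T).T  # (N, q)
    beta, *_ = np.linalg.lstsq(x, z, rcond=None)
    resid = z - x @ beta
    rss_full = float(np.sum(resid ** 2))
    out = {}
    for term, cols in term_cols.items():
        keep = [j for j in range(x.shape[1]) if j not in cols]
        xr = x[:, keep]
        br, *_ = np.linalg.lstsq(xr, z, rcond=None)
        rss_r = float(np.sum((z - xr @ br) ** 2))
        out[term] = max(rss_r - rss_full, 0.0)
    return out, rss_full, resid


def greenhouse_geisser_epsilon(within_cov) -> float:
    """Greenhouse-Geisser epsilon from an L x L within-cell covariance.

    The covariance is transformed by orthonormal contrasts C and
    eps = tr(C'SC)^2 / ((L-1) tr((C'SC)^2)); eps = 1 under sphericity
    (compound symmetry) and for two-level factors.
    """
    s = np.asarray(within_cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise ValueError("need a square L x L covariance with L >= 2")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if np.min(np.linalg.eigvalsh((s + s.T) / 2)) < -1e-8 * max(1.0, np.abs(s).max()):
        raise ValueError("covariance must be positive semidefinite")
    c = _orthonormal_contrasts(s.shape[0])
    st = c.T @ s @ c
    tr = float(np.trace(st))
    tr2 = float(np.trace(st @ st))
    if tr2 == 0.0:
        return 1.0
    return float(tr ** 2 / ((s.shape[0] - 1) * tr2))


def _epsilon_from_residuals(resid: np.ndarray, df_err: int) -> float:
    """GG epsilon from contrast-space residuals (already transformed)."""
    q = resid.shape[1]
    if q <= 1:
        return 1.0
    s = resid.T @ resid / max(df_err, 1)
    tr = float(np.trace(s))
    tr2 = float(np.trace(s @ s))
    if tr2 == 0.0:
        return 1.0
    return float(np.clip(tr ** 2 / (q * tr2), 1.0 / q, 1.0))


def _f_row(effect, ss_eff, df1, ss_err, df_err, q, eps, tol=0.0):
    # clip numerically-zero sums of squares (constant dv -> 1e-16-scale SS)
    if ss_eff < tol:
        ss_eff = 0.0
    if ss_err < tol:
        ss_err = 0.0
    df2 = q * df_err
    if ss_err <= 0.0:
        f = 0.0 if ss_eff <= 0.0 else np.inf
    else:
        f = (ss_eff / df1) / (ss_err / df2)
    p_unc = float(sstats.f.sf(f, df1, df2)) if np.isfinite(f) and df2 > 0 else (
        1.0 if f == 0.0 else 0.0)
    d1g, d2g = eps * df1, eps * df2
    p_gg = float(sstats.f.sf(f, d1g, d2g)) if np.isfinite(f) and d2g > 0 else p_unc
    eta = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0
    return {"effect": effect, "ss": ss_eff, "df1": df1, "df2": df2, "F": f,
            "p_uncorrected": p_unc, "eps": eps, "df1_gg": d1g, "df2_gg": d2g,
            "p": p_gg, "eta_p2": eta}


# ---------------------------------------------------------------------------
# mixed (split-plot) repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _build_between(data_sub: pd.DataFrame, between, covariates):
    """Design matrix over subjects: intercept + effect-coded group + centered
    covariates.  Returns (X, term->columns map, group levels)."""
    n = len(data_sub)
    cols = [np.ones((n, 1))]
    term_cols = {}
    levels = None
    if between is not None:
        xg, levels = _sum_coding(data_sub[between])
        term_cols[between] = list(range(1, 1 + xg.shape[1]))
        cols.append(xg)
    j = sum(c.shape[1] for c in cols)
    for cov in covariates:
        v = _covariate_column(data_sub[cov], cov)[:, None]
        term_cols[cov] = [j]
        cols.append(v)
        j += 1
    x = np.hstack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        logger.warning("between-subject design is rank deficient "
                       "(covariate collinear with %s?)", between)
    return x, term_cols, levels


def _wide_within(data, dv, subject, within, between, covariates):
    """Pivot to one row per subject; drop subjects missing any within cell."""
    within = list(within)
    cells = [tuple(sorted(pd.unique(data[w]))) for w in within]
    cell_index = list(itertools.product(*cells))
    grouped = data.groupby([subject, *within], sort=True)[dv].mean()
    wide = grouped.unstack(within) if within else data.set_index(subject)[[dv]]
    if within:
        wide = wide.reindex(columns=(cell_index if len(within) > 1
                                     else [c[0] for c in cell_index]))
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("dropped %d subjects missing within-subject cells", dropped)
    keep_cols = [subject] + ([between] if between else []) + list(covariates)
    sub_info = (data[keep_cols].drop_duplicates(subject)
                .set_index(subject).loc[complete.index].reset_index())
    return complete.to_numpy(dtype=float), sub_info, cells


def mixed_anova(data: pd.DataFrame, dv: str, subject: str, within=(),
                between: str | None = None, covariates=()) -> pd.DataFrame:
    """Split-plot repeated-measures ANOVA.

    ``within`` may name zero, one or two within-subject factors;
    ``between`` one grouping factor; ``covariates`` subject-constant
    columns (non-numeric two-level covariates are 0/1 coded).  Each
    within-subject effect stratum is spanned by orthonormal contrasts,
    and the Greenhouse-Geisser correction is estimated from that
    stratum's residual covariance (eps = 1 for single-contrast strata).
    Subjects missing any within cell are removed listwise.
    """
    within = [within] if isinstance(within, str) else list(within)
    covariates = [covariates] if isinstance(covariates, str) else list(covariates)
    if len(within) > 2:
        raise ValueError("at most two within-subject factors supported")
    y, sub_info, cells = _wide_within(data, dv, subject, within, between, covariates)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    x, term_cols, _ = _build_between(sub_info, between, covariates)
    p = x.shape[1]
    if n <= p:
        raise ValueError("more between-subject parameters than subjects")
    m = y.shape[1]
    rows = []
    tol = 1e-12 * max(1.0, float(np.sum(y * y)))

    # between-subject stratum: scaled row means keep the SS partition exact
    yb = y.mean(axis=1) * np.sqrt(m)
    ss_terms, rss, _ = _type3_ss(yb, x, term_cols)
    df_err_b = n - p
    for term, cols in term_cols.items():
        rows.append(_f_row(term, ss_terms[term], len(cols), rss, df_err_b, 1, 1.0,
                           tol))

    # within-subject strata
    contrasts = [_orthonormal_contrasts(len(c)) for c in cells]
    ones = [np.ones((len(c), 1)) / np.sqrt(len(c)) for c in cells]
    strata = []
    if len(within) >= 1:
        mat = contrasts[0] if len(within) == 1 else np.kron(contrasts[0], ones[1])
        strata.append((within[0], mat))
    if len(within) == 2:
        strata.append((within[1], np.kron(ones[0], contrasts[1])))
        strata.append((f"{within[0]}:{within[1]}", np.kron(contrasts[0], contrasts[1])))
    for name, mat in strata:
        z = y @ mat
        q = z.shape[1]
        w_terms = {name: [0]}  # intercept tests the within effect itself
        for term, cols in term_cols.items():
            w_terms[f"{name}:{term}"] = cols
        ss_w, rss_w, resid = _type3_ss(z, x, w_terms)
        eps = _epsilon_from_residuals(resid, n - p)
        if eps < 0.75:
            logger.info("stratum %s: eps=%.3f, sphericity doubtful", name, eps)
        for term, cols in w_terms.items():
            df1 = q * (1 if term == name else len(cols))
            rows.append(_f_row(term, ss_w[term], df1, rss_w, n - p, q, eps, tol))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple effects
# ---------------------------------------------------------------------------

def simple_effects(data: pd.DataFrame, dv: str, subject: str, within: str,
                   between: str, slice_by: str, covariates=(),
                   error_term: str = "omnibus") -> pd.DataFrame:
    """Follow-up of a within x between interaction.

    The factor not named by ``slice_by`` is tested within each level of
    ``slice_by``.  With ``error_term="omnibus"`` the pooled residual of
    the full split-plot model supplies the denominator; ``"slice"`` uses
    each slice's own residual.  Pairwise follow-ups are Holm-adjusted
    within each slice.
    """
    if slice_by not in (within, between):
        raise ValueError("slice_by must name the within or the between factor")
    if error_term not in ("omnibus", "slice"):
        raise ValueError("error_term must be 'omnibus' or 'slice'")
    covariates = [covariates] if isinstance(covariates, str) else list(covariates)
    tested = between if slice_by == within else within
    y, sub_info, cells = _wide_within(data, dv, subject, [within], between, covariates)
    n, m = y.shape
    x, term_cols, _ = _build_between(sub_info, between, covariates)
    p = x.shape[1]
    w_levels = list(cells[0])
    g_levels = sorted(pd.unique(sub_info[between]))

    # omnibus pooled error on the per-observation scale
    yb = y.mean(axis=1) * np.sqrt(m)
    _, rss_b, _ = _type3_ss(yb, x, {})
    zc = y @ _orthonormal_contrasts(m)
    _, rss_w, _ = _type3_ss(zc, x, {})
    ms_omni = (rss_b + rss_w) / ((n - p) * m)
    df_omni = (n - p) * m

    rows = []
    pair_rows = []
    if slice_by == within:
        # test the between factor at each within level
        for j, lev in enumerate(w_levels):
            ys = y[:, j]
            ss_terms, rss_s, _ = _type3_ss(ys, x, {between: term_cols[between]})
            df1 = len(term_cols[between])
            if error_term == "slice":
                ms_err, df_err = rss_s / (n - p), n - p
            else:
                ms_err, df_err = ms_omni, df_omni
            f = (ss_terms[between] / df1) / ms_err if ms_err > 0 else 0.0
            rows.append({"slice": lev, "tested": between, "F": f,
                         "df1": df1, "df2": df_err,
                         "p": float(sstats.f.sf(f, df1, df_err))})
            pvals, pairs = [], []
            for a, b in itertools.combinations(g_levels, 2):
                ga = ys[(sub_info[between] == a).to_numpy()]
                gb = ys[(sub_info[between] == b).to_numpy()]
                se = np.sqrt(ms_err * (1 / len(ga) + 1 / len(gb)))
                t = (ga.mean() - gb.mean()) / se if se > 0 else 0.0
                pairs.append((lev, f"{a} - {b}", ga.mean() - gb.mean(), t))
                pvals.append(2 * float(sstats.t.sf(abs(t), df_err)))
            for (lev_, label, diff, t), ph in zip(pairs, holm_bonferroni(pvals)):
                pair_rows.append({"slice": lev_, "comparison": label,
                                  "difference": diff, "t": t, "p_holm": ph})
    else:
        # test the within factor inside each group
        cmat = _orthonormal_contrasts(m)
        z = y @ cmat
        for lev in g_levels:
            sel = (sub_info[between] == lev).to_numpy()
            zg = z[sel]
            ng = zg.shape[0]
            ss_eff = ng * float(np.sum(zg.mean(axis=0) ** 2))
            df1 = z.shape[1]
            if error_term == "slice":
                rss_g = float(np.sum((zg - zg.mean(axis=0)) ** 2))
                ms_err, df_err = rss_g / max((ng - 1) * df1, 1), (ng - 1) * df1
            else:
                ms_err, df_err = rss_w / ((n - p) * df1), (n - p) * df1
            f = (ss_eff / df1) / ms_err if ms_err > 0 else 0.0
            rows.append({"slice": lev, "tested": within, "F": f,
                         "df1": df1, "df2": df_err,
                         "p": float(sstats.f.sf(f, df1, df_err))})
            pvals, pairs = [], []
            for i, j in itertools.combinations(range(m), 2):
                d = y[sel, i] - y[sel, j]
                se = np.sqrt(2 * ms_err / len(d)) if error_term == "omnibus" \
                    else d.std(ddof=1) / np.sqrt(len(d))
                t = d.mean() / se if se > 0 else 0.0
                dfp = df_err if error_term == "omnibus" else len(d) - 1
                pairs.append((lev, f"{w_levels[i]} - {w_levels[j]}", d.mean(), t))
                pvals.append(2 * float(sstats.t.sf(abs(t), dfp)))
            for (lev_, label, diff, t), ph in zip(pairs, holm_bonferroni(pvals)):
                pair_rows.append({"slice": lev_, "comparison": label,
                                  "difference": diff, "t": t, "p_holm": ph})
    table = pd.DataFrame(rows)
    table.attrs["pairwise"] = pd.DataFrame(pair_rows)
    return table


# ---------------------------------------------------------------------------
# correlations of treatment-induced changes
# ---------------------------------------------------------------------------

def prepost_difference_correlation(scales: pd.DataFrame, params: pd.DataFrame,
                                   scale_cols=("HAMD", "PHQ9", "NSSI"),
                                   param_cols=("duration", "coverage", "occurrence"),
                                   arm: str | None = None,
                                   times=("before", "after")) -> pd.DataFrame:
    """Pearson correlations between treatment-induced changes.

    For each clinical scale and each microstate parameter x class, the
    per-subject after-minus-before differences are correlated; two-sided
    p-values are Holm-adjusted across all pairs.
    """
    if arm is not None:
        scales = scales[scales["arm"] == arm]
        params = params[params["arm"] == arm]
    before, after = times
    s_wide = scales.pivot_table(index="subject", columns="time",
                                values=list(scale_cols), aggfunc="mean")
    d_scale = pd.DataFrame({c: s_wide[(c, after)] - s_wide[(c, before)]
                            for c in scale_cols})
    p_wide = params.pivot_table(index="subject", columns=["time", "class"],
                                values=list(param_cols), aggfunc="mean")
    rows = []
    pvals = []
    classes = sorted(params["class"].unique())
    for pc in param_cols:
        for cls in classes:
            d_par = p_wide[(pc, after, cls)] - p_wide[(pc, before, cls)]
            for sc in scale_cols:
                pair = pd.concat([d_scale[sc], d_par], axis=1).dropna()
                if len(pair) < 3:
                    raise ValueError("need at least 3 paired subjects per correlation")
                r, p = sstats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                rows.append({"scale": sc, "parameter": pc, "class": cls,
                             "r": float(r), "p": float(p), "n": len(pair)})
                pvals.append(float(p))
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(pvals)
    return out
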