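"""Count-based miRNA differential expression.

The chain is the standard one for small count matrices: TMM (trimmed mean
of M-values) scaling factors between samples, the voom transformation
(log2-CPM with precision weights from the empirical mean-variance trend)
and an empirical-Bayes moderated t-test in which per-feature variances are
shrunk towards a pooled prior estimated by moment matching on the
log-variances.  The final filter keeps features with symmetric fold change
above a threshold and raw p below a threshold.

All three steps are written here against their published definitions; the
R reference implementations serve only as independent oracles in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import benjamini_hochberg


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.percentile(counts, 100 * p, axis=0) / lib


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those.  For each sample, M (log-ratio) and A
    (average log abundance) values against the reference are computed over
    features positive in both; after trimming the extreme ``trim_m``
    fraction of M on each side and ``trim_a`` of A, the factor is 2 to the
    inverse-variance-weighted mean M.  Factors are rescaled so their
    geometric mean (hence product) is 1.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive total count")
    f75 = _quantile_factor(x, lib)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    # degenerate: essentially identical samples
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep) or np.sum(w[keep]) == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 2.0**f if np.isfinite(f) else 1.0


# ---------------------------------------------------------------------------
# voom


@dataclass
class VoomOutput:
    """Log2-CPM matrix, matching precision weights and the fitted trend."""

    log2_cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray  # mean log2 count
    trend_y: np.ndarray  # sqrt residual standard deviation
    groups: pd.Series


def _group_means(y: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values and residual sd of the per-feature two-group model."""
    fitted = np.empty_like(y)
    rss = np.zeros(y.shape[0])
    df = y.shape[1] - len(np.unique(groups))
    for g in np.unique(groups):
        cols = groups == g
        mean_g = y[:, cols].mean(axis=1, keepdims=True)
        fitted[:, cols] = mean_g
        rss += ((y[:, cols] - mean_g) ** 2).sum(axis=1)
    sd = np.sqrt(rss / df)
    return fitted, sd


def voom_transform(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    span: float = 0.5,
    robust_iterations: int = 2,
) -> VoomOutput:
    """Log2-CPM with precision weights from the mean-variance trend.

    ``log2CPM = log2((count + 0.5) / (lib * factor + 1) * 1e6)``.  A
    per-feature two-group fit yields residual standard deviations; the
    lowess trend of sqrt(sd) on mean log2 count, interpolated at each
    observation's fitted log2 count, gives the precision weight
    ``trend^-4``.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    if counts.shape[1] < groups.nunique() + 1:
        raise ValueError("fewer samples than the design can support")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0) * factors.reindex(counts.columns).to_numpy()
    y = np.log2((x + 0.5) / (lib + 1.0) * 1e6)

    g = groups.to_numpy()
    fitted, sd = _group_means(y, g)
    # mean log2 count of each feature, and sqrt-sd of its residuals
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sd)

    order = np.argsort(sx, kind="mergesort")
    if np.allclose(sy, sy[0]):
        # flat variance (e.g. identical counts): constant trend
        trend_x, trend_y = sx[order], np.full_like(sx, max(sy[0], 1e-6))
    else:
        smoothed = lowess(
            sy, sx, frac=span, it=robust_iterations, return_sorted=True
        )
        trend_x, trend_y = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-6)

    # fitted log2 count of each observation
    lam = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    w = np.interp(lam, trend_x, trend_y) ** -4
    idx, cols = counts.index, counts.columns
    return VoomOutput(
        log2_cpm=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        trend_x=trend_x,
        trend_y=trend_y,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# moderated t


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection (y must be > 0)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1.0 < tol:
            break
    return math.sqrt(lo * hi)


def estimate_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior df d0 and prior variance s0^2.

    Works on z = log s^2, whose distribution under the scaled-F model has
    known digamma/trigamma moments; the trigamma equation is inverted
    numerically.  When the observed spread is no larger than expected from
    chi-square sampling alone the prior df is infinite and the prior
    variance is the arithmetic mean of the observed variances (so equal
    variances collapse the moderated t to the ordinary pooled t).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    d = df_residual
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        return math.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_2 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_2


@dataclass
class ModeratedTFit:
    """Per-feature moderated-t results plus the shared prior."""

    table: pd.DataFrame
    d0: float
    s0_2: float
    df_residual: float


def moderated_t_fit(voom: VoomOutput, treated_label: str = "treated") -> ModeratedTFit:
    """Weighted two-group fit with empirical-Bayes variance moderation.

    Per feature, weighted least squares on the two group means gives the
    log2 fold change (treated minus control), its unscaled variance and a
    residual variance s^2 with n-2 degrees of freedom.  The posterior
    variance is ``(d0 s0^2 + d s^2) / (d0 + d)`` and the moderated t is
    referred to a t distribution with ``d0 + d`` degrees of freedom
    (normal when d0 is infinite).
    """
    y = voom.log2_cpm.to_numpy()
    w = voom.weights.to_numpy()
    g = voom.groups.to_numpy()
    is_t = g == treated_label
    if is_t.sum() == 0 or (~is_t).sum() == 0:
        raise ValueError(f"need samples in both groups (treated label {treated_label!r})")
    df = y.shape[1] - 2
    if df < 1:
        raise ValueError("zero residual degrees of freedom: cannot moderate variances")

    wt, wc = w[:, is_t], w[:, ~is_t]
    yt, yc = y[:, is_t], y[:, ~is_t]
    swt, swc = wt.sum(axis=1), wc.sum(axis=1)
    mt = (wt * yt).sum(axis=1) / swt
    mc = (wc * yc).sum(axis=1) / swc
    logfc = mt - mc
    v_unscaled = 1.0 / swt + 1.0 / swc
    rss = (wt * (yt - mt[:, None]) ** 2).sum(axis=1) + (wc * (yc - mc[:, None]) ** 2).sum(axis=1)
    s2 = rss / df

    d0, s0_2 = estimate_prior(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    t = logfc / np.sqrt(s2_post * v_unscaled)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p_value": p,
            "adj_p_value": benjamini_hochberg(p),
            "s2": s2,
            "s2_post": s2_post,
        },
        index=voom.log2_cpm.index,
    )
    return ModeratedTFit(table=table, d0=d0, s0_2=s0_2, df_residual=df)


# ---------------------------------------------------------------------------
# filtering and end-to-end chain


def filter_mirnas(
    results: pd.DataFrame, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Keep features with |logFC| > log2(fc_threshold) and raw p < p_threshold.

    Both inequalities are strict.  Upregulated features come first sorted
    by descending logFC, then downregulated sorted ascending (most extreme
    first in each block).
    """
    lfc_min = math.log2(fc_threshold)
    kept = results[(results["logFC"].abs() > lfc_min) & (results["p_value"] < p_threshold)]
    up = kept[kept["logFC"] > 0].sort_values("logFC", ascending=False, kind="mergesort")
    down = kept[kept["logFC"] < 0].sort_values("logFC", ascending=True, kind="mergesort")
    return pd.concat([up, down])


def differential_expression(
    counts: pd.DataFrame, groups: pd.Series, drop_all_zero: bool = True
) -> ModeratedTFit:
    """Full chain: TMM factors -> voom -> moderated t on a count matrix."""
    if drop_all_zero:
        counts = counts[counts.sum(axis=1) > 0]
    factors = tmm_factors(counts)
    voom = voom_transform(counts, factors, groups)
    return moderated_t_fit(voom)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    return table.set_index(table.columns[0])[table.columns[1]]


def load_reference_mirnas() -> pd.DataFrame:
    """Bundled nine-miRNA secretome differential-expression summary
    (logFC and raw p), the worked example for the filtering rule."""
    path = files("secretodiff.data").joinpath("mirna_reference.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="mirna")
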