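"""Label-free proteomic differential abundance and the staged filter cascade.

Input is a protein quantification table: one row per accession with a
unique-peptide count, a high-confidence identification flag and positive
(or missing) abundances for the replicates of two groups.  Per protein the
module computes the treated/control abundance ratio of group means, a
ratio-variability percentage (CV of all cross-group replicate-pair
ratios), a one-way ANOVA p-value on log2 abundances and a BH q-value, then
applies the staged selection: identified -> quantified -> q < 0.05 ->
variability < 30% -> symmetric fold change > 1.5, splitting the survivors
into up- and downregulated sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import benjamini_hochberg  # noqa: F401  (re-exported module surface)


def _group_columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(prefix + "_")]
    if not cols:
        raise ValueError(f"no columns with prefix {prefix!r}_ in table")
    return cols


def compute_ratio_stats(
    table: pd.DataFrame,
    treated_prefix: str = "treated",
    control_prefix: str = "control",
) -> pd.DataFrame:
    """Per-protein ratio, variability and ANOVA statistics.

    A protein is *quantified* when it has at least one valid abundance in
    each group; unquantified proteins keep NaN statistics.  The ANOVA
    p-value needs >= 2 valid values per group.
    """
    tcols = _group_columns(table, treated_prefix)
    ccols = _group_columns(table, control_prefix)
    t_arr = table[tcols].to_numpy(dtype=float)
    c_arr = table[ccols].to_numpy(dtype=float)

    n = len(table)
    ratio = np.full(n, np.nan)
    variability = np.full(n, np.nan)
    anova_p = np.full(n, np.nan)
    quantified = np.zeros(n, dtype=bool)

    for i in range(n):
        t = t_arr[i][np.isfinite(t_arr[i])]
        c = c_arr[i][np.isfinite(c_arr[i])]
        if t.size == 0 or c.size == 0:
            continue
        quantified[i] = True
        ratio[i] = t.mean() / c.mean()
        pair = np.outer(t, 1.0 / c).ravel()
        if pair.size >= 2 and pair.mean() > 0:
            variability[i] = 100.0 * pair.std(ddof=1) / pair.mean()
        if t.size >= 2 and c.size >= 2:
            anova_p[i] = sps.f_oneway(np.log2(t), np.log2(c)).pvalue

    out = pd.DataFrame(
        {
            "quantified": quantified,
            "abundance_ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "ratio_variability_pct": variability,
            "anova_p": anova_p,
        },
        index=table.index,
    )
    for meta in ("unique_peptides", "high_conf"):
        if meta in table.columns:
            out[meta] = table[meta]
    return out


@dataclass
class CascadeReport:
    """Counts at each stage of the selection cascade."""

    identified: int
    quantified: int
    q_lt_threshold: int
    variability_lt_threshold: int
    selected: int
    up: int
    down: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def annotate_cascade(
    results: pd.DataFrame,
    q_max: float = 0.05,
    max_variability_pct: float = 30.0,
    min_fold_change: float = 1.5,
    min_unique_peptides: int = 1,
    require_high_confidence: bool = True,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the staged differential-protein filter, keeping every row.

    Stages (each conditional on the previous): identification (high
    confidence with at least ``min_unique_peptides`` unique peptides),
    quantification, BH q-value below ``q_max``, ratio variability strictly
    below ``max_variability_pct``, symmetric fold change
    ``max(r, 1/r)`` strictly above ``min_fold_change``.  Returns the
    annotated results table (flag columns ``identified``, ``q_pass``,
    ``var_pass``, ``fc_pass``, ``selected``, ``direction``) and the stage
    counts.
    """
    res = results.copy()
    if res.empty:
        empty = res.assign(
            identified=pd.Series(dtype=bool),
            q_value=pd.Series(dtype=float),
            q_pass=pd.Series(dtype=bool),
            var_pass=pd.Series(dtype=bool),
            fc_pass=pd.Series(dtype=bool),
            selected=pd.Series(dtype=bool),
            direction=pd.Series(dtype=object),
        )
        return empty, CascadeReport(0, 0, 0, 0, 0, 0, 0)

    identified = pd.Series(True, index=res.index)
    if require_high_confidence and "high_conf" in res.columns:
        identified &= res["high_conf"].astype(bool)
    if "unique_peptides" in res.columns:
        identified &= res["unique_peptides"] >= min_unique_peptides
    quantified = identified & res["quantified"].astype(bool)

    # q-values computed across the quantified proteins only
    q = np.full(len(res), np.nan)
    mask = quantified.to_numpy()
    q[mask] = benjamini_hochberg(res.loc[mask, "anova_p"])
    res["q_value"] = q

    q_pass = quantified & (res["q_value"] < q_max).fillna(False)
    var_pass = q_pass & (res["ratio_variability_pct"] < max_variability_pct).fillna(False)
    r = res["abundance_ratio"]
    sym_fc = np.maximum(r, 1.0 / r)
    fc_pass = var_pass & (sym_fc > min_fold_change).fillna(False)

    res["identified"] = identified
    res["q_pass"] = q_pass
    res["var_pass"] = var_pass
    res["fc_pass"] = fc_pass
    res["selected"] = fc_pass
    res["direction"] = np.where(
        ~fc_pass, "none", np.where(res["abundance_ratio"] > 1.0, "up", "down")
    )

    report = CascadeReport(
        identified=int(identified.sum()),
        quantified=int(quantified.sum()),
        q_lt_threshold=int(q_pass.sum()),
        variability_lt_threshold=int(var_pass.sum()),
        selected=int(fc_pass.sum()),
        up=int((res["direction"] == "up").sum()),
        down=int((res["direction"] == "down").sum()),
    )
    return res, report


def filter_cascade(results: pd.DataFrame, **thresholds) -> tuple[pd.DataFrame, CascadeReport]:
    """Selected proteins (rows passing every stage) plus the stage counts.

    Thin wrapper over :func:`annotate_cascade`; accepts the same threshold
    keyword arguments.
    """
    annotated, report = annotate_cascade(results, **thresholds)
    return annotated[annotated["selected"].astype(bool)], report


def pca_scores(
    abundances: pd.DataFrame, missing: str = "min"
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples from a protein x sample abundance matrix.

    Columns are samples.  Abundances are log2-transformed, missing values
    are imputed with the protein-wise minimum (``missing="min"``) or the
    protein is dropped (``missing="drop"``), proteins are mean-centered and
    the samples are decomposed by SVD.  The sign of each component is fixed
    so its largest-|loading| protein has a positive loading.  Returns
    (scores: sample x PC, loadings: protein x PC, variance_explained).
    """
    if abundances.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    x = np.log2(abundances.replace(0, np.nan))
    if missing == "drop":
        x = x.dropna(axis=0)
    elif missing == "min":
        x = x.apply(lambda row: row.fillna(row.min()), axis=1)
    else:
        raise ValueError("missing must be 'min' or 'drop'")
    x = x.dropna(axis=0)  # proteins missing everywhere have no information
    mat = x.to_numpy().T  # samples x proteins
    mat = mat - mat.mean(axis=0, keepdims=True)
    if not np.any(mat):
        raise ValueError("constant matrix: zero variance, PCA undefined")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    # deterministic orientation: largest-|loading| protein positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var_explained = s**2 / np.sum(s**2)
    pcs = [f"PC{k + 1}" for k in range(len(s))]
    return (
        pd.DataFrame(scores, index=abundances.columns, columns=pcs),
        pd.DataFrame(vt.T, index=x.index, columns=pcs),
        var_explained,
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """(log2 ratio, -log10 p) pairs with the selection label, plot-ready."""
    out = pd.DataFrame(
        {
            "log2_ratio": results["log2_ratio"],
            "neg_log10_p": -np.log10(results["anova_p"]),
        },
        index=results.index,
    )
    out["selected"] = results["selected"] if "selected" in results.columns else False
    return out
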