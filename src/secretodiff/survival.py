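"""Signature survival analysis and expression-drug-response association.

A gene signature is scored as the per-sample mean expression of its
members; samples are dichotomized at the median score (ties to the low
arm) and the arms are compared with the Kaplan-Meier estimator, the
two-sample log-rank test and a univariate Cox proportional-hazards model
on the arm indicator (Efron tie handling), reporting the hazard ratio of
high versus low with its 95% confidence interval.

Drug association regresses each drug's response on each gene's expression
across a cell-line panel by ordinary least squares, with the slope tested
by the one-way ANOVA F statistic (F = t^2 for a single predictor) and a
configurable significance gate (default p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

log = logging.getLogger(__name__)


def signature_score(expression: pd.DataFrame, gene_list) -> pd.Series:
    """Per-sample mean expression over the available signature genes.

    ``expression`` is gene x sample.  Genes missing from the matrix are
    logged and ignored; if none are present this raises.
    """
    genes = list(dict.fromkeys(gene_list))
    present = [g for g in genes if g in expression.index]
    absent = sorted(set(genes) - set(present))
    if absent:
        log.info("signature genes missing from expression matrix: %s", absent)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    return expression.loc[present].mean(axis=0).rename("signature_score")


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median: score > median -> 'high', else 'low'.

    Ties at the median go to the low arm.  Raises when all scores are
    equal (no split exists).
    """
    if len(scores) < 2:
        raise ValueError("need at least two samples to split")
    med = scores.median()
    if (scores == scores.iloc[0]).all():
        raise ValueError("constant scores: median split impossible")
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="arm")


@dataclass
class SurvivalResult:
    """KM curves per arm, log-rank test and the Cox hazard ratio."""

    km_curves: dict[str, pd.DataFrame]  # arm -> (time, survival) step points
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    cox_beta: float
    cox_se: float
    arm_sizes: dict[str, int]


def km_logrank_cox(
    time: pd.Series,
    event: pd.Series,
    arms: pd.Series,
    high_label: str = "high",
    low_label: str = "low",
) -> SurvivalResult:
    """Compare two survival arms.

    Product-limit curves per arm, the two-sample log-rank chi-square
    (1 df, two-sided p) and a univariate Cox fit on the high-vs-low
    indicator with Efron tie handling; the CI is ``exp(beta +/- 1.96 se)``.
    Both arms must contain at least one event.
    """
    frame = pd.DataFrame({"time": time, "event": event, "arm": arms}).dropna()
    if set(frame["arm"]) != {high_label, low_label}:
        raise ValueError(f"arms must be exactly {{{high_label!r}, {low_label!r}}}")
    if (frame["time"] < 0).any():
        raise ValueError("times must be non-negative")
    for label in (high_label, low_label):
        if frame.loc[frame["arm"] == label, "event"].sum() == 0:
            raise ValueError(f"arm {label!r} has no events")

    curves = {}
    for label, sub in frame.groupby("arm"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[label].to_numpy()}
        )

    hi = frame[frame["arm"] == high_label]
    lo = frame[frame["arm"] == low_label]
    lr = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])

    cox_frame = frame.assign(high=(frame["arm"] == high_label).astype(float))[
        ["time", "event", "high"]
    ]
    cph = CoxPHFitter()
    cph.fit(cox_frame, duration_col="time", event_col="event")
    beta = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    return SurvivalResult(
        km_curves=curves,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=float(np.exp(beta)),
        hr_ci=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        cox_beta=beta,
        cox_se=se,
        arm_sizes={high_label: len(hi), low_label: len(lo)},
    )


def cox_univariate(time: pd.Series, event: pd.Series, covariate: pd.Series) -> dict:
    """Univariate Cox PH fit on a continuous covariate (Efron ties).

    Used for parameter recovery against a planted per-unit log hazard
    ratio; the arm-based :func:`km_logrank_cox` estimates a different
    (dichotomized) contrast.
    """
    frame = pd.DataFrame({"time": time, "event": event, "x": covariate}).dropna()
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return {
        "beta": beta,
        "se": se,
        "hazard_ratio": float(np.exp(beta)),
        "ci": (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
    }


def expression_response_regression(
    expression: pd.DataFrame,
    responses: pd.DataFrame,
    gene_list=None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """OLS of each drug response on each gene's expression across lines.

    ``expression`` is gene x cell line, ``responses`` drug x cell line;
    only lines present in both are used (>= 3 required).  Per pair:
    slope, intercept, R^2, F = (R^2 / (1 - R^2)) (n - 2), the ANOVA p from
    F(1, n-2) and a significance flag at ``alpha``.  Zero-variance
    predictors yield NaN statistics and are never significant.
    """
    genes = list(expression.index if gene_list is None else gene_list)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        log.info("genes absent from panel expression: %s", sorted(missing))
        genes = [g for g in genes if g in expression.index]
    if not genes:
        raise ValueError("no requested gene present in the expression matrix")
    lines = expression.columns.intersection(responses.columns)
    if len(lines) < 3:
        raise ValueError("need at least three cell lines with both values")

    from scipy import stats as sps

    rows = []
    for drug in responses.index:
        yv = responses.loc[drug, lines].to_numpy(dtype=float)
        for gene in genes:
            xv = expression.loc[gene, lines].to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(yv)
            n = int(ok.sum())
            if n < 3 or np.var(xv[ok]) == 0:
                rows.append((gene, drug, n, *([np.nan] * 5), False))
                continue
            fit = sps.linregress(xv[ok], yv[ok])
            r2 = fit.rvalue**2
            if r2 >= 1.0:
                f_stat, p = np.inf, 0.0
            else:
                f_stat = (r2 / (1.0 - r2)) * (n - 2)
                p = float(sps.f.sf(f_stat, 1, n - 2))
            rows.append(
                (gene, drug, n, fit.slope, fit.intercept, r2, f_stat, p, bool(p < alpha))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "drug",
            "n",
            "slope",
            "intercept",
            "r_squared",
            "f_statistic",
            "anova_p",
            "significant",
        ],
    )
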