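"""Membrane antibody-array quantification and differential cytokine scoring.

A membrane carries duplicate spots per analyte plus positive (POS) and
negative (NEG) control spots.  Quantification averages duplicates,
subtracts the NEG background and rescales by the POS span so that the
positive controls map to 1; normalized means are floored at a small
constant (default 0.01) to keep log-fold changes finite.  Differential
scoring then compares treated and control membranes per analyte with a
two-tailed two-sample t-test and reports differential intensity, fold
change, relative fold change (fold change - 1) and log2 fold change, plus
a configurable count of "hits": how many of the enabled criteria call the
analyte differential.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib.resources import files
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_FLOOR = 0.01


class LayoutError(ValueError):
    """Invalid array layout (missing controls, duplicate coordinates...)."""


class NormalizationError(ValueError):
    """Raised when POS/NEG controls cannot anchor the intensity scale."""


@dataclass
class ArrayLayout:
    """Map from grid coordinates to analyte names and control roles.

    ``spots`` columns: ``row`` (letter), ``col`` (integer), ``name``,
    ``role`` (``analyte``/``POS``/``NEG``/``BLANK``), ``dup_group``.
    """

    spots: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"row", "col", "name", "role", "dup_group"}
        missing = required - set(self.spots.columns)
        if missing:
            raise LayoutError(f"layout missing columns: {sorted(missing)}")

    def validate(self) -> None:
        coords = self.spots[["row", "col"]].apply(tuple, axis=1)
        if coords.duplicated().any():
            raise LayoutError("duplicate grid coordinates in layout")
        if not (self.spots["role"] == "POS").any():
            raise LayoutError("layout has no POS control spots")
        if len(self.analytes()) == 0:
            raise LayoutError("layout defines no analytes")

    def analytes(self) -> list[str]:
        mask = self.spots["role"] == "analyte"
        return list(dict.fromkeys(self.spots.loc[mask, "name"]))

    @classmethod
    def grid(
        cls,
        analytes: Sequence[str],
        n_duplicates: int = 2,
        n_pos: int = 4,
        n_neg: int = 4,
        n_cols: int = 14,
    ) -> "ArrayLayout":
        """Build a rectangular layout with duplicate analyte spots and
        leading POS/NEG control spots, row-major like a printed membrane."""
        entries = [("POS", "POS")] * n_pos + [("NEG", "NEG")] * n_neg
        for a in analytes:
            entries.extend([(a, "analyte")] * n_duplicates)
        rows = []
        letters = string.ascii_uppercase
        dup_counter: dict[str, int] = {}
        for i, (name, role) in enumerate(entries):
            r, c = divmod(i, n_cols)
            letter = letters[r % 26] * (r // 26 + 1)
            g = dup_counter.get(name, 0)
            dup_counter[name] = g + 1
            rows.append((letter, c + 1, name, role, f"{name}"))
        layout = cls(pd.DataFrame(rows, columns=["row", "col", "name", "role", "dup_group"]))
        layout.validate()
        return layout

    @classmethod
    def from_csv(cls, path) -> "ArrayLayout":
        layout = cls(pd.read_csv(path))
        layout.validate()
        return layout

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False)


def summarize_membrane(
    raw_spots: pd.DataFrame, layout: ArrayLayout, floor: float = DEFAULT_FLOOR
) -> pd.Series:
    """Normalized per-analyte intensity of a single membrane.

    ``raw_spots`` must have columns ``row``, ``col``, ``intensity``.
    Duplicates are averaged, the NEG mean is subtracted, the result is
    divided by the background-subtracted POS mean (so POS spots map to 1)
    and clipped below at ``floor``.
    """
    merged = raw_spots.merge(layout.spots, on=["row", "col"], how="inner", validate="1:1")
    if len(merged) < len(layout.spots):
        raise LayoutError("raw spot table does not cover the layout")
    if (merged["intensity"] < 0).any():
        raise ValueError("raw intensities must be non-negative")
    pos = merged.loc[merged["role"] == "POS", "intensity"].mean()
    neg_spots = merged.loc[merged["role"] == "NEG", "intensity"]
    neg = neg_spots.mean() if len(neg_spots) else 0.0
    if not np.isfinite(pos) or pos <= neg:
        raise NormalizationError("POS control mean must exceed NEG background")
    analyte = merged[merged["role"] == "analyte"]
    means = analyte.groupby("name")["intensity"].mean()
    normalized = ((means - neg) / (pos - neg)).clip(lower=floor)
    normalized.index.name = "analyte"
    return normalized.reindex(layout.analytes())


def quantify_membranes(
    spots: pd.DataFrame, layout: ArrayLayout, floor: float = DEFAULT_FLOOR
) -> pd.DataFrame:
    """Normalize every membrane in a long (membrane_id, row, col, intensity)
    table; returns an analyte x membrane matrix."""
    out = {}
    for mem_id, sub in spots.groupby("membrane_id", sort=False):
        out[mem_id] = summarize_membrane(sub[["row", "col", "intensity"]], layout, floor)
    return pd.DataFrame(out)


def differential_cytokine_stats(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-analyte differential metrics between treated and control arrays.

    ``treated`` / ``control`` are analyte x replicate matrices of
    normalized intensities.  Reported per analyte: floored means,
    two-tailed t-test p-value (pooled variance by default, Welch with
    ``welch=True``; NA when either condition has <2 replicates or both
    have zero variance), differential intensity (treated - control), fold
    change, relative fold change and log2 fold change.
    """
    if treated.empty or control.empty:
        raise ValueError("need at least one replicate per condition")
    treated = treated.reindex(control.index)
    mt = treated.mean(axis=1).clip(lower=floor)
    mc = control.mean(axis=1).clip(lower=floor)
    fc = mt / mc
    p = np.full(len(mt), np.nan)
    if treated.shape[1] >= 2 and control.shape[1] >= 2:
        t_arr, c_arr = treated.to_numpy(), control.to_numpy()
        var0 = (np.nanvar(t_arr, axis=1) == 0) & (np.nanvar(c_arr, axis=1) == 0)
        res = sps.ttest_ind(t_arr, c_arr, axis=1, equal_var=not welch, nan_policy="omit")
        p = np.where(var0, np.nan, res.pvalue)
    return pd.DataFrame(
        {
            "intensity": mt,
            "control_intensity": mc,
            "p_value": p,
            "differential_intensity": mt - mc,
            "fold_change": fc,
            "relative_fold_change": fc - 1.0,
            "log2_fc": np.log2(fc),
        },
        index=mt.index.rename("analyte"),
    )


def derive_fold_metrics(intensity: float, differential_intensity: float) -> dict:
    """Recompute fold-change metrics from a summary row.

    Given the treated mean intensity and the differential intensity
    (treated - control), reconstructs the control mean and returns the
    fold change, relative fold change and log2 fold change it implies.
    """
    control = intensity - differential_intensity
    if control <= 0:
        raise ValueError("implied control mean must be positive")
    fc = intensity / control
    return {
        "control_intensity": control,
        "fold_change": fc,
        "relative_fold_change": fc - 1.0,
        "log2_fc": float(np.log2(fc)),
    }


@dataclass
class HitCriteria:
    """Thresholds behind the per-analyte hit count; ``None`` disables one.

    Defaults are a documented convention (p < 0.05, |differential| >= 0.05,
    |relative FC| >= 0.20, |log2 FC| >= 0.32, symmetric FC >= 1.25), not a
    claim about any particular published hit column.
    """

    p_max: Optional[float] = 0.05
    min_abs_differential: Optional[float] = 0.05
    min_abs_relative_fc: Optional[float] = 0.20
    min_abs_log2_fc: Optional[float] = 0.32
    min_symmetric_fc: Optional[float] = 1.25

    def __post_init__(self) -> None:
        if self.p_max is not None and not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        for name in (
            "min_abs_differential",
            "min_abs_relative_fc",
            "min_abs_log2_fc",
            "min_symmetric_fc",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "HitCriteria":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def count_hits(stats: pd.DataFrame, criteria: HitCriteria = HitCriteria()) -> pd.Series:
    """Number of enabled criteria each analyte satisfies (NA p never hits)."""
    n = pd.Series(0, index=stats.index, dtype=int)
    if criteria.p_max is not None:
        n += (stats["p_value"] < criteria.p_max).fillna(False).astype(int)
    if criteria.min_abs_differential is not None:
        n += (stats["differential_intensity"].abs() >= criteria.min_abs_differential).astype(int)
    if criteria.min_abs_relative_fc is not None:
        n += (stats["relative_fold_change"].abs() >= criteria.min_abs_relative_fc).astype(int)
    if criteria.min_abs_log2_fc is not None:
        n += (stats["log2_fc"].abs() >= criteria.min_abs_log2_fc).astype(int)
    if criteria.min_symmetric_fc is not None:
        sym = np.maximum(stats["fold_change"], 1.0 / stats["fold_change"])
        n += (sym >= criteria.min_symmetric_fc).astype(int)
    return n.rename("n_hits")


def select_candidates(
    stats: pd.DataFrame,
    cap: Optional[int] = None,
    min_hits: Optional[int] = None,
) -> pd.DataFrame:
    """Rank analytes by hit count, then |log2 FC|, then name (deterministic).

    ``stats`` must carry an ``n_hits`` column (see :func:`count_hits`).
    ``min_hits`` keeps only analytes at or above that hit count; ``cap``
    truncates the ranked list.
    """
    if stats.empty:
        return stats
    ranked = stats.assign(_abs_lfc=stats["log2_fc"].abs(), _name=stats.index.astype(str))
    ranked = ranked.sort_values(
        ["n_hits", "_abs_lfc", "_name"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns=["_abs_lfc", "_name"])
    if min_hits is not None:
        ranked = ranked[ranked["n_hits"] >= min_hits]
    if cap is not None:
        ranked = ranked.head(cap)
    return ranked


def load_example_summary() -> pd.DataFrame:
    """Bundled per-analyte summary of an 80-cytokine C5 membrane experiment
    (treated mean intensity, t-test p, differential intensity, relative and
    log2 fold change, hit count), used as a worked example throughout the
    docs and tests."""
    path = files("secretodiff.data").joinpath("cytokine_array_c5_summary.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="analyte", na_values=["NA"])
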