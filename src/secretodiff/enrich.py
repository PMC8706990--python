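"""Gene-set statistics: overrepresentation and preranked running-sum enrichment.

Overrepresentation analysis (ORA) scores the overlap between a query set
and each gene set with the one-sided hypergeometric tail, BH-corrected
across sets.  Preranked enrichment walks a metric-ordered gene list with a
weighted Kolmogorov-Smirnov-style running sum: members of the set add
|metric|^w (normalized), non-members subtract a uniform step, and the
enrichment score (ES) is the extreme of the running sum.  Significance
comes from gene-label permutations: the normalized ES (NES) divides by the
mean |null ES| of the same sign and the FDR follows the sign-stratified
permutation convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import benjamini_hochberg


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping emptied sets."""
        uni = set(universe)
        kept = {
            name: [m for m in members if m in uni] for name, members in self.sets.items()
        }
        kept = {k: v for k, v in kept.items() if v}
        return GeneSetCollection(kept, {k: self.descriptions.get(k, "") for k in kept})


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members... per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = [g for g in parts[2:] if g]
            sets[name] = members
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora_test(query, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each set in the query.

    ``query`` must be a subset of ``universe``; sets are intersected with
    the universe.  p is the probability of an overlap at least as large as
    observed; FDR is BH across sets.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must be non-empty")
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    restricted = collection.restrict(uni)
    n_uni, n_query = len(uni), len(q)
    rows = []
    for name, members in restricted.sets.items():
        k_set = len(set(members))
        overlap = len(q & set(members))
        expected = n_query * k_set / n_uni
        p = float(sps.hypergeom.sf(overlap - 1, n_uni, k_set, n_query))
        rows.append(
            {
                "set": name,
                "set_size": k_set,
                "overlap": overlap,
                "expected": expected,
                "fold_enrichment": overlap / expected if expected > 0 else np.nan,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["fdr"] = benjamini_hochberg(out["p_value"])
    return out


# ---------------------------------------------------------------------------
# preranked enrichment


def _order_ranked(ranked: pd.Series) -> pd.Series:
    """Descending by metric, ties broken by identifier (deterministic)."""
    if ranked.index.duplicated().any():
        raise ValueError("ranked list contains duplicate identifiers")
    frame = ranked.rename("metric").rename_axis("id").reset_index()
    frame = frame.sort_values(["metric", "id"], ascending=[False, True], kind="mergesort")
    return frame.set_index("id")["metric"]


def enrichment_score(
    ranked: pd.Series, members, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """ES of one set on an ordered metric list, with the running sum.

    Hit steps are proportional to |metric|^weight (uniform when the
    exponent is 0); miss steps are 1/(N - Nh).  Returns (ES, running sum,
    index of the extreme position).
    """
    metric = ranked.to_numpy(dtype=float)
    hit = np.asarray(ranked.index.isin(set(members)))
    n = metric.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must hit a strict, non-empty subset of the ranking")
    inc = np.where(hit, np.abs(metric) ** weight_exponent, 0.0)
    total = inc.sum()
    if total == 0:  # all hit metrics are exactly 0: fall back to uniform
        inc = hit.astype(float)
        total = inc.sum()
    steps = inc / total - (~hit) / (n - nh)
    running = np.cumsum(steps)
    i_extreme = int(np.argmax(np.abs(running)))
    return float(running[i_extreme]), running, i_extreme


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked enrichment of every set with permutation significance.

    The null distribution redraws each set's members uniformly from the
    ranked identifiers (gene-label permutation), with a fixed seed.  NES is
    ES over the mean |null ES| of the same sign; the nominal p compares
    against same-sign nulls; FDR follows the sign-stratified normalized-ES
    convention, clipped to [0, 1].  Sets that do not intersect the ranking
    (or fall below ``min_size``) are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ordered = _order_ranked(ranked)
    ids = set(ordered.index)
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_all: list[np.ndarray] = []
    for name, members in collection.sets.items():
        inside = [m for m in dict.fromkeys(members) if m in ids]
        if len(inside) < min_size:
            warnings.warn(f"gene set {name!r} skipped: <{min_size} members in the ranking")
            continue
        if len(inside) == len(ordered):
            warnings.warn(f"gene set {name!r} skipped: covers the whole ranking")
            continue
        es, running, i_ext = enrichment_score(ordered, inside, weight_exponent)
        # leading edge: hits at or before (after, for negative ES) the extreme
        hit_pos = np.asarray(ordered.index.isin(set(inside))).nonzero()[0]
        if es >= 0:
            leading = [ordered.index[i] for i in hit_pos if i <= i_ext]
        else:
            leading = [ordered.index[i] for i in hit_pos if i >= i_ext]

        null_es = np.empty(n_perm)
        pos = np.arange(len(ordered))
        for b in range(n_perm):
            draw = rng.choice(pos, size=len(inside), replace=False)
            null_es[b] = _es_from_positions(ordered.to_numpy(), draw, weight_exponent)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            nes = es / np.mean(np.abs(same_sign))
        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        null_nes = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                neg_null / np.abs(neg_null.mean()) if neg_null.size else neg_null,
            ]
        )
        null_nes_all.append(null_nes)
        rows.append(
            {
                "set": name,
                "size": len(inside),
                "es": es,
                "nes": nes,
                "p_value": float(p),
                "leading_edge": ",".join(map(str, leading)),
            }
        )

    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p_value", "leading_edge"]
    )
    if len(out):
        out["fdr"] = _gsea_fdr(out["nes"].to_numpy(), np.concatenate(null_nes_all))
        out["enriched"] = out["fdr"] < 0.05
    return out


def _es_from_positions(metric: np.ndarray, hit_idx: np.ndarray, w: float) -> float:
    n = metric.size
    nh = hit_idx.size
    hit = np.zeros(n, dtype=bool)
    hit[hit_idx] = True
    inc = np.where(hit, np.abs(metric) ** w, 0.0)
    total = inc.sum()
    if total == 0:
        inc = hit.astype(float)
        total = inc.sum()
    running = np.cumsum(inc / total - (~hit) / (n - nh))
    return float(running[np.argmax(np.abs(running))])


def _gsea_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified permutation FDR on normalized enrichment scores."""
    fdr = np.full(nes.shape, np.nan)
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            null_frac_pool = null_nes[null_nes >= 0]
            obs_pool = nes[np.isfinite(nes) & (nes >= 0)]
            null_frac = np.mean(null_frac_pool >= v) if null_frac_pool.size else 0.0
            obs_frac = np.mean(obs_pool >= v)
        else:
            null_frac_pool = null_nes[null_nes <= 0]
            obs_pool = nes[np.isfinite(nes) & (nes <= 0)]
            null_frac = np.mean(null_frac_pool <= v) if null_frac_pool.size else 0.0
            obs_frac = np.mean(obs_pool <= v)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    return fdr
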