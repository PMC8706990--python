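"""Synthetic multiomics data with planted ground truth.

Each generator emulates the statistical structure one downstream stage
assumes: log-normal label-free protein abundances in two groups of
replicates, duplicate-spot membrane intensities with positive/negative
control spots, negative-binomial miRNA counts with per-sample library
sizes, exponential proportional-hazards survival cohorts driven by a
signature score, and cell-line panels where drug response is linear in the
expression of a planted driver gene.  All generators are deterministic
under a fixed seed and return the planted truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimConfig:
    """Knobs of the synthetic data-generating process.

    Parameters
    ----------
    seed
        Seed of the pseudo-random generator; a fixed seed gives
        bit-identical output.
    n_analytes, n_proteins, n_features
        Feature counts for the cytokine-array, proteomics and miRNA-count
        generators respectively.
    n_replicates_per_group
        Biological replicates per condition for proteomics/miRNA (default
        3, the usual label-free design).
    array_replicates_per_group
        Independent membranes per condition (default 2, the usual
        antibody-array design).
    de_fraction
        Fraction of features with a planted effect; ``de_fraction * n``
        rounded is the planted-positive count.
    effect_log2fc_range
        Planted |log2 fold change| drawn uniformly from this ordered range;
        the sign is random per feature.
    noise_cv
        Replicate-level coefficient of variation of intensities (both
        proteins and array spots).
    library_size_range
        Inclusive integer range of per-sample sequencing depths.
    nb_dispersion
        Negative-binomial dispersion phi (variance = mu + phi mu^2);
        values below 1e-12 fall back to Poisson sampling.
    baseline_hazard
        Constant baseline hazard of the exponential survival model.
    hazard_log_hr
        Log hazard ratio per standard deviation of the signature score.
    censoring_rate
        Expected fraction of independently censored samples, in [0, 1).
    floor
        Minimum normalized membrane intensity (default 0.01).
    missing_fraction, missing_not_at_random
        Fraction of protein abundances set missing, and whether missingness
        preferentially hits low-abundance values.
    """

    seed: int = 0
    n_analytes: int = 80
    n_proteins: int = 1500
    n_features: int = 800
    n_replicates_per_group: int = 3
    array_replicates_per_group: int = 2
    de_fraction: float = 0.1
    effect_log2fc_range: tuple[float, float] = (1.0, 2.0)
    noise_cv: float = 0.15
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    nb_dispersion: float = 0.1
    baseline_hazard: float = 0.1
    hazard_log_hr: float = math.log(2.0)
    censoring_rate: float = 0.2
    floor: float = 0.01
    missing_fraction: float = 0.0
    missing_not_at_random: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError(
                f"censoring_rate must be in [0, 1), got {self.censoring_rate}"
            )
        for name in ("effect_log2fc_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        lo, hi = self.library_size_range
        if int(lo) != lo or int(hi) != hi:
            raise ConfigError("library sizes must be integers")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.floor <= 0:
            raise ConfigError("floor must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigError("missing_fraction must be in [0, 1]")
        if self.n_replicates_per_group < 2:
            raise ConfigError("n_replicates_per_group must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effect_log2fc_range", "library_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with generated feature identifiers."""

    feature_ids: list[str]
    is_de: np.ndarray
    log2fc: np.ndarray
    hazard_log_hr: Optional[float] = None
    signature_genes: Optional[list[str]] = None
    planted_pairs: Optional[pd.DataFrame] = None  # gene/drug/slope/intercept
    extras: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"is_de": self.is_de, "log2fc": self.log2fc},
            index=pd.Index(self.feature_ids, name="feature"),
        )


def _log2_sigma(noise_cv: float) -> float:
    # CV of a log-normal variable -> sd of its log2
    return math.sqrt(math.log1p(noise_cv**2)) / math.log(2.0)


def _plant_effects(rng, n, de_fraction, effect_range):
    k = int(round(de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=k, replace=False)
    is_de[idx] = True
    lfc = np.zeros(n)
    lo, hi = effect_range
    lfc[idx] = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    return is_de, lfc


def generate_protein_abundances(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Label-free protein quantification table for two groups of replicates.

    Returns a table indexed by accession with ``unique_peptides``,
    ``high_conf`` and ``control_i``/``treated_i`` abundance columns, plus
    the planted truth.  Non-differential proteins share their group mean;
    differential proteins have the treated mean shifted by the planted
    log2 fold change.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    r = config.n_replicates_per_group
    ids = [f"P{i + 1:05d}" for i in range(n)]
    base = rng.normal(20.0, 2.0, size=n)  # log2 abundance
    is_de, lfc = _plant_effects(rng, n, config.de_fraction, config.effect_log2fc_range)
    sigma = _log2_sigma(config.noise_cv)

    control = base[:, None] + sigma * rng.standard_normal((n, r))
    treated = (base + lfc)[:, None] + sigma * rng.standard_normal((n, r))
    table = pd.DataFrame(index=pd.Index(ids, name="accession"))
    table["unique_peptides"] = rng.poisson(6.0, size=n)
    table["high_conf"] = (rng.uniform(size=n) < 0.98).astype(int)
    for j in range(r):
        table[f"control_{j + 1}"] = np.exp2(control[:, j])
    for j in range(r):
        table[f"treated_{j + 1}"] = np.exp2(treated[:, j])

    if config.missing_fraction > 0:
        abund_cols = [c for c in table.columns if c.startswith(("control_", "treated_"))]
        vals = table[abund_cols].to_numpy()
        if config.missing_not_at_random:
            # low-abundance values are more likely to drop out
            ranks = pd.DataFrame(vals).rank().to_numpy() / vals.size
            prob = config.missing_fraction * 2.0 * (1.0 - ranks)
        else:
            prob = np.full(vals.shape, config.missing_fraction)
        vals[rng.uniform(size=vals.shape) < prob] = np.nan
        table[abund_cols] = vals

    truth = GroundTruth(ids, is_de, lfc)
    return table, truth


def generate_cytokine_membranes(config: SimConfig, layout) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw spot intensities for control/treated antibody-array membranes.

    ``layout`` is a :class:`secretodiff.cytokines.ArrayLayout`.  Duplicate
    spots are noisy copies of the same analyte level, positive-control
    spots sit at a high constant, negative-control spots at background, and
    treated membranes apply the planted fold changes.  Output is a long
    table (membrane_id, row, col, intensity).
    """
    from .cytokines import LayoutError

    spots = layout.spots
    if not (spots["role"] == "POS").any():
        raise LayoutError("layout has no positive-control spots; normalization impossible")
    rng = np.random.default_rng(config.seed)
    analytes = layout.analytes()
    n = len(analytes)
    is_de, lfc = _plant_effects(rng, n, config.de_fraction, config.effect_log2fc_range)
    # true normalized level of each analyte (relative to the POS scale)
    level = np.exp2(rng.normal(-2.0, 1.5, size=n)).clip(max=0.9)
    level_treated = level * np.exp2(lfc)

    background = 0.05
    pos_level = 1.0
    membranes = [
        (f"control_{i + 1}", dict(zip(analytes, level)))
        for i in range(config.array_replicates_per_group)
    ] + [
        (f"treated_{i + 1}", dict(zip(analytes, level_treated)))
        for i in range(config.array_replicates_per_group)
    ]

    records = []
    for mem_id, levels in membranes:
        scale = 1000.0  # arbitrary scanner units; normalization removes it
        for _, spot in spots.iterrows():
            role = spot["role"]
            if role == "POS":
                t = pos_level
            elif role in ("NEG", "BLANK"):
                t = 0.0
            else:
                t = levels[spot["name"]]
            raw = scale * (background + t * (pos_level - background) / pos_level)
            if config.noise_cv > 0:
                raw *= np.exp2(_log2_sigma(config.noise_cv) * rng.standard_normal())
            records.append((mem_id, spot["row"], spot["col"], raw))
    table = pd.DataFrame(records, columns=["membrane_id", "row", "col", "intensity"])
    truth = GroundTruth(list(analytes), is_de, lfc, extras={"true_level": level})
    return table, truth


def generate_mirna_counts(
    config: SimConfig, base_means: Optional[Sequence[float]] = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial miRNA count matrix (feature x sample) for two groups.

    Per-sample library sizes are drawn from ``library_size_range``; group
    mean proportions are scaled by them, and counts are sampled NB with the
    configured dispersion (Poisson when the dispersion is ~0).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    r = config.n_replicates_per_group
    ids = [f"mir-{i + 1:04d}" for i in range(n)]
    is_de, lfc = _plant_effects(rng, n, config.de_fraction, config.effect_log2fc_range)
    if base_means is not None:
        rel = np.asarray(base_means, dtype=float)
        if rel.size != n:
            raise ConfigError("base_means length must equal n_features")
    else:
        rel = np.exp(rng.normal(3.0, 1.5, size=n))
    lo, hi = config.library_size_range
    lib = rng.integers(int(lo), int(hi) + 1, size=2 * r)

    total = rel.sum()
    prop_c = rel / total if total > 0 else rel
    prop_t = rel * np.exp2(lfc)
    prop_t = prop_t / total if total > 0 else prop_t

    counts = np.zeros((n, 2 * r), dtype=np.int64)
    for j in range(2 * r):
        mu = (prop_c if j < r else prop_t) * lib[j]
        if config.nb_dispersion < 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            nb_n = 1.0 / config.nb_dispersion
            p = nb_n / (nb_n + mu)
            counts[:, j] = np.where(mu > 0, rng.negative_binomial(nb_n, np.minimum(p, 1.0)), 0)
    cols = [f"control_{j + 1}" for j in range(r)] + [f"treated_{j + 1}" for j in range(r)]
    table = pd.DataFrame(counts, index=pd.Index(ids, name="mirna"), columns=cols)
    truth = GroundTruth(ids, is_de, lfc, extras={"library_sizes": lib})
    return table, truth


def generate_survival_cohort(
    config: SimConfig, n_samples: int, n_genes: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Survival table + expression matrix under an exponential PH model.

    The hazard of sample *i* is ``h0 * exp(beta * z_i)`` where ``z`` is the
    standardized mean expression of the signature genes.  Censoring is
    independent: with probability ``censoring_rate`` a sample is censored
    uniformly before its event time.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(n_genes, n_samples)),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    sig = expr.mean(axis=0)
    z = (sig - sig.mean()) / sig.std(ddof=0)
    beta = config.hazard_log_hr
    hazard = config.baseline_hazard * np.exp(beta * z.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=n_samples) < config.censoring_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    surv = pd.DataFrame(
        {
            "sample_id": samples,
            "time": t_obs,
            "event": (~censored).astype(int),
        }
    ).set_index("sample_id")
    truth = GroundTruth(
        genes,
        np.ones(n_genes, dtype=bool),
        np.zeros(n_genes),
        hazard_log_hr=beta,
        signature_genes=genes,
    )
    return surv, expr, truth


def generate_cellline_panel(
    config: SimConfig, n_lines: int = 20, n_genes: int = 30, n_drugs: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cell-line expression and per-drug response tables.

    For each drug one planted driver gene makes the response linear in its
    expression (slope drawn from ``effect_log2fc_range``, random sign) plus
    Gaussian noise of standard deviation ``noise_cv``; with
    ``de_fraction == 0`` responses are pure noise.
    """
    if n_lines < 3:
        raise ConfigError("n_lines must be >= 3")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    lines = [f"CL{i + 1:03d}" for i in range(n_lines)]
    drugs = [f"drug_{i + 1}" for i in range(n_drugs)]
    expr = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(n_genes, n_lines)),
        index=pd.Index(genes, name="gene"),
        columns=lines,
    )
    resp = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_drugs, n_lines)),
        index=pd.Index(drugs, name="drug"),
        columns=lines,
    )
    pairs = []
    if config.de_fraction > 0:
        lo, hi = config.effect_log2fc_range
        for d, drug in enumerate(drugs):
            gene = genes[int(rng.integers(n_genes))]
            slope = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            intercept = rng.normal(0.0, 1.0)
            noise = config.noise_cv * rng.standard_normal(n_lines)
            resp.loc[drug] = slope * expr.loc[gene].to_numpy() + intercept + noise
            pairs.append((gene, drug, slope, intercept))
    planted = pd.DataFrame(pairs, columns=["gene", "drug", "slope", "intercept"])
    truth = GroundTruth(
        genes,
        np.isin(genes, planted["gene"].to_numpy() if len(pairs) else []),
        np.zeros(n_genes),
        planted_pairs=planted,
    )
    return expr, resp, truth


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Write any generated matrix as TSV with the feature IDs first."""
    frame.to_csv(path, sep="\t")
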