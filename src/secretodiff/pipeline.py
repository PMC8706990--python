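"""End-to-end orchestration with a single flat config and a run manifest.

The pipeline wires the stages in dependency order: synthetic (or
user-supplied) inputs -> cytokine-array scoring -> protein DE cascade ->
miRNA DE -> preranked enrichment on the moderated t ranking -> signature
survival and drug association.  Every stage writes plain TSV/JSON so it is
independently inspectable, and the manifest records the tool version, a
hash of the config and a checksum per output so deterministic stages can
be verified to reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cytokines, enrich, mirna, proteomics, simulate, survival


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic-data run."""

    seed: int = 0
    out_dir: str = "secretodiff_run"
    # stage toggles
    run_cytokines: bool = True
    run_proteins: bool = True
    run_mirna: bool = True
    run_enrichment: bool = True
    run_survival: bool = True
    run_drug_association: bool = True
    # thresholds
    q_max: float = 0.05
    max_variability_pct: float = 30.0
    min_fold_change: float = 1.5
    mirna_fc_threshold: float = 1.5
    mirna_p_threshold: float = 0.05
    alpha_drug: float = 0.01
    floor: float = cytokines.DEFAULT_FLOOR
    gsea_permutations: int = 1000
    # synthetic-data knobs not covered above
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, lo, hi in (
            ("q_max", 0.0, 1.0),
            ("mirna_p_threshold", 0.0, 1.0),
            ("alpha_drug", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")
        if self.min_fold_change < 1 or self.mirna_fc_threshold < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.max_variability_pct <= 0:
            raise ValueError("max_variability_pct must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages on synthetic data; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimConfig(seed=config.seed, floor=config.floor, **config.sim)
    outputs: list[Path] = []
    stages: list[str] = []

    if config.run_cytokines:
        layout = cytokines.ArrayLayout.grid([f"CK{i + 1:02d}" for i in range(sim_cfg.n_analytes)])
        spots, _truth = simulate.generate_cytokine_membranes(sim_cfg, layout)
        norm = cytokines.quantify_membranes(spots, layout, floor=config.floor)
        treated = norm[[c for c in norm.columns if c.startswith("treated")]]
        control = norm[[c for c in norm.columns if c.startswith("control")]]
        stats = cytokines.differential_cytokine_stats(treated, control, floor=config.floor)
        stats["n_hits"] = cytokines.count_hits(stats)
        ranked = cytokines.select_candidates(stats)
        path = out / "cytokine_stats.tsv"
        ranked.to_csv(path, sep="\t")
        outputs.append(path)
        stages.append("cytokines")

    protein_results = None
    if config.run_proteins:
        table, truth = simulate.generate_protein_abundances(sim_cfg)
        results = proteomics.compute_ratio_stats(table)
        annotated, report = proteomics.annotate_cascade(
            results,
            q_max=config.q_max,
            max_variability_pct=config.max_variability_pct,
            min_fold_change=config.min_fold_change,
        )
        protein_results = annotated
        p1 = out / "protein_results.tsv"
        annotated.to_csv(p1, sep="\t")
        p2 = out / "protein_cascade.json"
        report.to_json(p2)
        p3 = out / "protein_volcano.tsv"
        proteomics.volcano_table(annotated).to_csv(p3, sep="\t")
        outputs += [p1, p2, p3]
        stages.append("proteins")

    mirna_fit = None
    if config.run_mirna:
        counts, _truth = simulate.generate_mirna_counts(sim_cfg)
        groups = pd.Series(
            ["control"] * sim_cfg.n_replicates_per_group
            + ["treated"] * sim_cfg.n_replicates_per_group,
            index=counts.columns,
        )
        mirna_fit = mirna.differential_expression(counts, groups)
        p1 = out / "mirna_results.tsv"
        mirna_fit.table.to_csv(p1, sep="\t")
        p2 = out / "mirna_filtered.tsv"
        mirna.filter_mirnas(
            mirna_fit.table, config.mirna_fc_threshold, config.mirna_p_threshold
        ).to_csv(p2, sep="\t")
        outputs += [p1, p2]
        stages.append("mirna")

    if config.run_enrichment and mirna_fit is not None:
        ranked = mirna_fit.table["t"]
        rng = np.random.default_rng(sim_cfg.seed + 1)
        ids = list(ranked.index)
        sets = {
            f"SET_{i + 1:02d}": list(rng.choice(ids, size=25, replace=False))
            for i in range(10)
        }
        collection = enrich.GeneSetCollection(sets)
        gsea = enrich.gsea_preranked(
            ranked, collection, n_perm=config.gsea_permutations, seed=sim_cfg.seed
        )
        p1 = out / "enrichment_gsea.tsv"
        gsea.to_csv(p1, sep="\t")
        query = list(mirna_fit.table.sort_values("p_value").head(50).index)
        ora = enrich.ora_test(query, ids, collection)
        p2 = out / "enrichment_ora.tsv"
        ora.to_csv(p2, sep="\t")
        outputs += [p1, p2]
        stages.append("enrichment")

    if config.run_survival:
        surv, expr, truth = simulate.generate_survival_cohort(sim_cfg, 400, 20)
        score = survival.signature_score(expr, truth.signature_genes)
        arms = survival.median_split(score)
        res = survival.km_logrank_cox(surv["time"], surv["event"], arms)
        payload = {
            "logrank_chi2": res.logrank_chi2,
            "logrank_p": res.logrank_p,
            "hazard_ratio": res.hazard_ratio,
            "hr_ci_low": res.hr_ci[0],
            "hr_ci_high": res.hr_ci[1],
            "arm_sizes": res.arm_sizes,
        }
        p1 = out / "survival_result.json"
        p1.write_text(json.dumps(payload, indent=2))
        outputs.append(p1)
        stages.append("survival")

    if config.run_drug_association:
        expr, resp, _truth = simulate.generate_cellline_panel(sim_cfg)
        assoc = survival.expression_response_regression(expr, resp, alpha=config.alpha_drug)
        p1 = out / "drug_association.tsv"
        assoc.to_csv(p1, sep="\t", index=False)
        outputs.append(p1)
        stages.append("drug_association")

    from . import __version__

    manifest = {
        "tool": "secretodiff",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
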