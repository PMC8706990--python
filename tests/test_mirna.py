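"""TMM normalization, voom weights, moderated t, fold-change filter."""

import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from secretodiff import mirna, simulate
from secretodiff.mirna import (
    ModeratedTFit,
    VoomOutput,
    differential_expression,
    filter_mirnas,
    load_reference_mirnas,
    moderated_t_fit,
    tmm_factors,
    voom_transform,
)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(tmm_factors(counts), [1.0, 1.0])

    def test_library_size_difference_absorbed(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, 500)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(tmm_factors(counts), [1.0, 1.0], atol=1e-9)

    def test_inflated_features_shift_factor_like_brute_force(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, 400) + 1
        b = base.copy()
        b[:20] = b[:20] * 8  # 5% of features inflated in sample b
        counts = pd.DataFrame({"a": base, "b": b})
        factors = tmm_factors(counts)
        # brute-force the trimmed weighted mean on the same M/A values
        la, lb = base.sum(), b.sum()
        m = np.log2((b / lb) / (base / la))
        aa = 0.5 * np.log2((b / lb) * (base / la))
        w = (lb - b) / (lb * b) + (la - base) / (la * base)
        n = len(m)
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rm, ra = sps.rankdata(m), sps.rankdata(aa)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        raw_b = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        expected = np.array([1.0, raw_b]) / np.sqrt(raw_b)
        np.testing.assert_allclose(factors, expected, rtol=1e-10)
        assert raw_b < 1  # most features diluted in b relative to composition

    def test_scale_invariance_of_m_values_and_trimming(self, tiny_counts):
        # M, A and the trim ranks are built from count proportions, so they
        # are exactly invariant to per-sample rescaling; only the binomial
        # precision weights retain a depth dependence, leaving factors
        # equal to within a fraction of a percent
        counts, _ = tiny_counts
        f1 = tmm_factors(counts)
        scaled = counts * np.array([3, 1, 7, 2, 1, 5])
        f2 = tmm_factors(scaled)
        np.testing.assert_allclose(f1, f2, rtol=1e-2)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestVoom:
    def test_equal_counts_give_flat_output(self):
        counts = pd.DataFrame(np.full((10, 4), 50), columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        out = voom_transform(counts, pd.Series(1.0, index=list("abcd")), groups)
        assert np.ptp(out.log2_cpm.to_numpy()) == pytest.approx(0.0)
        assert np.ptp(out.weights.to_numpy()) == pytest.approx(0.0)

    def test_zero_count_closed_form(self):
        # log2CPM of a zero count at library size 1e6, factor 1
        counts = pd.DataFrame(
            {"a": [0, 999_990, 10], "b": [0, 999_980, 20], "c": [0, 999_990, 10], "d": [0, 999_985, 15]}
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        lib = counts.sum()  # each exactly 1e6
        assert (lib == 1_000_000).all()
        out = voom_transform(counts, pd.Series(1.0, index=list("abcd")), groups)
        expected = math.log2(0.5 / 1_000_001 * 1e6)
        assert out.log2_cpm.iloc[0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-1.0, abs=1e-4)

    def test_weights_increase_with_count_abundance(self):
        # shallow libraries so the Poisson part of the variance dominates
        # at the low end and the mean-variance trend has a visible slope
        cfg = simulate.SimConfig(
            seed=19, n_features=400, de_fraction=0.0,
            library_size_range=(50_000, 60_000),
        )
        counts, _ = simulate.generate_mirna_counts(cfg)
        counts = counts[counts.sum(axis=1) > 0]
        groups = pd.Series(["control"] * 3 + ["treated"] * 3, index=counts.columns)
        out = voom_transform(counts, tmm_factors(counts), groups)
        mean_count = counts.mean(axis=1)
        med_weight = out.weights.median(axis=1)
        rho = sps.spearmanr(mean_count, med_weight).statistic
        assert rho > 0.5

    def test_weights_positive_and_shapes_match(self, tiny_counts):
        counts, groups = tiny_counts
        out = voom_transform(counts, tmm_factors(counts), groups)
        assert out.weights.shape == counts.shape
        assert (out.weights.to_numpy() > 0).all()


class TestModeratedT:
    @staticmethod
    def _manual_voom(y, groups):
        idx = [f"f{i}" for i in range(y.shape[0])]
        cols = [f"s{j}" for j in range(y.shape[1])]
        frame = pd.DataFrame(y, index=idx, columns=cols)
        return VoomOutput(
            log2_cpm=frame,
            weights=pd.DataFrame(1.0, index=idx, columns=cols),
            trend_x=np.zeros(2),
            trend_y=np.ones(2),
            groups=pd.Series(groups, index=cols),
        )

    def test_logfc_is_group_mean_difference_at_equal_weights(self):
        rng = np.random.default_rng(7)
        y = rng.normal(5, 1, (40, 6))
        groups = ["control"] * 3 + ["treated"] * 3
        fit = moderated_t_fit(self._manual_voom(y, groups))
        expected = y[:, 3:].mean(axis=1) - y[:, :3].mean(axis=1)
        np.testing.assert_allclose(fit.table["logFC"], expected, atol=1e-12)

    def test_equal_variances_collapse_to_ordinary_t(self):
        # every feature has the same residual variance: moderation cannot
        # change anything, so the moderated t equals the pooled t
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (50, 1))
        pattern = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])  # same spread everywhere
        y = base + pattern[None, :]
        groups = ["control"] * 3 + ["treated"] * 3
        fit = moderated_t_fit(self._manual_voom(y, groups))
        t_ref = np.array(
            [sps.ttest_ind(y[i, 3:], y[i, :3]).statistic for i in range(y.shape[0])]
        )
        np.testing.assert_allclose(fit.table["t"], t_ref, atol=1e-8)

    def test_null_type_one_error_calibrated(self):
        hits, total = 0, 0
        for seed in range(3):
            cfg = simulate.SimConfig(seed=700 + seed, n_features=2000, de_fraction=0.0)
            counts, _ = simulate.generate_mirna_counts(cfg)
            groups = pd.Series(["control"] * 3 + ["treated"] * 3, index=counts.columns)
            fit = differential_expression(counts, groups)
            hits += int((fit.table["p_value"] < 0.05).sum())
            total += len(fit.table)
        rate = hits / total
        half = 2.576 * math.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < half

    def test_planted_effects_recovered_with_power(self):
        cfg = simulate.SimConfig(
            seed=31, n_features=2000, de_fraction=0.1, effect_log2fc_range=(2.0, 2.0)
        )
        counts, truth = simulate.generate_mirna_counts(cfg)
        groups = pd.Series(["control"] * 3 + ["treated"] * 3, index=counts.columns)
        fit = differential_expression(counts, groups)
        table = fit.table.reindex(truth.feature_ids)
        de = np.asarray(truth.is_de)
        hits = (table["p_value"] < 0.05) & (table["logFC"].abs() > math.log2(1.5))
        sensitivity = hits.to_numpy()[de].mean()
        assert sensitivity >= 0.7

    def test_zero_residual_df_rejected(self):
        y = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            moderated_t_fit(self._manual_voom(y, ["control", "treated"]))


class TestFilter:
    def test_reference_mirnas_all_pass_gate(self):
        ref = load_reference_mirnas().rename(columns={"p_value": "p_value"})
        out = filter_mirnas(ref.assign(p_value=ref["p_value"]))
        assert len(out) == 9
        assert out.index[0] == "hsa-mir-130a-3p"  # strongest upregulation first
        assert (out["logFC"].abs() > math.log2(1.5)).all()

    def test_boundary_logfc_excluded(self):
        table = pd.DataFrame(
            {"logFC": [math.log2(1.5), 1.96], "p_value": [0.01, 0.03]},
            index=["boundary", "keeper"],
        )
        out = filter_mirnas(table)
        assert list(out.index) == ["keeper"]

    def test_output_subset_and_block_ordering(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {"logFC": rng.normal(0, 2, 50), "p_value": rng.uniform(0, 1, 50)},
            index=[f"m{i}" for i in range(50)],
        )
        out = filter_mirnas(table)
        assert set(out.index) <= set(table.index)
        up = out[out["logFC"] > 0]["logFC"]
        down = out[out["logFC"] < 0]["logFC"]
        assert list(up) == sorted(up, reverse=True)
        assert list(down) == sorted(down)


def test_chain_matches_r_reference_implementations(tiny_counts):
    """Independent oracle: edgeR TMM factors and limma-voom moderated t on
    the same matrix agree with this implementation."""
    counts, groups = tiny_counts
    fit = differential_expression(counts, groups)
    factors = tmm_factors(counts)
    voom = voom_transform(counts, factors, groups)

    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        counts.to_csv(td / "counts.tsv", sep="\t")
        script = f"""
        suppressMessages({{library(edgeR); library(limma)}})
        counts <- read.delim('{td / "counts.tsv"}', row.names=1)
        d <- calcNormFactors(DGEList(counts=as.matrix(counts)), method='TMM')
        design <- model.matrix(~factor(c(0,0,0,1,1,1)))
        v <- voom(d, design)
        fit <- eBayes(lmFit(v, design))
        tt <- topTable(fit, coef=2, number=Inf, sort.by='none')
        write.table(data.frame(id=rownames(tt), tt), '{td / "r_fit.tsv"}',
                    sep='\\t', row.names=FALSE, quote=FALSE)
        write.table(data.frame(id=rownames(v$E), v$E), '{td / "r_logcpm.tsv"}',
                    sep='\\t', row.names=FALSE, quote=FALSE)
        cat(d$samples$norm.factors, sep='\\n')
        """
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_factors = np.array([float(x) for x in proc.stdout.split()])
        r_fit = pd.read_csv(td / "r_fit.tsv", sep="\t", index_col=0)
        r_logcpm = pd.read_csv(td / "r_logcpm.tsv", sep="\t", index_col=0)

    np.testing.assert_allclose(factors, r_factors, atol=1e-6)
    np.testing.assert_allclose(voom.log2_cpm.to_numpy(), r_logcpm.to_numpy(), atol=1e-10)
    r_fit = r_fit.reindex(fit.table.index)
    np.testing.assert_allclose(fit.table["logFC"], r_fit["logFC"], atol=5e-3)
    np.testing.assert_allclose(fit.table["p_value"], r_fit["P.Value"], atol=5e-3)
    assert np.corrcoef(fit.table["t"], r_fit["t"])[0, 1] > 0.999
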