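import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epidriver import (
    AnalysisThresholds,
    GeneAnnotation,
    correlate_alteration_expression,
    de_postprocess,
    eqtm_scan,
    nb_wald_de,
    updown_proportion_test,
    zscore_aberration_rates,
)
from epidriver._stats import bh_fdr, bonferroni
from conftest import make_cohort


class TestZAberrationRates:
    def test_small_row(self):
        z = pd.DataFrame([[2.5, -3, 0, 1, -2.1, 0.5]], index=["G1"])
        rates = zscore_aberration_rates(z)
        assert rates.loc["G1", "up_frac"] == pytest.approx(1 / 6)
        assert rates.loc["G1", "down_frac"] == pytest.approx(2 / 6)

    def test_all_missing_row_is_nan(self):
        z = pd.DataFrame([[np.nan, np.nan]], index=["G1"])
        rates = zscore_aberration_rates(z)
        assert np.isnan(rates.loc["G1", "up_frac"])
        assert np.isnan(rates.loc["G1", "down_frac"])

    def test_missing_cells_excluded_from_denominator(self):
        z = pd.DataFrame([[3.0, np.nan, 0.0, np.nan]], index=["G1"])
        rates = zscore_aberration_rates(z)
        assert rates.loc["G1", "up_frac"] == pytest.approx(0.5)


class TestAlterationExpressionCorrelation:
    def test_perfect_coupling(self):
        cohort = make_cohort([[0, 0, 0, 0]], [[0, 1, 2, 2]],
                             z=[[0.0, 1.0, 2.0, 2.0]])
        out = correlate_alteration_expression(cohort, "CNA")
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_constant_predictor_skipped(self):
        cohort = make_cohort([[0, 0, 0]], [[1, 1, 1]], z=[[0.0, 1.0, 2.0]])
        out = correlate_alteration_expression(cohort, "CNA")
        assert out["skip_reason"].iloc[0] == "zero predictor variance"
        assert not out["passes_filter"].iloc[0]

    def test_sna_track_equals_point_biserial(self):
        rng = np.random.default_rng(4)
        sna = (rng.random((10, 40)) < 0.3).astype(int)
        z = rng.normal(size=(10, 40)) + sna
        cohort = make_cohort(sna, np.zeros_like(sna), z=z)
        out = correlate_alteration_expression(cohort, "SNA").set_index("gene")
        for i, gene in enumerate(cohort.genes):
            if np.ptp(sna[i]) == 0:
                assert out.loc[gene, "skip_reason"] != ""
                continue
            expected = stats.pointbiserialr(sna[i], z[i])
            assert out.loc[gene, "r"] == pytest.approx(expected.correlation)
            assert out.loc[gene, "p_value"] == pytest.approx(expected.pvalue)

    def test_filter_uses_track_specific_r2(self):
        # same r^2 = 0.2: passes at the SNA limit (10%), fails at CNA (30%)
        rng = np.random.default_rng(5)
        n = 500
        x = rng.integers(0, 2, n)
        y = 1.0 * x + rng.normal(0, 1.0, n)
        cohort = make_cohort([x], [x * 2], z=[y])
        sna_out = correlate_alteration_expression(cohort, "SNA")
        cna_out = correlate_alteration_expression(cohort, "CNA")
        r2 = sna_out["r_squared"].iloc[0]
        assert 0.1 < r2 < 0.3
        assert sna_out["passes_filter"].iloc[0]
        assert not cna_out["passes_filter"].iloc[0]


def ann(symbol, chrom="1", strand="+", tss=10_000):
    return GeneAnnotation(symbol=symbol, chromosome=chrom, strand=strand,
                          tss=tss, erg_class="other")


class TestEqtmScan:
    def make_inputs(self, cpg_positions, strand="+", n=20, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{j}" for j in range(n)]
        counts = pd.DataFrame(
            rng.poisson(100, size=(1, n)).astype(float),
            index=pd.Index(["G1"], name="gene"), columns=samples)
        cpg_ids = [f"cg{k}" for k in range(len(cpg_positions))]
        coords = pd.DataFrame({"chrom": "1", "pos": cpg_positions},
                              index=pd.Index(cpg_ids, name="cpg_id"))
        betas = pd.DataFrame(rng.beta(2, 2, size=(len(cpg_ids), n)),
                             index=coords.index, columns=samples)
        return betas, coords, counts, [ann("G1", strand=strand)]

    def test_perfect_anticorrelation(self):
        betas, coords, counts, anns = self.make_inputs([10_000])
        expr = counts.loc["G1"]
        betas.loc["cg0"] = 1 - expr / (expr.max() + 1)
        out = eqtm_scan(betas, coords, counts, anns, log_transform=False)
        row = out[out["cpg_id"] == "cg0"].iloc[0]
        assert row["pearson_r"] < -0.99

    def test_window_bounds_respected(self):
        # tss=10000, + strand: [9000, 10500]; cpg at tss-1500 is outside
        betas, coords, counts, anns = self.make_inputs([8_500, 9_000, 10_500, 10_501])
        out = eqtm_scan(betas, coords, counts, anns)
        assert set(out["cpg_id"]) == {"cg1", "cg2"}

    def test_minus_strand_window_mirrored(self):
        # '-' strand: [tss-500, tss+1000]
        betas, coords, counts, anns = self.make_inputs(
            [9_499, 9_500, 11_000, 11_001], strand="-")
        out = eqtm_scan(betas, coords, counts, anns)
        assert set(out["cpg_id"]) == {"cg1", "cg2"}

    def test_translation_invariance(self):
        betas, coords, counts, anns = self.make_inputs([9_500, 10_200])
        base = eqtm_scan(betas, coords, counts, anns)
        shift = 1_000_000
        coords2 = coords.assign(pos=coords["pos"] + shift)
        anns2 = [ann("G1", tss=anns[0].tss + shift)]
        shifted = eqtm_scan(betas, coords2, counts, anns2)
        assert shifted["pearson_r"].tolist() == base["pearson_r"].tolist()
        assert set(shifted["cpg_id"]) == set(base["cpg_id"])

    def test_single_top_cpg_per_gene(self):
        betas, coords, counts, anns = self.make_inputs([9_500, 10_000, 10_200])
        out = eqtm_scan(betas, coords, counts, anns)
        assert out.groupby("gene")["is_top_for_gene"].sum().eq(1).all()


class TestDePostprocess:
    def make_table(self):
        return pd.DataFrame([
            # reads-boundary, |logFC|-boundary, fdr-boundary and clear cases
            {"gene": "G1", "total_reads": 8, "log2_fc": 3.0, "fdr": 0.001},
            {"gene": "G2", "total_reads": 100, "log2_fc": 0.9, "fdr": 0.001},
            {"gene": "G3", "total_reads": 100, "log2_fc": 1.0, "fdr": 0.001},
            {"gene": "G4", "total_reads": 100, "log2_fc": -1.5, "fdr": 0.05},
            {"gene": "G5", "total_reads": 10, "log2_fc": 1.5, "fdr": 0.049},
            {"gene": "G6", "total_reads": 100, "log2_fc": -4.0, "fdr": 0.0001},
        ])

    def test_boundary_enumeration(self):
        filtered, (up, down) = de_postprocess(self.make_table())
        # G1 fails min reads; G2 and G3 fail |logFC| > 1 (strict); G4 fails
        # FDR < 0.05 (strict); G5 and G6 survive
        assert filtered["gene"].tolist() == ["G5", "G6"]
        assert (up, down) == (1, 1)

    def test_configurable_logfc_cut(self):
        t = AnalysisThresholds(logfc_cut=2.0)
        filtered, _ = de_postprocess(self.make_table(), t)
        assert filtered["gene"].tolist() == ["G6"]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="fdr"):
            de_postprocess(self.make_table().drop(columns=["fdr"]))


class TestProportionTest:
    def test_reference_value(self):
        z, p = updown_proportion_test(30, 10, 50, 50)
        assert z == pytest.approx(2.700, abs=1e-3)
        assert p == pytest.approx(0.0069, abs=2e-4)

    def test_identical_proportions(self):
        z, p = updown_proportion_test(20, 20, 10, 10)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetric_in_groups(self):
        z1, p1 = updown_proportion_test(30, 10, 50, 50)
        z2, p2 = updown_proportion_test(50, 50, 30, 10)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_zero_total_group_raises(self):
        with pytest.raises(ValueError):
            updown_proportion_test(0, 0, 5, 5)


class TestBuiltinDe:
    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(6)
        genes = pd.Index([f"G{i}" for i in range(50)], name="gene")
        mu = np.full(50, 200.0)
        tum = pd.DataFrame(rng.poisson(np.outer(mu * np.where(genes == "G0", 8, 1), np.ones(15))),
                           index=genes, columns=[f"T{j}" for j in range(15)])
        nor = pd.DataFrame(rng.poisson(np.outer(mu, np.ones(15))),
                           index=genes, columns=[f"N{j}" for j in range(15)])
        de = nb_wald_de(tum, nor).set_index("gene")
        assert de.loc["G0", "log2_fc"] == pytest.approx(3.0, abs=0.3)
        assert de.loc["G0", "fdr"] < 0.01
        assert (de.drop("G0")["fdr"] > 0.05).mean() > 0.9

    def test_output_feeds_postprocess(self):
        rng = np.random.default_rng(7)
        genes = pd.Index(["A", "B"], name="gene")
        t = pd.DataFrame(rng.poisson(100, (2, 5)), index=genes)
        n = pd.DataFrame(rng.poisson(100, (2, 5)), index=genes)
        de = nb_wald_de(t, n)
        filtered, counts = de_postprocess(de)
        assert isinstance(filtered, pd.DataFrame) and len(counts) == 2


class TestMultipleTesting:
    def test_bh_monotone_and_bounded_below_by_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        adj = bonferroni(p)
        assert (adj <= 1.0).all()
        assert (adj >= p).all()
        assert np.allclose(np.minimum(p * 50, 1.0), adj)
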