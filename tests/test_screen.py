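import numpy as np
import pandas as pd
import pytest

from epidriver import (
    AnalysisThresholds,
    FormatError,
    ScreenParams,
    SimulationParams,
    consensus_hits,
    count_guides_from_fastq,
    gini_coefficient,
    library_representation,
    metastasis_mutation_comparison,
    simulate_screen_data,
)
from epidriver import test_guides as guide_enrichment_test
from conftest import make_cohort


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return str(path)


LIB = pd.DataFrame({
    "guide_id": ["g1", "g2"],
    "gene": ["GA", "GB"],
    "spacer": ["AAAACCCCGGGGTTTTACGT", "TTTTCCCCGGGGAAAATTTT"],
})


class TestGuideCounting:
    def test_counts_and_mapping_stats(self, tmp_path):
        s1, s2 = LIB["spacer"]
        reads = [f"AAA{s1}CCC"] * 3 + [f"GG{s2}TT"] + ["A" * 30]
        path = write_fastq(tmp_path / "a.fastq", reads)
        counts, stats = count_guides_from_fastq({"D0": path}, LIB)
        assert counts["D0"].tolist() == [3, 1]
        row = stats.iloc[0]
        assert (row["mapped"], row["ambiguous"], row["unmapped"]) == (4, 0, 1)
        assert row["mapped"] + row["ambiguous"] + row["unmapped"] == row["total"]

    def test_read_with_two_spacers_is_ambiguous(self, tmp_path):
        s1, s2 = LIB["spacer"]
        path = write_fastq(tmp_path / "a.fastq", [s1 + s2])
        counts, stats = count_guides_from_fastq({"D0": path}, LIB)
        assert counts["D0"].sum() == 0
        assert stats.iloc[0]["ambiguous"] == 1

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(FormatError, match="malformed FASTQ record at index"):
            count_guides_from_fastq({"D0": str(path)}, LIB)

    def test_revcomp_mode_recovers_flipped_reads(self, tmp_path):
        s1 = LIB["spacer"][0]
        rc = s1.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        path = write_fastq(tmp_path / "a.fastq", [f"AA{rc}GG"])
        counts, _ = count_guides_from_fastq({"D0": path}, LIB)
        assert counts["D0"].sum() == 0
        counts, _ = count_guides_from_fastq({"D0": path}, LIB, search_revcomp=True)
        assert counts.loc["g1", "D0"] == 1

    def test_one_mismatch_mode(self, tmp_path):
        s1 = LIB["spacer"][0]
        mutated = "G" + s1[1:]
        path = write_fastq(tmp_path / "a.fastq", [f"AA{mutated}GG"])
        counts0, _ = count_guides_from_fastq({"D0": path}, LIB, max_mismatch=0)
        counts1, _ = count_guides_from_fastq({"D0": path}, LIB, max_mismatch=1)
        assert counts0["D0"].sum() == 0
        assert counts1.loc["g1", "D0"] == 1

    def test_order_independent(self, tmp_path):
        s1, s2 = LIB["spacer"]
        reads = [f"A{s1}C", f"T{s2}G", f"G{s1}A"]
        p1 = write_fastq(tmp_path / "a.fastq", reads)
        p2 = write_fastq(tmp_path / "b.fastq", list(reversed(reads)))
        c1, _ = count_guides_from_fastq({"X": p1}, LIB)
        c2, _ = count_guides_from_fastq({"X": p2}, LIB)
        pd.testing.assert_frame_equal(c1, c2)


class TestLibraryRepresentation:
    def test_uniform_counts(self):
        counts = pd.DataFrame({"D0": [10, 10, 10, 10]},
                              index=pd.Index(list("abcd"), name="guide_id"))
        rep = library_representation(counts, "D0")
        assert rep["skew_ratio_p90_p10"] == pytest.approx(1.0)
        assert rep["gini"] == pytest.approx(0.0)
        assert rep["zero_fraction"] == 0.0

    @pytest.mark.parametrize("k", [2, 5, 20])
    def test_single_dominant_guide_closed_form(self, k):
        values = [0] * (k - 1) + [1000]
        assert gini_coefficient(values) == pytest.approx(1 - 1 / k)

    def test_gini_matches_definition_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.multinomial(5000, rng.dirichlet(np.full(50, 2.0))).astype(float)
        # mean absolute difference definition
        diffs = np.abs(x[:, None] - x[None, :]).mean()
        expected = diffs / (2 * x.mean())
        assert gini_coefficient(x) == pytest.approx(expected)

    def test_empty_counts_rejected(self):
        counts = pd.DataFrame({"D0": []})
        with pytest.raises(ValueError):
            library_representation(counts, "D0")


class TestGuideTest:
    def test_identical_conditions_no_hits(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(100, 200)
        counts = pd.DataFrame({"D0": base, "D14": base},
                              index=pd.Index([f"g{i}" for i in range(200)],
                                             name="guide_id"))
        calls = guide_enrichment_test(counts, ("D14", "D0"))
        assert (calls["z"] == 0).all()
        assert (calls["p_value"] == 1.0).all()

    def test_missing_condition_rejected(self):
        counts = pd.DataFrame({"D0": [1, 2]},
                              index=pd.Index(["a", "b"], name="guide_id"))
        with pytest.raises(ValueError, match="D14"):
            guide_enrichment_test(counts, ("D14", "D0"))

    def test_planted_enrichment_called(self):
        params = SimulationParams(seed=12, screen=ScreenParams(
            n_genes=200, n_enriched=5, n_depleted=5, fold=16.0))
        sim = simulate_screen_data(params)
        calls = guide_enrichment_test(sim.counts, ("D14", "D0"), library=sim.library)
        called = set(calls.loc[calls["p_value"] < 0.001, "guide_id"])
        planted = set(sim.truth["guide_id"])
        assert planted <= called
        directions = calls.set_index("guide_id").loc[sim.truth["guide_id"], "direction"]
        assert (directions.to_numpy() == sim.truth["direction"].to_numpy()).all()


def make_calls(rows):
    return pd.DataFrame(rows, columns=["guide_id", "gene", "comparison",
                                       "p_value", "direction"])


class TestConsensusHits:
    COMPS = ["D14_vs_D0", "D21_vs_D0", "D28_vs_D0"]

    def test_dual_threshold_rule(self):
        a = make_calls([("g1", "GA", "D14_vs_D0", 1e-4, "enriched")])
        b = make_calls([("g1", "GA", "D14_vs_D0", 0.05, "enriched")])
        _, guide, _ = consensus_hits({"methodA": a, "methodB": b},
                                     ["D14_vs_D0"])
        assert not guide["consensus"].any()
        b.loc[0, "p_value"] = 0.005  # below the 0.01 cutoff of method B
        _, guide, _ = consensus_hits({"methodA": a, "methodB": b},
                                     ["D14_vs_D0"])
        assert guide["consensus"].all()

    def test_direction_must_agree_between_methods(self):
        a = make_calls([("g1", "GA", "D14_vs_D0", 1e-4, "enriched")])
        b = make_calls([("g1", "GA", "D14_vs_D0", 1e-4, "depleted")])
        _, guide, _ = consensus_hits({"methodA": a, "methodB": b},
                                     ["D14_vs_D0"])
        assert not guide["consensus"].any()

    def test_gene_needs_every_required_comparison(self):
        rows = [("g1", "GA", c, 1e-5, "enriched") for c in self.COMPS]
        a = make_calls(rows)
        genes, _, _ = consensus_hits({"methodA": a}, self.COMPS)
        assert genes.set_index("gene").loc["GA", "candidate"]
        # drop one timepoint -> no longer a candidate
        genes, _, _ = consensus_hits({"methodA": make_calls(rows[:2])}, self.COMPS)
        assert not genes.set_index("gene").loc["GA", "candidate"]

    def test_opposite_directions_across_timepoints_mixed(self):
        rows = [("g1", "GA", self.COMPS[0], 1e-5, "enriched"),
                ("g1", "GA", self.COMPS[1], 1e-5, "depleted"),
                ("g1", "GA", self.COMPS[2], 1e-5, "enriched")]
        genes, _, _ = consensus_hits({"methodA": make_calls(rows)}, self.COMPS)
        row = genes.set_index("gene").loc["GA"]
        assert row["direction"] == "mixed" and not row["candidate"]

    def test_crafted_calls_match_hand_enumeration(self):
        # 5 genes x 3 timepoints: G1 full enriched; G2 misses D28; G3 full
        # depleted; G4 direction flip; G5 fails method B at D21
        rows_a, rows_b = [], []
        plan = {
            "G1": [("enriched", 1e-5, 1e-5)] * 3,
            "G2": [("enriched", 1e-5, 1e-5)] * 2 + [("enriched", 0.5, 0.5)],
            "G3": [("depleted", 1e-5, 1e-5)] * 3,
            "G4": [("enriched", 1e-5, 1e-5), ("depleted", 1e-5, 1e-5),
                   ("enriched", 1e-5, 1e-5)],
            "G5": [("enriched", 1e-5, 1e-5), ("enriched", 1e-5, 0.5),
                   ("enriched", 1e-5, 1e-5)],
        }
        for gene, specs in plan.items():
            for comp, (direction, pa, pb) in zip(self.COMPS, specs):
                rows_a.append((f"{gene}_g", gene, comp, pa, direction))
                rows_b.append((f"{gene}_g", gene, comp, pb, direction))
        genes, _, inter = consensus_hits(
            {"methodA": make_calls(rows_a), "methodB": make_calls(rows_b)},
            self.COMPS)
        got = genes.set_index("gene")
        assert got.loc["G1", "candidate"] and got.loc["G1", "direction"] == "enriched"
        assert got.loc["G3", "candidate"] and got.loc["G3", "direction"] == "depleted"
        for gene in ("G2", "G4", "G5"):
            assert not got.loc[gene, "candidate"]
        full = inter[(inter["direction"] == "enriched")
                     & (inter["comparisons"] == "&".join(self.COMPS))]
        assert full["n_guides"].iloc[0] == 1  # only G1's guide

    def test_tightening_threshold_never_adds_hits(self):
        rng = np.random.default_rng(7)
        rows = [(f"g{i}", f"G{i}", "D14_vs_D0", rng.random() * 0.01, "enriched")
                for i in range(50)]
        calls = {"methodA": make_calls(rows)}
        loose = consensus_hits(calls, ["D14_vs_D0"],
                               AnalysisThresholds(screen_p={"methodA": 0.01}))
        tight = consensus_hits(calls, ["D14_vs_D0"],
                               AnalysisThresholds(screen_p={"methodA": 0.001}))
        loose_hits = set(loose[1].loc[loose[1]["consensus"], "guide_id"])
        tight_hits = set(tight[1].loc[tight[1]["consensus"], "guide_id"])
        assert tight_hits <= loose_hits

    def test_disjoint_method_tables_rejected(self):
        a = make_calls([("g1", "GA", "c", 1e-4, "enriched")])
        b = make_calls([("g2", "GB", "c", 1e-4, "enriched")])
        with pytest.raises(ValueError, match="overlapping"):
            consensus_hits({"methodA": a, "methodB": b}, ["c"])


class TestMetastasisComparison:
    def cohort_with_labels(self, mutated, labels, code="C1"):
        sna = np.asarray([mutated], dtype=int)
        cohort = make_cohort(sna, np.zeros_like(sna), code=code,
                             genes=["GX"])
        cohort.metastasis = pd.Series(labels, index=cohort.samples)
        return cohort

    def test_percentages_per_subset(self):
        mutated = [1, 1] + [0] * 8 + [1] + [0] * 19
        labels = ["M1"] * 10 + ["M0"] * 20
        out = metastasis_mutation_comparison(
            [self.cohort_with_labels(mutated, labels)], ["GX"])
        row = out.iloc[0]
        assert row["mean_pct_m1"] == pytest.approx(20.0)
        assert row["mean_pct_m0"] == pytest.approx(5.0)

    def test_cancer_without_m1_excluded(self):
        c1 = self.cohort_with_labels([1, 0, 0, 0], ["M1", "M1", "M0", "M0"], "C1")
        c2 = self.cohort_with_labels([1, 1, 1, 1], ["M0"] * 4, "C2")
        out = metastasis_mutation_comparison([c1, c2], ["GX"])
        assert out.iloc[0]["n_cancers"] == 1
        assert out.iloc[0]["mean_pct_m1"] == pytest.approx(50.0)

    def test_na_labels_excluded(self):
        c = self.cohort_with_labels([1, 1, 0, 0], ["M1", "NA", "M0", "NA"])
        out = metastasis_mutation_comparison([c], ["GX"])
        assert out.iloc[0]["mean_pct_m1"] == pytest.approx(100.0)
        assert out.iloc[0]["mean_pct_m0"] == pytest.approx(0.0)

    def test_absent_gene_skipped_with_empty_result(self):
        c = self.cohort_with_labels([1, 0], ["M1", "M0"])
        out = metastasis_mutation_comparison([c], ["NOPE"])
        assert np.isnan(out.iloc[0]["mean_pct_m1"])
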