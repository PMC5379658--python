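import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tnbc_concord.data_model import ExpressionMatrix, GeneAnnotation
from tnbc_concord.transcript_bias import (
    class_table,
    exon_position_bias,
    length_bias,
    overlap_enrichment,
    read_category_summary,
    rrna_fraction,
)


def _annotation(classes, lengths=None):
    lengths = lengths if lengths is not None else [1000] * len(classes)
    return GeneAnnotation(pd.DataFrame(
        {"transcript_class": classes, "transcript_length": lengths},
        index=pd.Index([f"G{i}" for i in range(len(classes))], name="gene_id"),
    ))


def _de_table(n, diff_mask, enriched):
    return pd.DataFrame(
        {"is_differential": diff_mask, "enriched_in": enriched},
        index=[f"G{i}" for i in range(n)],
    )


class TestClassTable:
    def test_counts_and_percentages(self):
        classes = ["protein_coding"] * 6 + ["snoRNA"] * 4
        diff = [True, True, False, False, False, False] + [True] * 4
        enr = ["FF", "FFPE", "none", "none", "none", "none"] + ["FFPE"] * 4
        table = class_table(_de_table(10, diff, enr), _annotation(classes))
        pc = table.loc["Protein coding"]
        assert pc["n_all"] == 6 and pc["n_differential"] == 2
        assert pc["pct_differential"] == pytest.approx(100 * 2 / 6)
        sno = table.loc["snoRNA"]
        assert sno["pct_ffpe_of_differential"] == pytest.approx(100.0)
        tot = table.loc["Total"]
        assert tot["n_all"] == 10 and tot["n_differential"] == 6
        assert tot["n_ffpe_enriched"] + tot["n_ff_enriched"] == 6

    def test_empty_differential_set_no_division_errors(self):
        classes = ["lincRNA", "miRNA"]
        table = class_table(
            _de_table(2, [False, False], ["none", "none"]),
            _annotation(classes),
        )
        assert table["n_differential"].sum() == 0
        assert np.isfinite(table["pct_ffpe_of_differential"]).all()

    def test_unannotated_gene_rejected_with_ids(self):
        de = _de_table(3, [True] * 3, ["FFPE"] * 3)
        ann = _annotation(["protein_coding", "protein_coding"])
        with pytest.raises(ValueError, match="G2"):
            class_table(de, ann)


class TestLengthBias:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        n = 300
        lengths = np.round(rng.lognormal(8, 0.5, n)).astype(int)
        diff = [True] * n
        enr = ["FF", "FFPE"] * (n // 2)
        out = length_bias(
            _de_table(n, diff, enr),
            _annotation(["protein_coding"] * n, lengths),
        )
        assert out.test is not None
        assert out.test.p_value > 0.01

    def test_planted_twofold_length_bias_detected(self):
        """FFPE-enriched transcripts drawn from a 2x longer length
        distribution are flagged at p < 0.01 with 200 per group."""
        rng = np.random.default_rng(1)
        n_per = 200
        ff_len = np.round(rng.lognormal(8.0, 0.5, n_per)).astype(int)
        ffpe_len = np.round(rng.lognormal(8.0 + math.log(2), 0.5, n_per)).astype(int)
        lengths = np.concatenate([ff_len, ffpe_len])
        out = length_bias(
            _de_table(2 * n_per, [True] * 2 * n_per,
                      ["FF"] * n_per + ["FFPE"] * n_per),
            _annotation(["protein_coding"] * 2 * n_per, lengths),
        )
        assert out.test.p_value < 0.01
        assert (out.summary.loc["FFPE_enriched", "median_bp"]
                > out.summary.loc["FF_enriched", "median_bp"])

    def test_small_group_skips_test_with_notice(self):
        out = length_bias(
            _de_table(4, [True, True, False, False],
                      ["FF", "FFPE", "none", "none"]),
            _annotation(["protein_coding"] * 4),
        )
        assert out.test is None
        assert "skipped" in out.note


class TestExonPositionBias:
    def _matrix(self, counts_by_sample, exon_ids):
        return ExpressionMatrix(
            pd.DataFrame(counts_by_sample, index=exon_ids), "count"
        )

    def test_uniform_counts_give_zero(self):
        ids = [f"G1:e{i}" for i in range(6)]
        m = self._matrix({"s1": [5.0] * 6}, ids)
        out = exon_position_bias(m, {"G1": ids}, {"grp": ["s1"]})
        assert out.loc["G1", "grp"] == 0.0

    def test_strictly_increasing_counts_give_one(self):
        ids = [f"G1:e{i}" for i in range(12)]
        m = self._matrix({"s1": list(range(1, 13))}, ids)
        out = exon_position_bias(m, {"G1": ids}, {"grp": ["s1"]})
        assert out.loc["G1", "grp"] == pytest.approx(1.0)

    def test_invariant_to_scaling_a_sample(self):
        rng = np.random.default_rng(2)
        ids = [f"G1:e{i}" for i in range(8)]
        counts = rng.integers(1, 50, size=8).astype(float)
        m1 = self._matrix({"s1": counts, "s2": counts[::-1]}, ids)
        m2 = self._matrix({"s1": counts * 7.5, "s2": counts[::-1]}, ids)
        groups = {"grp": ["s1", "s2"]}
        out1 = exon_position_bias(m1, {"G1": ids}, groups)
        out2 = exon_position_bias(m2, {"G1": ids}, groups)
        assert out1.loc["G1", "grp"] == pytest.approx(out2.loc["G1", "grp"])

    def test_genes_below_exon_minimum_skipped(self):
        ids = [f"G1:e{i}" for i in range(3)]
        m = self._matrix({"s1": [1.0, 2.0, 3.0]}, ids)
        out = exon_position_bias(m, {"G1": ids}, {"grp": ["s1"]})
        assert out.empty
        assert out.attrs["n_skipped"] == 1

    def test_ff_three_prime_bias_exceeds_ffpe_on_synthetic_cohort(
        self, default_sim
    ):
        groups = {
            "FF": default_sim.counts_ff.sample_ids,
            "FFPE": default_sim.counts_ffpe.sample_ids,
        }
        out = exon_position_bias(
            default_sim.exon_counts, default_sim.gene_model, groups
        )
        assert len(out) >= 20
        assert out["FF"].mean() > out["FFPE"].mean()


def hypergeom_enumeration_oracle(universe_size, set_size, query_size, k):
    """P(X >= k) by enumerating every possible draw of the query."""
    universe = list(range(universe_size))
    members = set(range(set_size))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(members & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOverlapEnrichment:
    def test_perfect_overlap_closed_form(self):
        universe = [f"G{i}" for i in range(100)]
        query = universe[:5]
        out = overlap_enrichment(query, {"S": set(query)}, universe)
        assert out.loc["S", "p_value"] == pytest.approx(1 / math.comb(100, 5))

    def test_zero_overlap_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        out = overlap_enrichment(
            universe[:3], {"S": set(universe[10:14])}, universe
        )
        assert out.loc["S", "overlap_k"] == 0 or out.loc["S", "p_value"] <= 1.0
        # k = 0 -> P(X >= 0) = 1 is only attained when overlap is zero
        if out.loc["S", "overlap_k"] == 0:
            assert out.loc["S", "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "N,K,n,k", [(10, 4, 3, 2), (12, 5, 4, 1), (8, 3, 3, 3), (12, 6, 6, 4)]
    )
    def test_matches_enumeration_for_small_universes(self, N, K, n, k):
        universe = [f"G{i}" for i in range(N)]
        members = set(universe[:K])
        # pick a query achieving exactly k overlap
        query = universe[:k] + universe[K:K + (n - k)]
        out = overlap_enrichment(query, {"S": members}, universe)
        assert out.loc["S", "overlap_k"] == k
        assert out.loc["S", "p_value"] == pytest.approx(
            hypergeom_enumeration_oracle(N, K, n, k)
        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            overlap_enrichment(["X"], {"S": {"G1"}}, ["G1", "G2"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment([], {"S": {"G1"}}, ["G1"])
        with pytest.raises(ValueError):
            overlap_enrichment(["G1"], {"S": {"G1"}}, [])


class TestReadCategorySummary:
    def test_arithmetic(self):
        counts = pd.DataFrame(
            {"on_target": [80.0], "intronic": [15.0], "intergenic": [5.0],
             "unmapped": [10.0]},
            index=["S1"],
        )
        pct, comp = read_category_summary(counts)
        assert pct.loc["S1", "on_target_pct"] == pytest.approx(80.0)
        assert pct.loc["S1", "intronic_pct"] == pytest.approx(15.0)
        assert pct.loc["S1", "unmapped_pct_of_total"] == pytest.approx(
            100 * 10 / 110
        )
        assert comp is None

    def test_identical_samples_give_degenerate_comparison(self):
        counts = pd.DataFrame(
            {"on_target": [80.0] * 4, "intronic": [15.0] * 4,
             "intergenic": [5.0] * 4, "unmapped": [0.0] * 4},
            index=["a1", "a2", "b1", "b2"],
        )
        groups = pd.Series({"a1": "FF", "a2": "FF", "b1": "FFPE", "b2": "FFPE"})
        _, comp = read_category_summary(counts, groups)
        assert (comp["p_value"] == 1.0).all()

    def test_zero_mapped_reads_rejected(self):
        counts = pd.DataFrame(
            {"on_target": [0.0], "intronic": [0.0], "intergenic": [0.0],
             "unmapped": [10.0]},
            index=["S1"],
        )
        with pytest.raises(ValueError, match="S1"):
            read_category_summary(counts)

    def test_ffpe_intron_heavy_on_synthetic_cohort(self, default_sim):
        cats = default_sim.read_categories
        groups = pd.Series(
            {s: ("FFPE" if s.endswith("_FFPE") else "FF") for s in cats.index}
        )
        pct, comp = read_category_summary(cats, groups)
        ffpe = pct[groups == "FFPE"]
        ff = pct[groups == "FF"]
        assert ffpe["intronic_pct"].mean() > ff["intronic_pct"].mean()
        assert comp.loc["intronic_pct", "p_value"] < 1e-4


class TestRrnaFraction:
    def test_no_rrna_genes_gives_zero(self, tiny_counts, tiny_annotation):
        ann = tiny_annotation
        ann.table.loc["G3", "transcript_class"] = "miRNA"
        frac = rrna_fraction(tiny_counts, ann)
        assert (frac == 0.0).all()

    def test_all_counts_in_one_rrna_gene(self, tiny_annotation):
        counts = ExpressionMatrix(
            pd.DataFrame({"S": [0.0, 0.0, 55.0]}, index=["G1", "G2", "G3"]),
            "count",
        )
        assert rrna_fraction(counts, tiny_annotation)["S"] == pytest.approx(1.0)

    def test_hand_arithmetic(self, tiny_annotation):
        counts = ExpressionMatrix(
            pd.DataFrame({"S": [99.0, 99.0, 2.0]}, index=["G1", "G2", "G3"]),
            "count",
        )
        assert rrna_fraction(counts, tiny_annotation)["S"] == pytest.approx(0.01)

    def test_uncovered_gene_rejected(self, tiny_counts, tiny_annotation):
        tiny_annotation.table.drop(index="G2", inplace=True)
        with pytest.raises(ValueError, match="G2"):
            rrna_fraction(tiny_counts, tiny_annotation)
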