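import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnbc_concord.data_model import ExpressionMatrix, PairedDesign
from tnbc_concord.subtyping import UNCLASSIFIED, SubtypeResult
from tnbc_concord.concordance import (
    accuracy_vs_confidence,
    clopper_pearson,
    compare_groups,
    concordance,
    min_confidence_for_accuracy,
    paired_expression_correlation,
)


def _result(sample_id, call, confidence=0.3, strength=0.5):
    return SubtypeResult(sample_id, {call: strength}, call, strength,
                         confidence, 100)


def cp_grid_oracle(k, n, level=0.95, step=1e-4):
    """Independent Clopper-Pearson oracle: invert the binomial tail sums
    by grid search over p."""
    alpha = 1 - level
    grid = np.arange(0.0, 1.0 + step, step)
    sf = stats.binom.sf(k - 1, n, grid)  # P(X >= k | p)
    cdf = stats.binom.cdf(k, n, grid)  # P(X <= k | p)
    low = 0.0 if k == 0 else grid[sf >= alpha / 2].min()
    high = 1.0 if k == n else grid[cdf >= alpha / 2].max()
    return low, high


class TestClopperPearson:
    def test_published_interval_to_three_decimals(self):
        low, high = clopper_pearson(89, 98, 0.95)
        assert round(low, 3) == 0.833
        assert round(high, 3) == 0.957

    def test_zero_successes_lower_bound_is_zero(self):
        low, high = clopper_pearson(0, 10, 0.95)
        assert low == 0.0
        assert high < 1.0

    def test_all_successes_upper_bound_is_one(self):
        low, high = clopper_pearson(10, 10, 0.95)
        assert high == 1.0

    @pytest.mark.parametrize("k,n", [(5, 10), (1, 7), (89, 98), (49, 50)])
    def test_matches_binomial_tail_inversion_oracle(self, k, n):
        low, high = clopper_pearson(k, n)
        o_low, o_high = cp_grid_oracle(k, n)
        assert low == pytest.approx(o_low, abs=2e-4)
        assert high == pytest.approx(o_high, abs=2e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)
        with pytest.raises(ValueError):
            clopper_pearson(5, 10, level=1.0)

    def test_exact_interval_coverage_is_conservative(self):
        """Empirical coverage over simulated binomials is at least the
        nominal 95% (the exact interval is conservative)."""
        rng = np.random.default_rng(42)
        for p in (0.1, 0.5, 0.9):
            for n in (10, 100):
                ks = rng.binomial(n, p, size=2000)
                covered = 0
                for k, count in zip(*np.unique(ks, return_counts=True)):
                    low, high = clopper_pearson(int(k), n)
                    covered += count * (low <= p <= high)
                assert covered / 2000 >= 0.95


class TestConcordance:
    def test_six_of_nine_pairs(self):
        design = PairedDesign(
            pd.DataFrame(
                {
                    "sample_a": [f"a{i}" for i in range(9)],
                    "sample_b": [f"b{i}" for i in range(9)],
                },
                index=pd.Index([f"P{i}" for i in range(9)], name="pair_id"),
            )
        )
        a = {f"a{i}": _result(f"a{i}", "BL1") for i in range(9)}
        b = {
            f"b{i}": _result(f"b{i}", "BL1" if i < 6 else "M")
            for i in range(9)
        }
        rep = concordance(a, b, design)
        assert rep.n_pairs_evaluable == 9
        assert rep.n_concordant == 6
        assert rep.rate == pytest.approx(6 / 9)

    def test_identical_results_rate_one_ci_high_one(self, simple_design):
        a = {s: _result(s, "M") for s in ["P1_FF", "P2_FF", "P3_FF"]}
        b = {s: _result(s, "M") for s in ["P1_FFPE", "P2_FFPE", "P3_FFPE"]}
        rep = concordance(a, b, simple_design)
        assert rep.rate == 1.0
        assert rep.ci_high == 1.0

    def test_unclassified_pairs_excluded_and_listed(self, simple_design):
        a = {s: _result(s, "M") for s in ["P1_FF", "P2_FF", "P3_FF"]}
        b = {
            "P1_FFPE": _result("P1_FFPE", "M"),
            "P2_FFPE": _result("P2_FFPE", UNCLASSIFIED),
            "P3_FFPE": _result("P3_FFPE", "M"),
        }
        rep = concordance(a, b, simple_design)
        assert rep.n_pairs_evaluable == 2
        assert rep.excluded_pairs[0][0] == "P2"

    def test_all_unclassified_raises_no_evaluable(self, simple_design):
        a = {s: _result(s, UNCLASSIFIED) for s in ["P1_FF", "P2_FF", "P3_FF"]}
        b = {s: _result(s, "M") for s in ["P1_FFPE", "P2_FFPE", "P3_FFPE"]}
        with pytest.raises(ValueError, match="no evaluable pairs"):
            concordance(a, b, simple_design)

    def test_missing_sample_names_pair(self, simple_design):
        a = {s: _result(s, "M") for s in ["P1_FF", "P2_FF"]}
        b = {s: _result(s, "M") for s in ["P1_FFPE", "P2_FFPE", "P3_FFPE"]}
        with pytest.raises(KeyError, match="P3"):
            concordance(a, b, simple_design)

    def test_symmetric_in_result_order(self, simple_design):
        a = {s: _result(s, "M") for s in ["P1_FF", "P2_FF", "P3_FF"]}
        b = {
            "P1_FFPE": _result("P1_FFPE", "M"),
            "P2_FFPE": _result("P2_FFPE", "BL1"),
            "P3_FFPE": _result("P3_FFPE", "M"),
        }
        swapped_design = PairedDesign(
            simple_design.table.rename(
                columns={"sample_a": "sample_b", "sample_b": "sample_a"}
            )
        )
        r1 = concordance(a, b, simple_design)
        r2 = concordance(b, a, swapped_design)
        assert (r1.n_concordant, r1.n_pairs_evaluable) == (
            r2.n_concordant, r2.n_pairs_evaluable
        )


class TestAccuracyVsConfidence:
    def _setup(self):
        design = PairedDesign(
            pd.DataFrame(
                {
                    "sample_a": [f"a{i}" for i in range(6)],
                    "sample_b": [f"b{i}" for i in range(6)],
                },
                index=pd.Index([f"P{i}" for i in range(6)], name="pair_id"),
            )
        )
        confs = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
        agree = [False, False, True, True, True, True]
        a = {f"a{i}": _result(f"a{i}", "M", confidence=confs[i])
             for i in range(6)}
        b = {
            f"b{i}": _result(
                f"b{i}", "M" if agree[i] else "BL1", confidence=confs[i]
            )
            for i in range(6)
        }
        return a, b, design

    def test_cutoff_zero_reproduces_overall_rate(self):
        a, b, design = self._setup()
        curve = accuracy_vs_confidence(a, b, design, cutoff_grid=[0.0])
        assert curve.accuracy[0] == pytest.approx(4 / 6)

    def test_pair_counts_non_increasing_and_accuracy_rises(self):
        a, b, design = self._setup()
        curve = accuracy_vs_confidence(
            a, b, design, cutoff_grid=np.arange(0, 0.6, 0.05)
        )
        assert np.all(np.diff(curve.n_pairs) <= 0)
        assert curve.accuracy[np.searchsorted(curve.cutoffs, 0.2)] == 1.0

    def test_cutoff_beyond_all_confidences_is_undefined_not_crash(self):
        a, b, design = self._setup()
        curve = accuracy_vs_confidence(a, b, design, cutoff_grid=[1.5])
        assert curve.n_pairs[0] == 0
        assert np.isnan(curve.accuracy[0])

    def test_empty_grid_rejected(self):
        a, b, design = self._setup()
        with pytest.raises(ValueError, match="empty"):
            accuracy_vs_confidence(a, b, design, cutoff_grid=[])

    def test_min_confidence_for_accuracy(self):
        a, b, design = self._setup()
        curve = accuracy_vs_confidence(
            a, b, design, cutoff_grid=np.arange(0, 0.31, 0.01)
        )
        cutoff = min_confidence_for_accuracy(curve, target=0.95, min_pairs=3)
        # accuracy reaches 1.0 once the two low-confidence discordant pairs
        # fall away; the first such grid point keeps >= 3 pairs
        assert cutoff is not None
        sel = np.searchsorted(curve.cutoffs, cutoff)
        assert curve.accuracy[sel] >= 0.95
        assert min_confidence_for_accuracy(curve, target=1.01) is None


class TestPairedCorrelation:
    def test_identical_columns_give_rho_one(self, simple_design):
        x = np.arange(20, dtype=float)
        data = {}
        for pid in ["P1", "P2", "P3"]:
            data[f"{pid}_FF"] = x
            data[f"{pid}_FFPE"] = x if pid != "P2" else x[::-1]
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=[f"G{i}" for i in range(20)]), "count"
        )
        rho = paired_expression_correlation(matrix, simple_design)
        assert rho["P1"] == pytest.approx(1.0)
        assert rho["P2"] == pytest.approx(-1.0)

    def test_zero_variance_member_reported_nan(self, simple_design):
        data = {
            "P1_FF": [1.0, 2.0, 3.0], "P1_FFPE": [5.0, 5.0, 5.0],
            "P2_FF": [1.0, 2.0, 3.0], "P2_FFPE": [1.0, 3.0, 2.0],
            "P3_FF": [1.0, 2.0, 3.0], "P3_FFPE": [3.0, 2.0, 1.0],
        }
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=["G1", "G2", "G3"]), "count"
        )
        with pytest.warns(UserWarning, match="P1"):
            rho = paired_expression_correlation(matrix, simple_design)
        assert np.isnan(rho["P1"])
        assert rho["P3"] == pytest.approx(-1.0)

    def test_too_few_shared_genes_rejected(self, simple_design):
        data = {c: [1.0, 2.0] for c in
                ["P1_FF", "P1_FFPE", "P2_FF", "P2_FFPE", "P3_FF", "P3_FFPE"]}
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=["G1", "G2"]), "count"
        )
        with pytest.raises(ValueError, match=">=3"):
            paired_expression_correlation(matrix, simple_design)


def mwu_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestCompareGroups:
    def test_derived_exact_p_for_separated_triples(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 rank splits are as extreme
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = compare_groups(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_ties_fall_back_to_asymptotic(self):
        res = compare_groups([1.0, 1.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "asymptotic"
        assert 0.0 < res.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_groups([], [1.0])
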