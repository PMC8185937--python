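import itertools

import numpy as np
import pytest
from scipy import stats as sps

from sorcna.cna_io import CaseSet, CnaCall
from sorcna.sor import build_sors
from sorcna.stats import (
    bh_adjust,
    compare_region,
    differential_scan,
    fisher_exact_2x2,
    roc_auc,
    wilcoxon_rank_sum,
)
from tests.conftest import make_clinical


class TestWilcoxonRankSum:
    def test_fully_separated_pairs(self):
        # all 6 rank assignments equally likely; only one is this extreme
        res = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact"

    def test_interleaved_pairs(self):
        # P(rank-sum of x <= 4) = 2/6 by enumeration
        res = wilcoxon_rank_sum([1, 3], [2, 4], alternative="less")
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_two_sided(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_constant_data_degenerate(self):
        res = wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_exact_and_asymptotic_branches_agree(self):
        """On tie-free data at combined n = 10 the two branches differ by
        at most 0.02."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            exact = wilcoxon_rank_sum(x, y)
            assert exact.method == "exact"
            approx = sps.mannwhitneyu(x, y, method="asymptotic",
                                      use_continuity=True)
            assert exact.p_value == pytest.approx(approx.pvalue, abs=0.02)


class TestFisherExact:
    def test_diagonal_2x2(self):
        # 3 tables share these margins; the two extreme ones have prob 1/6
        assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == 1.0

    def test_strong_diagonal(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [1, 2]])

    def test_conditional_distribution_sums_to_one(self):
        """Hypergeometric probabilities over all tables with the observed
        margins sum to 1 (enumeration check of the null distribution)."""
        row1, row2 = 6, 4
        col1 = 5
        n = row1 + row2
        total = sum(
            sps.hypergeom.pmf(k, n, row1, col1)
            for k in range(max(0, col1 - row2), min(row1, col1) + 1)
        )
        assert total == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 10, 11], [0, 0, 1, 1], bootstrap_reps=100)
        assert res.auc == 1.0

    def test_constant_scores(self):
        res = roc_auc([3, 3, 3, 3], [0, 1, 0, 1], bootstrap_reps=100)
        assert res.auc == 0.5

    def test_four_point_example(self):
        # positives score 2 and 4: 3 of 4 (pos, neg) pairs concordant
        res = roc_auc([1, 2, 3, 4], [0, 1, 0, 1], bootstrap_reps=100)
        assert res.auc == 0.75

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            scores = rng.integers(0, 6, size=12).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=12)
            if labels.sum() in (0, 12):
                continue
            res = roc_auc(scores, labels, bootstrap_reps=50)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            )
            assert res.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_ci_brackets_auc_and_is_seed_stable(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40) + np.repeat([0, 1], 20)
        labels = np.repeat([0, 1], 20)
        a = roc_auc(scores, labels, bootstrap_reps=500, seed=11)
        b = roc_auc(scores, labels, bootstrap_reps=500, seed=11)
        assert a == b
        assert a.ci_low <= a.auc <= a.ci_high


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_rule_by_hand(self):
        # 0.03*3/3, min over tail of 0.02*3/2 and 0.01*3/1 -> all 0.03
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCompareRegion:
    def _case_set(self, burdens):
        """Cases with a loss covering the given fraction of chr1:1-1000."""
        calls = []
        ids = []
        for i, frac in enumerate(burdens):
            cid = f"C{i}"
            ids.append(cid)
            if frac > 0:
                calls.append(CnaCall(cid, "chr1", 1, int(1000 * frac), "loss"))
        return CaseSet(calls=calls, clinical=make_clinical(ids))

    def test_all_zero_burdens_give_p_one(self):
        cs = self._case_set([0, 0, 0, 0])
        grouping = {"C0": "a", "C1": "a", "C2": "b", "C3": "b"}
        res = compare_region(cs, ("chr1", 1, 1000), "loss", grouping)
        assert res.p_value == 1.0

    def test_full_versus_empty_groups(self):
        cs = self._case_set([1.0, 0.9, 0, 0])
        grouping = {"C0": "a", "C1": "a", "C2": "b", "C3": "b"}
        res = compare_region(cs, ("chr1", 1, 1000), "loss", grouping,
                             alternative="greater", group_order=("a", "b"))
        assert res.p_value == pytest.approx(1 / 6)
        assert res.n_per_group == (2, 2)

    def test_requires_exactly_two_groups(self):
        cs = self._case_set([1.0, 0, 0])
        with pytest.raises(ValueError, match="two group"):
            compare_region(cs, ("chr1", 1, 1000), "loss",
                           {"C0": "a", "C1": "b", "C2": "c"})


class TestDifferentialScan:
    def test_single_segment_equals_compare_region(self):
        calls = [CnaCall("C0", "chr1", 1, 500, "loss"),
                 CnaCall("C1", "chr1", 1, 500, "loss")]
        cs = CaseSet(calls=calls, clinical=make_clinical(["C0", "C1", "C2", "C3"]))
        profile = build_sors(cs, "loss")
        grouping = {"C0": "a", "C1": "a", "C2": "b", "C3": "b"}
        table = differential_scan(cs, profile, grouping)
        assert len(table) == 1
        direct = compare_region(cs, ("chr1", 1, 500), "loss", grouping)
        assert table.loc[0, "p_value"] == direct.p_value
        assert table.loc[0, "statistic"] == direct.statistic

    def test_adjusted_column_present_and_monotone(self):
        rng = np.random.default_rng(2)
        calls = []
        ids = [f"C{i}" for i in range(10)]
        for cid in ids:
            if rng.random() < 0.7:
                s = int(rng.integers(1, 800))
                calls.append(CnaCall(cid, "chr1", s, s + 150, "loss"))
        cs = CaseSet(calls=calls, clinical=make_clinical(ids))
        profile = build_sors(cs, "loss")
        grouping = {cid: ("a" if i < 5 else "b") for i, cid in enumerate(ids)}
        table = differential_scan(cs, profile, grouping, adjust=True)
        assert (table["p_adj"] >= table["p_value"] - 1e-12).all()
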