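"""Trial partitioning and the statistical battery, cross-checked against
exact enumeration and scipy."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sstats

import plvnet


class TestPartitionTerciles:
    def test_57_trials_gives_19_per_extreme_group(self):
        rng = np.random.default_rng(0)
        labels = plvnet.partition_terciles(rng.uniform(200, 500, 57))
        assert labels.mask("fast").sum() == 19
        assert labels.mask("slow").sum() == 19
        assert labels.mask("early").sum() == 19
        assert labels.mask("late").sum() == 19

    def test_six_trials_ranked(self):
        labels = plvnet.partition_terciles(np.array([1.0, 2, 3, 4, 5, 6]))
        np.testing.assert_array_equal(labels.mask("fast"), [1, 1, 0, 0, 0, 0])
        np.testing.assert_array_equal(labels.mask("slow"), [0, 0, 0, 0, 1, 1])

    def test_all_tied_resolved_chronologically(self):
        labels = plvnet.partition_terciles(np.full(9, 300.0))
        np.testing.assert_array_equal(labels.mask("fast"), [1, 1, 1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(labels.mask("slow"), [0, 0, 0, 0, 0, 0, 1, 1, 1])

    def test_order_invariance_up_to_tie_rule(self):
        rng = np.random.default_rng(1)
        rts = rng.uniform(200, 500, 30)  # distinct values
        perm = rng.permutation(30)
        direct = plvnet.partition_terciles(rts)
        shuffled = plvnet.partition_terciles(rts[perm])
        np.testing.assert_array_equal(direct.performance_class[perm], shuffled.performance_class)

    def test_order_class_is_chronological(self):
        labels = plvnet.partition_terciles(np.array([6.0, 5, 4, 3, 2, 1]))
        np.testing.assert_array_equal(labels.mask("early"), [1, 1, 0, 0, 0, 0])
        np.testing.assert_array_equal(labels.mask("late"), [0, 0, 0, 0, 1, 1])

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            plvnet.partition_terciles(np.arange(5.0))


def exact_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2.0
    stats = np.array([ranks[list(c)].sum() for c in combinations(range(len(combined)), n1)])
    return np.mean(np.abs(stats - mu) >= abs(observed - mu) - 1e-12)


class TestRankSum:
    def test_identical_samples(self):
        x = np.array([1.0, 2, 3, 4])
        r = plvnet.rank_sum(x, x)
        assert r.statistic == 0.0
        assert r.p_value >= 0.95

    def test_separated_small_samples_vs_exact(self):
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        assert exact_rank_sum_p(x, y) == pytest.approx(0.1)
        r = plvnet.rank_sum(x, y)
        assert abs(r.p_value - 0.1) < 0.05
        assert r.statistic < 0  # x ranks below y

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1 = rng.integers(3, 6)
        n2 = rng.integers(3, 11 - n1)
        x = rng.normal(0, 1, n1).round(1)  # rounding induces occasional ties
        y = rng.normal(0.5, 1, n2).round(1)
        r = plvnet.rank_sum(x, y)
        assert abs(r.p_value - exact_rank_sum_p(x, y)) < 0.05

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 20), rng.normal(0.6, 1, 25)
        r = plvnet.rank_sum(x, y, sided="two")
        _, p = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_one_sided_monotone_in_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        ps = [plvnet.rank_sum(x, y + shift, sided="less").p_value for shift in (0.0, 1.0, 3.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_or_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            plvnet.rank_sum(np.array([1.0]), np.array([1.0, 2, 3]))


class TestNodalContrast:
    def test_identical_groups_zero_t(self):
        feats = np.tile(np.array([1.0, 2, 3, 1, 2, 3])[:, None], (1, 4))
        res = plvnet.nodal_contrast_t(feats, np.arange(3), np.arange(3, 6))
        np.testing.assert_allclose(res.table["t"], 0.0)

    def test_welch_hand_example(self):
        feats = np.array([1.0, 2, 3, 4, 5, 6])[:, None]
        res = plvnet.nodal_contrast_t(feats, np.arange(3), np.arange(3, 6))
        assert res.table.loc[0, "t"] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert res.table.loc[0, "df"] == pytest.approx(4.0)

    def test_zero_variance_both_groups(self, caplog):
        feats = np.ones((6, 2))
        with caplog.at_level("WARNING"):
            res = plvnet.nodal_contrast_t(feats, np.arange(3), np.arange(3, 6))
        np.testing.assert_array_equal(res.table["p"], 1.0)

    def test_detection_count_grows_with_effect_size(self):
        """More channels cross the t-threshold as the group effect grows."""
        counts = []
        for effect in (0.0, 1.0, 3.0):
            n_detected = 0
            for seed in range(20):
                rng = np.random.default_rng(seed)
                feats = rng.normal(0, 1, size=(30, 8))
                feats[:15] += effect
                res = plvnet.nodal_contrast_t(feats, np.arange(15), np.arange(15, 30))
                n_detected += int((res.table["p"] < 0.05).sum())
            counts.append(n_detected)
        assert counts[0] < counts[1] < counts[2]

    def test_max_channel_identified(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(0, 1, size=(40, 5))
        feats[:20, 3] += 2.5
        res = plvnet.nodal_contrast_t(feats, np.arange(20), np.arange(20, 40))
        assert res.max_channel == 3
        single = res.result(3)
        assert single.p_value < 0.001


class TestCorrelateRt:
    def test_perfect_correlations(self):
        rts = np.array([300.0, 320, 250, 400, 380])
        assert plvnet.correlate_rt(rts, rts).statistic == pytest.approx(1.0)
        assert plvnet.correlate_rt(-rts + 500, rts).statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = np.array([0.0, 2, 1, 3, 4])
        r = plvnet.correlate_rt(x, y)
        assert r.statistic == pytest.approx(0.9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            plvnet.correlate_rt(np.ones(5), np.arange(5.0))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 10, 0.001)]
    )
    def test_threshold(self, alpha, m, expected):
        assert plvnet.bonferroni(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            plvnet.bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            plvnet.bonferroni(1.5, 4)
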