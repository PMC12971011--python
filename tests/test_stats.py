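import numpy as np
import pytest
from scipy import stats as sps

from dwiaspects.stats import (StatsError, delong_test, dice, group_compare,
                              icc_absolute_agreement, icc_mean_squares,
                              roc_youden, spearman_ci)
from dwiaspects.volume_io import LabeledVolume


class TestDice:
    def test_identical_nonempty(self, rng):
        m = (rng.random((10, 10, 10)) < 0.4).astype(np.uint8)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), np.uint8)
        b = np.zeros((10, 10, 10), np.uint8)
        a.ravel()[:100] = 1
        b.ravel()[50:150] = 1
        assert dice(a, b) == 0.5

    def test_both_empty_defined_one(self):
        z = np.zeros((4, 4, 4), np.uint8)
        assert dice(z, z) == 1.0

    def test_symmetry(self, rng):
        a = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch(self):
        a = LabeledVolume(np.zeros((4, 4, 4), np.uint8), np.eye(4))
        b = LabeledVolume(np.zeros((4, 4, 4), np.uint8),
                          np.diag([2.0, 1, 1, 1]))
        with pytest.raises(StatsError):
            dice(a, b)


class TestSpearman:
    def test_perfect_and_inverse(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman_ci(x, x)[0] == pytest.approx(1.0, abs=1e-12)
        assert spearman_ci(x, x[::-1])[0] == pytest.approx(-1.0, abs=1e-12)

    def test_worked_five_point_example(self):
        """Hand rank computation: d = (-2,1,1,0,0), r = 1-6*6/(5*24) = 0.7."""
        r, ci = spearman_ci([1, 2, 3, 4, 5], [3, 1, 2, 4, 5])
        assert r == pytest.approx(0.7)
        assert ci[0] <= r <= ci[1]

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        r1, _ = spearman_ci(x, y)
        r2, _ = spearman_ci(np.exp(3 * x), y ** 3 + 5 * y)
        assert r1 == pytest.approx(r2)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestICC:
    def test_duplicated_columns_unity(self):
        col = np.array([3.0, 5, 7, 9, 11, 4, 8])
        icc, ci = icc_absolute_agreement(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0, abs=1e-9)

    def test_offset_penalised_by_absolute_agreement(self, rng):
        col = rng.normal(0, 5, size=10)
        table = np.column_stack([col, col + 10.0])
        absolute, _ = icc_absolute_agreement(table)
        consistency, _ = icc_absolute_agreement(table, form="consistency")
        assert absolute < consistency - 0.2

    def test_independent_columns_near_zero(self, rng):
        table = rng.normal(size=(50, 2))
        icc, _ = icc_absolute_agreement(table)
        assert -0.3 < icc < 0.3

    def test_matches_mean_squares_formula(self, rng):
        """pingouin-backed estimate equals the textbook decomposition."""
        table = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        icc, _ = icc_absolute_agreement(table)
        assert icc == pytest.approx(icc_mean_squares(table), abs=1e-9)

    def test_variance_component_recovery(self):
        """Two-way random-effects simulation: ICC(2,1) estimates
        sigma_s^2 / (sigma_s^2 + sigma_r^2 + sigma_e^2).

        With only 3 sampled raters the ratio estimator carries a known
        upward skew (the rater mean square has 2 df), so the small-k check
        uses a correspondingly wide band and a larger-k design confirms
        convergence to the analytic value.
        """
        rng = np.random.default_rng(42)
        s2_s, s2_r, s2_e = 4.0, 1.0, 1.0
        want = s2_s / (s2_s + s2_r + s2_e)
        estimates = []
        for _ in range(20):
            subj = rng.normal(0, np.sqrt(s2_s), size=(200, 1))
            rater = rng.normal(0, np.sqrt(s2_r), size=(1, 3))
            err = rng.normal(0, np.sqrt(s2_e), size=(200, 3))
            estimates.append(icc_mean_squares(subj + rater + err))
        assert np.mean(estimates) == pytest.approx(want, abs=0.12)

        large_k = []
        for _ in range(10):
            subj = rng.normal(0, np.sqrt(s2_s), size=(400, 1))
            rater = rng.normal(0, np.sqrt(s2_r), size=(1, 25))
            err = rng.normal(0, np.sqrt(s2_e), size=(400, 25))
            large_k.append(icc_mean_squares(subj + rater + err))
        assert np.mean(large_k) == pytest.approx(want, abs=0.03)

    def test_too_few_subjects(self):
        with pytest.raises(StatsError):
            icc_absolute_agreement(np.zeros((3, 2)))


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                         direction="high")
        assert res.auc == 1.0
        assert 3 < res.threshold <= 10
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_four_point_hand_enumeration(self):
        res = roc_youden([1, 2, 3, 4], [0, 0, 1, 1], direction="high")
        assert res.auc == 1.0
        assert res.threshold == pytest.approx(3.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.accuracy == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = roc_youden(scores, labels)
        assert 0.45 < res.auc < 0.55

    def test_auc_equals_mann_whitney(self, rng):
        """Trapezoid AUC == normalised Mann-Whitney U, exactly."""
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = roc_youden(scores, labels, direction="high")
            u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                 alternative="two-sided").statistic
            auc_mw = u / (np.sum(labels == 1) * np.sum(labels == 0))
            assert res.auc == pytest.approx(auc_mw, abs=1e-12)

    def test_direction_flip_mirrors_auc(self):
        scores = [10, 9, 8, 3, 2, 1.0]
        labels = [1, 1, 1, 0, 0, 0]
        hi = roc_youden(scores, labels, direction="high")
        lo = roc_youden(scores, labels, direction="low")
        assert lo.auc == pytest.approx(1.0 - hi.auc)

    def test_low_direction_threshold_is_inclusive_upper_bound(self):
        # ASPECTS-style marker: low scores flag the positive class
        scores = [2, 3, 5, 6, 8, 9, 9, 10.0]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        res = roc_youden(scores, labels, direction="low")
        assert res.auc == 1.0
        assert 6 <= res.threshold < 8
        pred_pos = np.asarray(scores) <= res.threshold
        assert pred_pos.tolist() == [bool(l) for l in labels]

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_youden([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        auc_a, auc_b, p = delong_test(scores, scores, labels)
        assert auc_a == auc_b
        assert p == 1.0

    def test_monotone_transform_p_one(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = [0, 0, 1, 1, 1, 0]
        _, _, p = delong_test(scores, np.exp(scores * 4), labels)
        assert p == 1.0

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=400)
        good = labels * 2.0 + rng.normal(size=400)
        junk = rng.normal(size=400)
        auc_a, auc_b, p = delong_test(good, junk, labels)
        assert auc_a > 0.85 and abs(auc_b - 0.5) < 0.15
        assert p < 1e-6

    def test_type_one_error_near_nominal(self):
        """Two noisy versions of the same signal: reject rate ~ alpha."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(200):
            labels = np.concatenate([np.zeros(250, int), np.ones(250, int)])
            signal = labels * 1.0 + rng.normal(size=500)
            a = signal + rng.normal(size=500)
            b = signal + rng.normal(size=500)
            _, _, p = delong_test(a, b, labels)
            rejections += p < 0.05
        assert 0.02 < rejections / 200 < 0.09

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(StatsError):
            delong_test([1, 2, 3], [1, 2], [0, 1, 1])


class TestGroupCompare:
    def test_identical_samples_mann_whitney(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        test, _, p = group_compare(vals, groups, "continuous")
        assert test == "mann-whitney"
        assert p > 0.9

    def test_chi_square_on_large_table(self):
        """(100,50;50,100): chi2 = 300*(100*100-50*50)^2/(150^4) = 33.33."""
        vals = np.array([0] * 100 + [1] * 50 + [0] * 50 + [1] * 100)
        groups = np.array(["a"] * 150 + ["b"] * 150)
        test, stat, p = group_compare(vals, groups, "categorical")
        assert test == "chi-square"
        assert stat == pytest.approx(33.3333, abs=1e-3)
        assert p < 0.001

    def test_fisher_fires_on_small_counts(self):
        """Every cell below 10 -> Fisher's exact test."""
        vals = np.array([0] * 3 + [1] * 5 + [0] * 4 + [1] * 2)
        groups = np.array(["a"] * 8 + ["b"] * 6)
        test, _, _ = group_compare(vals, groups, "categorical")
        assert test == "fisher"

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            group_compare([1, 2], ["a", "a"], "continuous")
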