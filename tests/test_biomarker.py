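import numpy as np
import pytest

import metabokit as mk
from metabokit.biomarker import pair_count_auc
from metabokit.core_data import DataTableError


def bruteforce_auc(scores, y):
    """Pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, yy in zip(scores, y) if yy == 1]
    neg = [s for s, yy in zip(scores, y) if yy == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def trapezoid_area(curve):
    x = curve.one_minus_specificity
    y = curve.sensitivity
    return float(np.trapezoid(y, x))


class TestRocCurve:
    def test_pair_count_example(self):
        scores = [3, 5, 7, 1, 2, 6]
        labels = ["pos"] * 3 + ["neg"] * 3
        curve = mk.roc_curve(scores, labels, positive="pos")
        assert curve.auc == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        curve = mk.roc_curve([10, 11, 12, 1, 2, 3],
                             ["p"] * 3 + ["n"] * 3, positive="p")
        assert curve.auc == 1.0

    def test_all_ties_half(self):
        curve = mk.roc_curve([5.0] * 6, ["p"] * 3 + ["n"] * 3, positive="p")
        assert curve.auc == 0.5

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = ["p"] * 20 + ["n"] * 20
        curve = mk.roc_curve(scores, labels, positive="p")
        assert curve.sensitivity[0] == 0 and curve.one_minus_specificity[0] == 0
        assert curve.sensitivity[-1] == 1 and curve.one_minus_specificity[-1] == 1
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.one_minus_specificity) >= 0).all()

    def test_trapezoid_equals_pair_counting(self):
        """On 1000 random score vectors (with ties), the trapezoidal area
        of the reported curve equals the pair-counting AUC within 1e-10."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 10, size=n).astype(float)  # force ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            curve = mk.roc_curve(scores, y, positive=1, flip=False)
            assert abs(trapezoid_area(curve) - curve.auc) < 1e-10
            assert curve.auc == pytest.approx(bruteforce_auc(scores, y),
                                              abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        a1 = mk.roc_curve(scores, y, positive=1).auc
        a2 = mk.roc_curve(np.exp(scores), y, positive=1).auc
        assert a1 == pytest.approx(a2)

    def test_negation_complement(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 6, size=30).astype(float)
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        a = pair_count_auc(scores, y)
        b = pair_count_auc(-scores, y)
        assert a + b == pytest.approx(1.0)

    def test_flip_logged_never_silent(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["p"] * 3 + ["n"] * 3
        curve = mk.roc_curve(scores, labels, positive="p")
        assert curve.direction["flipped"]
        assert curve.auc == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(DataTableError):
            mk.roc_curve([1, 2, 3], ["p", "p", "p"], positive="p")


class TestAucCi:
    def test_perfect_separation_upper_bound_one(self):
        scores = np.r_[np.arange(10) + 100, np.arange(10)]
        labels = ["p"] * 10 + ["n"] * 10
        lo, hi = mk.auc_ci(scores, labels, positive="p", seed=0)
        assert hi == 1.0
        assert lo <= 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        labels = ["p"] * 50 + ["n"] * 50
        auc = mk.roc_curve(scores, labels, positive="p").auc
        lo, hi = mk.auc_ci(scores, labels, positive="p", seed=1)
        assert 0 <= lo <= auc <= hi <= 1

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(7)
        widths = []
        for n in (20, 200):
            scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            labels = ["p"] * n + ["n"] * n
            lo, hi = mk.auc_ci(scores, labels, positive="p", seed=2)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 20)]
        labels = ["p"] * 20 + ["n"] * 20
        assert mk.auc_ci(scores, labels, positive="p", seed=5) == \
            mk.auc_ci(scores, labels, positive="p", seed=5)


class TestPartialAuc:
    def _curve(self, seed=9):
        rng = np.random.default_rng(seed)
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        return mk.roc_curve(scores, y, positive=1)

    def test_full_range_equals_auc(self):
        curve = self._curve()
        assert mk.partial_auc(curve, 0, 1) == pytest.approx(curve.auc,
                                                            abs=1e-10)

    def test_diagonal_geometry(self):
        # random-guess diagonal: two points (0,0) and (1,1)
        diag = mk.RocCurve(thresholds=np.array([np.inf, -np.inf]),
                           sensitivity=np.array([0.0, 1.0]),
                           one_minus_specificity=np.array([0.0, 1.0]),
                           auc=0.5)
        assert mk.partial_auc(diag, 0, 0.5) == pytest.approx(0.125)
        assert mk.partial_auc(diag, 0, 0.5, standardized=True) == \
            pytest.approx(0.25)

    def test_perfect_curve_standardized_one(self):
        perfect = mk.RocCurve(thresholds=np.array([np.inf, 5.0, -np.inf]),
                              sensitivity=np.array([0.0, 1.0, 1.0]),
                              one_minus_specificity=np.array([0.0, 0.0, 1.0]),
                              auc=1.0)
        for lo, hi in ((0, 1), (0.2, 0.7), (0.9, 1.0)):
            assert mk.partial_auc(perfect, lo, hi, standardized=True) == \
                pytest.approx(1.0)

    def test_invalid_range(self):
        with pytest.raises(DataTableError):
            mk.partial_auc(self._curve(), 0.5, 0.5)


class TestOptimalCutoff:
    def test_perfect_separation(self):
        curve = mk.roc_curve([10, 11, 12, 1, 2, 3],
                             ["p"] * 3 + ["n"] * 3, positive="p")
        cut = mk.optimal_cutoff(curve)
        assert cut["sensitivity"] == 1.0 and cut["specificity"] == 1.0
        assert 3 < cut["threshold"] <= 10

    def test_youden_matches_exhaustive_scan(self):
        scores = np.array([3, 5, 7, 1, 2, 6], dtype=float)
        labels = ["pos"] * 3 + ["neg"] * 3
        curve = mk.roc_curve(scores, labels, positive="pos")
        cut = mk.optimal_cutoff(curve, criterion="youden")
        # scan every threshold by brute force
        best_j, best = -1.0, None
        for t in sorted(set(scores), reverse=True):
            sens = np.mean([s >= t for s, l in zip(scores, labels)
                            if l == "pos"])
            spec = np.mean([s < t for s, l in zip(scores, labels)
                            if l == "neg"])
            j = sens + spec - 1
            if j > best_j:
                best_j, best = j, (sens, spec)
        assert cut["sensitivity"] + cut["specificity"] - 1 == \
            pytest.approx(best_j)

    def test_all_ties_degenerate(self):
        curve = mk.roc_curve([5.0] * 6, ["p"] * 3 + ["n"] * 3, positive="p")
        cut = mk.optimal_cutoff(curve)
        assert cut["degenerate"]


class TestMccvExplore:
    def test_null_calibration(self, null_table):
        """Labels independent of data: mean held-out AUC stays near 0.5."""
        results = mk.mccv_explore(null_table, "B", feature_counts=[2, 5, 10],
                                  n_iter=50, seed=100)
        for r in results:
            assert 0.4 <= r.auc <= 0.6, r.n_features_used

    def test_planted_signal_detected(self, signal_table):
        results = mk.mccv_explore(signal_table, "B",
                                  feature_counts=[2, 3, 5, 10],
                                  n_iter=50, seed=101)
        best = max(r.auc for r in results)
        assert best > 0.9
        by_k = {r.n_features_used: r for r in results}
        informative = [f"M{j + 1:04d}" for j in range(5)]
        freqs = by_k[5].selection_frequency
        for f in informative:
            assert freqs.get(f, 0.0) > 0.8, f

    def test_seed_determinism(self, signal_table):
        r1 = mk.mccv_explore(signal_table, "B", feature_counts=[3],
                             n_iter=10, seed=7)
        r2 = mk.mccv_explore(signal_table, "B", feature_counts=[3],
                             n_iter=10, seed=7)
        assert r1[0].per_iteration_auc == r2[0].per_iteration_auc
        assert r1[0].selection_frequency == r2[0].selection_frequency
        np.testing.assert_array_equal(r1[0].mean_curve.sensitivity,
                                      r2[0].mean_curve.sensitivity)

    def test_no_test_split_leakage(self, signal_table):
        """Feature ranking uses the training split only: shuffling labels
        inside the test third leaves the ranking unchanged."""
        from metabokit.biomarker import _stratified_split, _welch_t_abs
        x = signal_table.values.to_numpy()
        y = (signal_table.group == "B").to_numpy().astype(int)
        rng = np.random.default_rng(0)
        train, test = _stratified_split(y, rng)
        rank_before = np.argsort(-_welch_t_abs(x[train], y[train]))
        y_shuffled = y.copy()
        y_shuffled[test] = np.random.default_rng(1).permutation(y[test])
        rank_after = np.argsort(-_welch_t_abs(x[train], y_shuffled[train]))
        np.testing.assert_array_equal(rank_before, rank_after)

    def test_ci_bounds_contain_mean(self, signal_table):
        [r] = mk.mccv_explore(signal_table, "B", feature_counts=[5],
                              n_iter=30, seed=8)
        lo, hi = r.auc_ci
        assert 0 <= lo <= r.auc <= hi <= 1

    def test_small_class_rejected(self, clean_table):
        with pytest.raises(DataTableError):
            mk.mccv_explore(clean_table, "B", n_iter=3, seed=0)

    @pytest.mark.parametrize("classifier", ["linear_svm", "random_forest"])
    def test_other_classifiers_detect_signal(self, signal_table, classifier):
        [r] = mk.mccv_explore(signal_table, "B", classifier=classifier,
                              feature_counts=[5], n_iter=15, seed=9)
        assert r.auc > 0.9


class TestEvaluateModel:
    def test_empty_holdout_reduces_to_mccv(self, signal_table):
        feats = ["M0001", "M0002", "M0003"]
        res = mk.evaluate_model(signal_table, "B", feats, n_iter=10, seed=3)
        [direct] = mk.mccv_explore(
            mk.DataTable(values=signal_table.values[feats],
                         group=signal_table.group),
            "B", feature_counts=[3], n_iter=10, seed=3)
        assert res.per_iteration_auc == direct.per_iteration_auc

    def test_holdout_auc_on_strong_signal(self, signal_table):
        holdout = ["A1", "A2", "A3", "B1", "B2", "B3"]
        res = mk.evaluate_model(signal_table, "B",
                                ["M0001", "M0002", "M0003"],
                                holdout_ids=holdout, n_iter=10, seed=4)
        assert res.holdout_curve is not None
        assert res.holdout_curve.auc > 0.85

    def test_single_marker_consistent_with_univariate_roc(self, signal_table):
        feat = "M0001"
        res = mk.evaluate_model(signal_table, "B", [feat], n_iter=40, seed=5)
        direct = mk.roc_curve(signal_table.values[feat],
                              signal_table.group.tolist(), positive="B",
                              flip=False)
        lo, hi = res.auc_ci
        assert lo - 0.05 <= direct.auc <= hi + 0.05

    def test_holdout_whole_class_rejected(self, signal_table):
        holdout = [s for s in signal_table.sample_ids if s.startswith("B")]
        with pytest.raises(DataTableError):
            mk.evaluate_model(signal_table, "B", ["M0001"],
                              holdout_ids=holdout, n_iter=5, seed=6)


class TestPermutationTest:
    def test_minimum_p_bound(self, signal_table):
        p = mk.permutation_test(signal_table, "B",
                                ["M0001", "M0002", "M0003"],
                                n_perm=19, n_iter=5, seed=11)
        assert p >= 1 / 20
        assert p == pytest.approx(1 / 20)   # strong signal: no perm wins

    def test_null_p_not_extreme(self, null_table):
        p = mk.permutation_test(null_table, "B", ["M0001", "M0002"],
                                n_perm=19, n_iter=5, seed=12)
        assert p > 0.05

    def test_too_few_permutations_rejected(self, signal_table):
        with pytest.raises(DataTableError):
            mk.permutation_test(signal_table, "B", ["M0001"], n_perm=5,
                                n_iter=5, seed=0)
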