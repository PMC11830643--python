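import itertools
from math import comb

import numpy as np
import pytest

import valvemorph as vm
from valvemorph.disparity import IncomparableCurvesError, RarefactionCurve

# 8-value fixture with tied values, chosen so the subsample-statistic
# distribution at every n has its 0.5 quantile strictly inside an atom:
# the Monte-Carlo median then coincides with the exhaustive median instead
# of wobbling between adjacent order statistics.
ORACLE_VALUES = np.array([0.0, 0.0, 0.0, 0.0, 2.0, 3.0, 4.0, 4.0])


def exhaustive_median(values, n, metric):
    stats = [np.var(c, ddof=1) if metric == "variance" else max(c) - min(c)
             for c in itertools.combinations(values, n)]
    return float(np.median(stats))


def make_curve(n_grid, lo, med, hi, metric="variance", variable="pSV",
               group="g"):
    n_grid = np.asarray(n_grid)
    return RarefactionCurve(group=group, metric=metric, variable=variable,
                            n_grid=n_grid, median=np.asarray(med, float),
                            ci_low=np.asarray(lo, float),
                            ci_high=np.asarray(hi, float),
                            mean=np.asarray(med, float), reps=100, seed=0)


class TestRarefy:
    def test_constant_vector_gives_zero_curve(self):
        curve = vm.rarefy(np.full(10, 3.0), "variance", n_min=2, reps=200,
                          seed=1)
        assert np.all(curve.median == 0)
        assert np.all(curve.ci_low == 0) and np.all(curve.ci_high == 0)

    def test_full_sample_point_is_exact(self):
        values = np.array([0.0, 1.0, 2.0, 3.0])
        var_curve = vm.rarefy(values, "variance", n_min=2, reps=50, seed=0)
        rng_curve = vm.rarefy(values, "range", n_min=2, reps=50, seed=0)
        # at n = N the subsample is the full set: variance 5/3, range 3
        for curve, expected in ((var_curve, 5 / 3), (rng_curve, 3.0)):
            assert curve.median[-1] == pytest.approx(expected)
            assert curve.ci_low[-1] == curve.ci_high[-1] == curve.median[-1]

    @pytest.mark.parametrize("metric", ["variance", "range"])
    def test_monte_carlo_matches_exhaustive_enumeration(self, metric):
        curve = vm.rarefy(ORACLE_VALUES, metric, n_min=2, reps=10000, seed=7)
        for i, n in enumerate(curve.n_grid):
            exact = exhaustive_median(ORACLE_VALUES, int(n), metric)
            assert curve.median[i] == pytest.approx(exact, rel=0.02), \
                f"n = {n}"

    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        a = vm.rarefy(values, "variance", reps=500, seed=99)
        b = vm.rarefy(values, "variance", reps=500, seed=99)
        np.testing.assert_array_equal(a.median, b.median)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_envelope_brackets_median_everywhere(self):
        rng = np.random.default_rng(4)
        curve = vm.rarefy(rng.exponential(size=40), "range", reps=300, seed=2)
        assert np.all(curve.ci_low <= curve.median)
        assert np.all(curve.median <= curve.ci_high)

    def test_range_median_nondecreasing(self):
        rng = np.random.default_rng(5)
        curve = vm.rarefy(rng.normal(size=35), "range", reps=1000, seed=6)
        assert np.all(np.diff(curve.median) >= 0)

    def test_variance_mean_unbiased(self):
        """Sampling without replacement keeps the (n-1)-denominator sample
        variance unbiased for the group's full variance at every n."""
        rng = np.random.default_rng(8)
        values = rng.normal(size=60)
        full = values.var(ddof=1)
        curve = vm.rarefy(values, "variance", reps=2000, seed=10)
        for i in range(len(curve.n_grid) - 1):
            spread = (curve.ci_high[i] - curve.ci_low[i]) / 3.92
            se = spread / np.sqrt(curve.reps)
            assert abs(curve.mean[i] - full) < 4 * se + 1e-12

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert vm.rarefy(np.arange(3.0), "variance", n_min=5) is None


class TestDivergenceThreshold:
    def test_identical_curves_never_diverge(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        curve = vm.rarefy(values, "variance", reps=300, seed=5)
        assert vm.divergence_threshold(curve, curve) is None

    def test_separated_envelopes_from_smallest_n(self):
        a = make_curve([5, 6, 7], lo=[0, 0, 0], med=[1, 1, 1], hi=[2, 2, 2])
        b = make_curve([5, 6, 7], lo=[3, 3, 3], med=[4, 4, 4], hi=[5, 5, 5])
        assert vm.divergence_threshold(a, b) == 5

    def test_unequal_variances_detected_and_persistent(self):
        rng = np.random.default_rng(2)
        a = vm.rarefy(rng.normal(0, 1, 60), "variance", reps=1000, seed=3,
                      group="a", variable="x")
        b = vm.rarefy(rng.normal(0, 5, 60), "variance", reps=1000, seed=4,
                      group="b", variable="x")
        threshold = vm.divergence_threshold(a, b)
        assert threshold is not None
        # oracle: direct scan over the stored envelopes
        disjoint = (a.ci_high < b.ci_low) | (b.ci_high < a.ci_low)
        expected = None
        for i in range(len(disjoint)):
            if disjoint[i:].all():
                expected = int(a.n_grid[i])
                break
        assert threshold == expected

    def test_sporadic_crossing_not_a_threshold(self):
        a = make_curve([5, 6, 7, 8], lo=[0] * 4, med=[1] * 4, hi=[2] * 4)
        b = make_curve([5, 6, 7, 8], lo=[3, 1, 3, 3], med=[4] * 4,
                       hi=[5] * 4)
        # envelopes touch at n = 6, so persistence starts at 7
        assert vm.divergence_threshold(a, b) == 7

    def test_mismatched_curves_rejected(self):
        a = make_curve([5, 6], [0, 0], [1, 1], [2, 2], variable="pSV")
        b = make_curve([5, 6], [0, 0], [1, 1], [2, 2], variable="XS")
        with pytest.raises(IncomparableCurvesError):
            vm.divergence_threshold(a, b)
        c = make_curve([10, 11], [0, 0], [1, 1], [2, 2])
        with pytest.raises(IncomparableCurvesError):
            vm.divergence_threshold(make_curve([5, 6], [0, 0], [1, 1],
                                               [2, 2]), c)


class TestRangeStabilization:
    def test_constant_data_stabilizes_immediately(self):
        curve = vm.rarefy(np.full(12, 2.0), "range", n_min=5, reps=100,
                          seed=0)
        assert vm.range_stabilization(curve) == 5

    def test_single_outlier_delays_stabilization(self):
        """The full range needs the outlier in the subsample; its inclusion
        probability is n/N, so the median range only reaches the full range
        once n exceeds about half the group size."""
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 1, 49), [60.0]])
        curve = vm.rarefy(values, "range", n_min=5, reps=2000, seed=7)
        assert vm.range_stabilization(curve) > 25

    def test_uniform_grid_matches_exact_distribution(self):
        """For an even grid the exact median-range distribution is closed
        form: P(range = v_j - v_i) = C(j-i-1, n-2) / C(N, n)."""
        N = 20
        values = np.arange(float(N))
        full = values.max() - values.min()

        def exact_median(n):
            acc, tot = 0.0, comb(N, n)
            for span in sorted({j - i for i in range(N)
                                for j in range(i + n - 1, N)}):
                weight = (N - span) * comb(span - 1, n - 2) / tot
                acc += weight
                if acc >= 0.5:
                    return float(span)
            return full

        target = 0.99 * full
        medians = {n: exact_median(n) for n in range(2, N + 1)}
        exact_n = min(n for n in medians
                      if all(medians[m] >= target for m in medians
                             if m >= n))
        curve = vm.rarefy(values, "range", n_min=2, reps=3000, seed=3)
        got = vm.range_stabilization(curve)
        assert got < N
        assert abs(got - exact_n) <= 1
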