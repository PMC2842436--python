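import math

import numpy as np
import pytest

from mixedclr import (
    ExpressionDataset,
    bspline_weight_matrix,
    build_dynamic_pairs,
    dynamic_mi_matrix,
    mi_from_weights,
    static_mi_matrix,
)


def cox_de_boor(x, i, degree, knots):
    """Textbook B-spline basis recursion, independent of scipy."""
    if degree == 0:
        last = knots[-1]
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        # right-closed last interval so x == domain end is covered
        if x == last and knots[i] < last and knots[i + 1] == last:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) * cox_de_boor(x, i, degree - 1, knots)
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (
            (knots[i + degree + 1] - x)
            / (knots[i + degree + 1] - knots[i + 1])
            * cox_de_boor(x, i + 1, degree - 1, knots)
        )
    return left + right


def weights_oracle(values, bins, order):
    values = np.asarray(values, float)
    degree = order - 1
    domain = bins - degree
    knots = np.concatenate(
        [np.zeros(degree + 1), np.arange(1.0, domain), np.full(degree + 1, float(domain))]
    )
    vmin, vmax = values.min(), values.max()
    z = (values - vmin) / (vmax - vmin) * domain if vmax > vmin else np.zeros_like(values)
    return np.array([[cox_de_boor(zi, b, degree, knots) for b in range(bins)] for zi in z])


def mi_bruteforce(wx, wy):
    """Direct double loop over samples and bin pairs."""
    n, bx = wx.shape
    by = wy.shape[1]
    joint = np.zeros((bx, by))
    for s in range(n):
        for a in range(bx):
            for b in range(by):
                joint[a, b] += wx[s, a] * wy[s, b]
    joint /= n
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for a in range(bx):
        for b in range(by):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (px[a] * py[b]))
    return max(mi, 0.0)


def histogram_mi(x, y, bins):
    """Classical plug-in histogram MI (hard binning on the min-max range)."""
    counts, _, _ = np.histogram2d(x, y, bins=bins)
    joint = counts / counts.sum()
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (px[a] * py[b]))
    return mi


class TestWeights:
    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_partition_of_unity(self, rng, order):
        w = bspline_weight_matrix(rng.uniform(size=57), bins=10, order=order)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(w >= 0)

    def test_matches_direct_basis_evaluation(self, rng):
        values = rng.uniform(size=40)
        for order in (1, 2, 3):
            w = bspline_weight_matrix(values, bins=10, order=order)
            np.testing.assert_allclose(w, weights_oracle(values, 10, order), atol=1e-12)

    def test_uniform_sample_bin_occupancy_matches_oracle(self, rng):
        values = rng.uniform(size=200)
        w = bspline_weight_matrix(values, bins=10, order=3)
        oracle = weights_oracle(values, 10, 3)
        np.testing.assert_allclose(w.sum(axis=0), oracle.sum(axis=0), atol=1e-10)

    def test_order_one_is_hard_binning(self, rng):
        values = rng.uniform(size=30)
        w = bspline_weight_matrix(values, bins=10, order=1)
        assert np.all(np.isin(w, [0.0, 1.0]))
        assert np.all(w.sum(axis=1) == 1.0)

    def test_constant_input_deterministic_single_bin(self):
        w = bspline_weight_matrix(np.full(8, 0.3), bins=10, order=3)
        np.testing.assert_array_equal(w[:, 0], np.ones(8))
        assert np.all(w[:, 1:] == 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            bspline_weight_matrix(np.array([0.1, 0.2]), bins=10, order=3)


class TestMIFromWeights:
    def test_self_information_equals_log_bins_for_distinct_values(self):
        values = np.repeat(np.arange(10.0), 3)
        w = bspline_weight_matrix(values, bins=10, order=1)
        assert mi_from_weights(w, w) == pytest.approx(math.log(10), abs=1e-12)

    def test_independent_variables_near_zero(self, rng):
        x = rng.uniform(size=2000)
        y = rng.uniform(size=2000)
        wx = bspline_weight_matrix(x, 10, 3)
        wy = bspline_weight_matrix(y, 10, 3)
        assert mi_from_weights(wx, wy) < 0.05

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(3):
            x, y = rng.uniform(size=50), rng.uniform(size=50)
            wx = bspline_weight_matrix(x, 10, 3)
            wy = bspline_weight_matrix(y, 10, 3)
            assert mi_from_weights(wx, wy) == pytest.approx(mi_bruteforce(wx, wy), abs=1e-12)

    def test_order_one_equals_histogram_mi(self, rng):
        x, y = rng.uniform(size=80), rng.uniform(size=80)
        wx = bspline_weight_matrix(x, 10, 1)
        wy = bspline_weight_matrix(y, 10, 1)
        assert mi_from_weights(wx, wy) == pytest.approx(histogram_mi(x, y, 10), abs=1e-12)

    def test_sample_count_mismatch_rejected(self, rng):
        wx = bspline_weight_matrix(rng.uniform(size=10), 10, 3)
        wy = bspline_weight_matrix(rng.uniform(size=11), 10, 3)
        with pytest.raises(ValueError, match="sample"):
            mi_from_weights(wx, wy)


def profile_dataset(profile):
    """Dataset whose profile matrix is exactly ``profile`` (one time course)."""
    from mixedclr import TimeSeriesExperiment

    n_obs, n = profile.shape
    ts = TimeSeriesExperiment(times=np.arange(n_obs, dtype=float), values=profile)
    return ExpressionDataset(genes=[f"G{i + 1}" for i in range(n)], time_series=[ts])


class TestStaticMatrix:
    def test_symmetric_and_matches_pairwise_oracle(self, rng):
        n = 5
        profile = rng.uniform(size=(30, n))
        mi = static_mi_matrix(profile_dataset(profile))
        assert np.array_equal(mi.values, mi.values.T)
        weights = [bspline_weight_matrix(profile[:, g], 10, 3) for g in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                expected = mi_bruteforce(weights[i], weights[j])
                assert mi.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_gene_achieves_row_maximum(self, rng):
        profile = rng.uniform(size=(40, 4))
        profile[:, 3] = profile[:, 0]  # duplicate gene
        mi = static_mi_matrix(profile_dataset(profile))
        assert mi.values[0, 3] == pytest.approx(np.max(mi.values[0]), abs=1e-12)

    def test_summary_reports_mean_and_sd(self, small_benchmark):
        _, dataset, _ = small_benchmark
        stats = static_mi_matrix(dataset).summary()
        assert stats["mean"] > 0 and stats["sd"] > 0


class TestDynamicMatrix:
    def test_matches_pairwise_oracle(self, rng, noisefree_benchmark):
        _, dataset, _ = noisefree_benchmark
        pairs = build_dynamic_pairs(dataset)
        mi = dynamic_mi_matrix(pairs)
        n = pairs.n_genes
        check = [(0, 1), (1, 0), (2, 7), (7, 2), (n - 1, 0)]
        for i, j in check:
            wy = bspline_weight_matrix(pairs.response[:, i], 10, 3)
            wx = bspline_weight_matrix(pairs.explanatory[:, j], 10, 3)
            assert mi.values[i, j] == pytest.approx(mi_bruteforce(wy, wx), abs=1e-12)

    def test_copied_response_achieves_row_maximum(self, tiny_dataset):
        pairs = build_dynamic_pairs(tiny_dataset)
        pairs.response[:, 0] = pairs.explanatory[:, 1]
        mi = dynamic_mi_matrix(pairs)
        assert mi.values[0, 1] == pytest.approx(np.max(mi.values[0]), abs=1e-12)

    def test_generally_asymmetric(self, small_benchmark):
        _, dataset, _ = small_benchmark
        mi = dynamic_mi_matrix(build_dynamic_pairs(dataset))
        assert not np.allclose(mi.values, mi.values.T)
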