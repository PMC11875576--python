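"""Band-pair selection, FBN construction and percentile thresholding."""

import numpy as np
import pytest

from wavefbn import (
    InvalidArgumentError,
    MiEstimatorConfig,
    PermutationConfig,
    RoiTimeSeries,
    WaveletConfig,
    apply_threshold,
    band_response_histogram,
    best_band_pair,
    build_raw_fbn,
    ccc,
    fcwt_decompose,
    resample_to_unit_rate,
)
from wavefbn.network import RawFbn
from wavefbn.synthetic import _narrowband


def _decompose(data, cfg=None):
    return fcwt_decompose(RoiTimeSeries("s", data, 1.0), cfg or WaveletConfig())


class TestBestBandPair:
    def test_single_band_returns_1_1(self):
        data = np.random.default_rng(0).standard_normal((240, 2))
        dec = _decompose(data, WaveletConfig(fn=1))
        est = best_band_pair(dec, 0, 1)
        assert (est.band_k, est.band_l) == (1, 1)

    def test_value_is_the_maximum_over_band_pairs(self, small_decomposition):
        dec = small_decomposition
        est = best_band_pair(dec, 0, 1)
        r = np.random.default_rng(1)
        for _ in range(10):
            k, l = sorted(r.integers(0, dec.n_bands, 2))
            spot = ccc(dec.coeffs[0, k], dec.coeffs[1, l]).magnitude
            assert est.value >= spot - 1e-12

    def test_planted_same_band_coupling_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            s = _narrowband(80, 0.1, 0.005, rng)  # band 4 of the default grid
            x = rng.standard_normal(80) + s
            y = rng.standard_normal(80) + s
            ts = resample_to_unit_rate(RoiTimeSeries("p", np.column_stack([x, y]), 3.0))
            est = best_band_pair(fcwt_decompose(ts), 0, 1)
            hits += (est.band_k, est.band_l) == (4, 4)
        assert hits >= 8

    def test_nmi_measure_and_same_band_exclusion(self, small_decomposition):
        est = best_band_pair(
            small_decomposition, 0, 1, measure="nmi", mi_cfg=MiEstimatorConfig(grid_points=32)
        )
        assert est.value >= 0
        est2 = best_band_pair(small_decomposition, 0, 1, include_same_band=False)
        assert est2.band_k < est2.band_l

    def test_invalid_rois(self, small_decomposition):
        with pytest.raises(InvalidArgumentError):
            best_band_pair(small_decomposition, 0, 99)
        with pytest.raises(InvalidArgumentError):
            best_band_pair(small_decomposition, 1, 1)


class TestBuildRawFbn:
    def test_two_rois_single_edge(self):
        data = np.random.default_rng(2).standard_normal((240, 2))
        raw = build_raw_fbn(_decompose(data), "ccc")
        assert raw.weights.shape == (2, 2)
        assert raw.weights[0, 1] == raw.weights[1, 0] > 0
        assert raw.weights[0, 0] == 0

    def test_identical_rois_dominate_their_row(self):
        r = np.random.default_rng(3)
        x = r.standard_normal(240)
        data = np.column_stack([x, x, r.standard_normal(240), r.standard_normal(240)])
        raw = build_raw_fbn(_decompose(data), "ccc")
        assert raw.weights[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert raw.weights[0, 1] == raw.weights[0].max()

    def test_matches_best_band_pair(self, small_decomposition):
        raw = build_raw_fbn(small_decomposition, "ccc")
        est = best_band_pair(small_decomposition, 1, 3)
        assert raw.weights[1, 3] == pytest.approx(est.value, abs=1e-12)
        assert (raw.band_k[1, 3], raw.band_l[1, 3]) == (est.band_k, est.band_l)

    def test_ccc_pvalues_present_and_valid(self, small_decomposition):
        raw = build_raw_fbn(
            small_decomposition, "ccc", perm_cfg=PermutationConfig(n_iter=50, seed=4)
        )
        iu = np.triu_indices(4, 1)
        assert np.all(raw.p_values[iu] > 0) and np.all(raw.p_values[iu] <= 1)

    def test_nmi_weights_are_normalized(self, small_decomposition):
        raw = build_raw_fbn(
            small_decomposition, "nmi", mi_cfg=MiEstimatorConfig(grid_points=32)
        )
        iu = np.triu_indices(4, 1)
        assert raw.weights[iu].min() == 0.0
        assert raw.weights[iu].max() == 1.0

    def test_pearson_reduction_single_real_band(self):
        # with fn=1 the CCC network ranks pairs like |Pearson| of the
        # band-filtered signals: check self-consistency against plain ccc
        data = np.random.default_rng(5).standard_normal((240, 3))
        dec = _decompose(data, WaveletConfig(fn=1))
        raw = build_raw_fbn(dec, "ccc")
        direct = ccc(dec.coeffs[0, 0], dec.coeffs[2, 0]).magnitude
        assert raw.weights[0, 2] == pytest.approx(direct, abs=1e-12)


class TestApplyThreshold:
    def _raw(self, weights, p=None):
        n = weights.shape[0]
        return RawFbn(
            weights=weights,
            band_k=np.ones((n, n), int),
            band_l=np.ones((n, n), int),
            p_values=p,
            method="CCCf",
        )

    def test_zero_threshold_keeps_all_significant(self):
        w = np.array([[0, 0.5, 0.2], [0.5, 0, 0.9], [0.2, 0.9, 0]], float)
        fbn = apply_threshold(self._raw(w), t=0.0)
        np.testing.assert_allclose(fbn.weights, w)
        assert fbn.n_edges == 3

    def test_decile_quantile_example(self):
        vals = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        n = 5
        w = np.zeros((n, n))
        w[np.triu_indices(n, 1)] = vals
        w = w + w.T
        fbn = apply_threshold(self._raw(w), t=0.5)
        # linear-interpolation median of {0.1..1.0} is 0.55: 5 edges survive
        assert fbn.n_edges == 5
        assert fbn.weights[fbn.weights > 0].min() >= 0.55

    def test_pvalue_gating_zeroes_non_significant(self):
        w = np.array([[0, 0.9], [0.9, 0]], float)
        p = np.array([[1, 0.05], [0.05, 1]], float)
        fbn = apply_threshold(self._raw(w, p), t=0.0, alpha=0.05)
        assert fbn.n_edges == 0  # p >= alpha is removed

    def test_edge_count_monotone_in_t(self, rng):
        for _ in range(5):
            w = np.zeros((8, 8))
            iu = np.triu_indices(8, 1)
            w[iu] = rng.uniform(size=iu[0].size)
            w = w + w.T
            raw = self._raw(w)
            counts = [apply_threshold(raw, t).n_edges for t in np.linspace(0, 0.99, 12)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_composition_idempotent(self, rng):
        w = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        w[iu] = rng.uniform(size=iu[0].size)
        w = w + w.T
        once = apply_threshold(self._raw(w), 0.6)
        twice = apply_threshold(self._raw(apply_threshold(self._raw(w), 0.0).weights), 0.6)
        np.testing.assert_allclose(once.weights, twice.weights)

    def test_invalid_threshold(self):
        with pytest.raises(InvalidArgumentError):
            apply_threshold(self._raw(np.zeros((3, 3))), t=1.5)


class TestBandResponseHistogram:
    def _raw_with_pairs(self, n, pairs):
        bk = np.zeros((n, n), int)
        bl = np.zeros((n, n), int)
        for (i, j), (k, l) in pairs.items():
            bk[i, j] = bk[j, i] = k
            bl[i, j] = bl[j, i] = l
        return RawFbn(np.ones((n, n)), bk, bl, None, "CCCf")

    def test_single_edge_counts_both_ends(self):
        raw = self._raw_with_pairs(2, {(0, 1): (2, 9)})
        counts = band_response_histogram([raw], n_bands=10)
        expected = np.zeros(10, int)
        expected[1] = expected[8] = 1
        np.testing.assert_array_equal(counts, expected)

    def test_same_band_pair_counts_twice(self):
        raw = self._raw_with_pairs(3, {(0, 1): (4, 4), (0, 2): (4, 4), (1, 2): (4, 4)})
        counts = band_response_histogram([raw], n_bands=10)
        assert counts[3] == 6

    def test_total_is_conserved(self, small_decomposition):
        raws = [build_raw_fbn(small_decomposition, "ccc")] * 3
        counts = band_response_histogram(raws, n_bands=10)
        n_edges = 4 * 3 // 2
        assert counts.sum() == 2 * n_edges * 3
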