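"""Circular-shift bootstrap mask, ROI labeling, ROI power extraction."""

import numpy as np
import pytest
from scipy import stats as sps

from pinprick_tfr.core import PipelineError
from pinprick_tfr.masking import (
    MaskConfig,
    ROI,
    _tstats_shifted,
    baseline_corrected_stack,
    build_mask,
    circular_shift_null,
    extract_roi_power,
    grand_average_stack,
    label_rois,
    pointwise_tstats,
    roi_jaccard,
)
from pinprick_tfr.timefreq import EpochWindowTF, TFRMatrix, morlet_frequencies


def _tfr(values, t0=-1.5):
    n_f, n_t = values.shape
    freqs = morlet_frequencies(n_f, 1, 35) if n_f != 30 else morlet_frequencies()
    return TFRMatrix(values, freqs, np.arange(n_t) / 256.0 + t0, "dB")


class TestGrandAverage:
    def test_identical_inputs_average_to_themselves(self, rng):
        v = rng.standard_normal((30, 948))
        stack, grand = grand_average_stack([_tfr(v.copy()) for _ in range(4)])
        np.testing.assert_allclose(grand.values, v, atol=1e-14)
        assert stack.shape == (4, 30, 948)

    def test_symmetric_pair_averages_to_zero(self):
        a, b = np.ones((30, 948)), -np.ones((30, 948))
        _, grand = grand_average_stack([_tfr(a), _tfr(b)])
        np.testing.assert_allclose(grand.values, 0.0, atol=1e-14)

    def test_order_invariance(self, rng):
        mats = [_tfr(rng.standard_normal((30, 948))) for _ in range(5)]
        _, g1 = grand_average_stack(mats)
        _, g2 = grand_average_stack(mats[::-1])
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-12)

    def test_axis_mismatch_rejected(self, rng):
        a = _tfr(rng.standard_normal((30, 948)))
        b = _tfr(rng.standard_normal((30, 900)))
        with pytest.raises(PipelineError):
            grand_average_stack([a, b])


class TestTStats:
    def test_closed_form_three_participants(self):
        """Values 1, 2, 3 dB vs zero baseline: t = 2 / (1/sqrt(3)) = 3.464."""
        X = np.array([[[1.0]], [[2.0]], [[3.0]]])
        t = pointwise_tstats(X)
        assert t[0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), rel=1e-12)

    def test_symmetric_values_give_zero(self):
        X = np.array([[[1.0]], [[-1.0]], [[0.0]]])
        assert pointwise_tstats(X)[0, 0] == 0.0

    def test_zero_variance_gives_infinite_t(self):
        X = np.full((4, 2, 2), 1.5)
        t = pointwise_tstats(X)
        assert np.all(np.isinf(t))

    def test_baseline_correction_per_frequency(self, rng):
        stack = rng.standard_normal((5, 30, 948))
        times = np.arange(948) / 256.0 - 1.5
        X, atimes = baseline_corrected_stack(stack, times)
        win = EpochWindowTF()
        assert atimes[0] >= win.analysis[0] and atimes[-1] < win.analysis[1]
        bsel = (times >= -0.4) & (times < -0.1)
        asel = (times >= 0.0) & (times < 1.6)
        expected = stack[:, :, asel] - stack[:, :, bsel].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(X, expected, atol=1e-12)


class TestNull:
    def test_null_size_matches_iterations(self, rng):
        X = rng.standard_normal((6, 8, 12))
        null = circular_shift_null(X, MaskConfig(n_iterations=250), seed=0)
        assert null.shape == (250, 8, 12)

    def test_identity_shift_reproduces_observed(self, rng):
        X = rng.standard_normal((6, 8, 12))
        null = circular_shift_null(X, shifts=[(0, 0)])
        np.testing.assert_allclose(null[0], pointwise_tstats(X), rtol=1e-6)

    def test_shift_preserves_value_multiset(self, rng):
        X = rng.standard_normal((4, 6, 10))
        shifted = np.roll(X[0], (3, 7), axis=(0, 1))
        np.testing.assert_allclose(np.sort(shifted.ravel()),
                                   np.sort(X[0].ravel()), atol=0)

    def test_shared_mode_equals_direct_recompute(self, rng):
        X = rng.standard_normal((5, 6, 9))
        shifts = [(2, 3), (5, 1), (0, 8)]
        null = circular_shift_null(X, shifts=shifts)
        for row, (df, dt) in zip(null, shifts):
            np.testing.assert_allclose(row, _tstats_shifted(X, df, dt), rtol=1e-5)

    def test_enumeration_mask_matches_bruteforce_oracle(self, rng):
        """On a 4 x 8 toy stack, the shared-shift percentile mask from the
        full 32-shift enumeration equals a from-scratch oracle that shifts
        every participant's matrix and recomputes scipy's one-sample t."""
        X = rng.standard_normal((6, 4, 8))
        X[:, 1, 3] += 3.0  # one planted bin
        shifts = [(df, dt) for df in range(4) for dt in range(8)]
        cfg = MaskConfig(n_iterations=100, percentile=95.0, two_sided=True)
        null = circular_shift_null(X, cfg, shifts=shifts)
        mask = build_mask(pointwise_tstats(X), null, cfg)

        oracle_null = np.empty((32, 4, 8))
        for i, (df, dt) in enumerate(shifts):
            rolled = np.stack([np.roll(x, (df, dt), axis=(0, 1)) for x in X])
            oracle_null[i] = sps.ttest_1samp(rolled, 0.0, axis=0).statistic
        thr = np.quantile(np.abs(oracle_null), 0.95, axis=0)
        oracle_mask = np.abs(sps.ttest_1samp(X, 0.0, axis=0).statistic) >= thr
        np.testing.assert_array_equal(mask, oracle_mask)

    def test_independent_mode_type_one_error_near_five_percent(self):
        """Stationary Gaussian stacks: expected bin inclusion ~5%."""
        rng = np.random.default_rng(2024)
        cfg = MaskConfig(n_iterations=300)
        rates = []
        for _ in range(40):
            X = rng.standard_normal((12, 20, 40))
            t = pointwise_tstats(X)
            null = circular_shift_null(X, cfg, seed=rng)
            rates.append(build_mask(t, null, cfg).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)


class TestBuildMask:
    def test_observed_below_all_null_excluded(self):
        t = np.zeros((2, 2))
        null = np.abs(np.random.default_rng(0).standard_normal((100, 2, 2))) + 1.0
        assert not build_mask(t, null).any()

    def test_dominant_effect_always_included(self, rng):
        t = np.full((3, 3), 50.0)
        null = rng.standard_normal((200, 3, 3))
        assert build_mask(t, null).all()

    def test_one_sided_mode_ignores_negative_effects(self, rng):
        t = np.array([[10.0, -10.0]])
        null = rng.standard_normal((500, 1, 2))
        cfg = MaskConfig(two_sided=False)
        m = build_mask(t, null, cfg)
        assert m[0, 0] and not m[0, 1]


class TestLabelROIs:
    def test_disjoint_rectangles_recovered_exactly(self):
        mask = np.zeros((20, 50), dtype=bool)
        mask[2:6, 5:15] = True
        mask[10:15, 30:45] = True
        rois = label_rois(mask, MaskConfig(min_roi_bins=5))
        assert len(rois) == 2
        assert sorted(r.n_bins for r in rois) == [4 * 10, 5 * 15]

    def test_single_bin_speckle_dropped(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        assert label_rois(mask, MaskConfig(min_roi_bins=10)) == []

    def test_empty_mask_gives_empty_roiset(self):
        assert label_rois(np.zeros((5, 5), dtype=bool)) == []

    def test_sign_stratification_splits_touching_opposites(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[2:6, 2:18] = True
        tmap = np.zeros((10, 20))
        tmap[2:4, 2:18] = 5.0   # synchronization rows
        tmap[4:6, 2:18] = -5.0  # touching desynchronization rows
        rois = label_rois(mask, MaskConfig(min_roi_bins=5), tmap=tmap)
        assert len(rois) == 2
        assert sorted(r.sign for r in rois) == [-1, 1]

    def test_effect_floor_excludes_weak_bins(self):
        mask = np.ones((6, 10), dtype=bool)
        tmap = np.full((6, 10), 4.0)
        grand = np.full((6, 10), 0.1)
        grand[0:3] = 1.0
        rois = label_rois(mask, MaskConfig(min_roi_bins=5), tmap=tmap,
                          grand_db=grand)
        assert len(rois) == 1 and rois[0].n_bins == 30

    def test_band_trough_splits_merged_component(self):
        """Two same-sign band effects joined by a weak bridge are cut apart."""
        mask = np.zeros((20, 30), dtype=bool)
        mask[2:12, 5:25] = True
        tmap = np.zeros((20, 30))
        tmap[2:6, 5:25] = 6.0
        tmap[6:8, 5:25] = 2.0  # trough rows
        tmap[8:12, 5:25] = 6.0
        rois = label_rois(mask, MaskConfig(min_roi_bins=5), tmap=tmap)
        assert len(rois) == 2


class TestROIPower:
    def _roi(self, rows, cols, label="alpha_desync"):
        bins = np.array([(r, c) for r in rows for c in cols])
        return ROI(label, -1, 0, 0, 0, 0, bins)

    def test_constant_map_reads_constant(self):
        tfr = _tfr(np.full((30, 948), 3.0))
        roi = self._roi(range(5, 10), range(10, 40))
        out = extract_roi_power(tfr, [roi])
        assert out["alpha_desync"] == pytest.approx(3.0)

    def test_single_bin_roi_reads_that_bin(self):
        vals = np.zeros((30, 948))
        tfr = _tfr(vals)
        win = EpochWindowTF()
        asel = np.flatnonzero((tfr.times >= 0) & (tfr.times < 1.6))
        vals[7, asel[13]] = -2.5
        out = extract_roi_power(tfr, [self._roi([7], [13])], win)
        assert out["alpha_desync"] == pytest.approx(-2.5)

    def test_roi_outside_grid_rejected(self):
        tfr = _tfr(np.zeros((30, 948)))
        with pytest.raises(PipelineError):
            extract_roi_power(tfr, [self._roi([7], [100_000])])


class TestJaccard:
    def test_perfect_overlap_is_one(self):
        freqs = morlet_frequencies()
        times = np.arange(410) / 256.0
        rect = (5.0, 13.0, 0.1, 0.5)
        rows = np.flatnonzero((freqs >= 5) & (freqs <= 13))
        cols = np.flatnonzero((times >= 0.1) & (times <= 0.5))
        bins = np.array([(r, c) for r in rows for c in cols])
        roi = ROI("alpha_desync", -1, 5, 13, 0.1, 0.5, bins)
        assert roi_jaccard(roi, rect, freqs, times) == pytest.approx(1.0)

    def test_disjoint_overlap_is_zero(self):
        freqs = morlet_frequencies()
        times = np.arange(410) / 256.0
        roi = ROI("x", 1, 0, 0, 0, 0, np.array([[0, 0]]))
        assert roi_jaccard(roi, (20.0, 30.0, 1.0, 1.5), freqs, times) == 0.0
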