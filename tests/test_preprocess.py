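"""Conditioning-chain units: each stage against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial import polynomial as npoly

from endoraman import (
    CalibrationSet,
    PreprocessParams,
    SNVNormalizer,
    bubblefill_baseline,
    preprocess,
    snv,
)
from endoraman.errors import (
    CalibrationError,
    DegenerateInputError,
    ParameterError,
    RangeError,
)
from endoraman.preprocess import (
    calibrate_axis,
    correct_response,
    remove_cosmic_rays,
    smooth_sg,
    subtract_dark,
    truncate,
)
from endoraman.types import SpectralAxis


def test_params_validation():
    with pytest.raises(ParameterError):
        PreprocessParams(bubble_min_width=0.0)
    with pytest.raises(ParameterError):
        PreprocessParams(sg_window=4)
    with pytest.raises(ParameterError):
        PreprocessParams(sg_window=3, sg_order=3)
    with pytest.raises(ParameterError):
        PreprocessParams(truncate_lo=1800.0, truncate_hi=800.0)


def test_subtract_dark(raw_ds):
    rec = raw_ds.records[0]
    out = subtract_dark(rec)
    np.testing.assert_allclose(out, rec.frames - rec.dark_frame[None, :])


class TestDespike:
    def test_spike_removed_across_frames(self, rng):
        base = 100.0 + 5.0 * np.sin(np.linspace(0, 6, 400))
        frames = base + rng.normal(0, 1.0, size=(8, 400))
        clean_val = np.median(frames[:, 123])
        frames[2, 123] += 5000.0
        out = remove_cosmic_rays(frames, threshold=8.0)
        assert abs(out[2, 123] - clean_val) < 5.0
        # untouched pixels are bit-identical
        mask = np.ones_like(frames, bool)
        mask[2, 123] = False
        np.testing.assert_array_equal(out[mask], frames[mask])

    def test_downward_outliers_left_alone(self, rng):
        frames = 100.0 + rng.normal(0, 1.0, size=(8, 50))
        frames[3, 10] -= 500.0
        out = remove_cosmic_rays(frames, threshold=8.0)
        assert out[3, 10] == frames[3, 10]

    def test_single_frame_fallback(self, rng):
        y = 100.0 + rng.normal(0, 1.0, size=300)
        y[150] += 4000.0
        out = remove_cosmic_rays(y[None, :], threshold=8.0)
        assert out.shape == (1, 300)
        assert out[0, 150] < 120.0


class TestCalibrateAxis:
    def test_recovers_known_polynomial(self):
        true = np.array([390.0, 1.1, -5e-5])  # c0 + c1 p + c2 p^2
        px = np.array([60.0, 250.0, 480.0, 700.0, 930.0, 1200.0, 1500.0])
        calib = CalibrationSet(px, npoly.polyval(px, true), np.ones(1601))
        axis = calibrate_axis(calib, 1601, degree=2)
        expected = npoly.polyval(np.arange(1601.0), true)
        np.testing.assert_allclose(axis.shifts, expected, atol=1e-6)

    def test_too_few_references(self):
        calib = CalibrationSet([10.0, 500.0], [400.0, 900.0], np.ones(100))
        with pytest.raises(CalibrationError):
            calibrate_axis(calib, 100, degree=2)

    def test_non_monotonic_fit_rejected(self):
        px = np.array([100.0, 500.0, 900.0])
        sh = np.array([800.0, 1500.0, 900.0])
        calib = CalibrationSet(px, sh, np.ones(1000))
        with pytest.raises(CalibrationError):
            calibrate_axis(calib, 1000, degree=2)


class TestResponseCorrection:
    def test_uniform_response_is_noop(self, rng):
        y = rng.normal(size=64)
        calib = CalibrationSet([0.0, 1.0], [800.0, 900.0], np.full(64, 3.7))
        np.testing.assert_allclose(correct_response(y, calib), y)

    def test_known_division(self):
        resp = np.array([1.0, 2.0, 1.0, 2.0])
        calib = CalibrationSet([0.0, 1.0], [800.0, 900.0], resp)
        y = np.array([2.0, 4.0, 2.0, 4.0])
        out = correct_response(y, calib)
        # response normalized to unit mean (1.5) before division
        np.testing.assert_allclose(out, y / (resp / 1.5))

    def test_nonpositive_response_rejected(self):
        calib = CalibrationSet([0.0, 1.0], [800.0, 900.0], np.array([1.0, 0.0]))
        with pytest.raises(CalibrationError):
            correct_response(np.ones(2), calib)


def _voigt(x, c, fwhm=15.0):
    u = (x - c) / fwhm
    return 0.5 / (1.0 + 4 * u**2) + 0.5 * np.exp(-4 * np.log(2) * u**2)


class TestBubbleFill:
    def test_baseline_under_signal_and_raman_nonnegative(self, rng):
        x = np.linspace(800.0, 1800.0, 1001)
        y = 1000 + 500 * np.exp(-((x - 1200) / 400) ** 2) + 300 * _voigt(x, 1004)
        raman, baseline = bubblefill_baseline(x, y)
        assert np.all(raman >= 0)
        assert np.all(baseline <= y + 1e-9)

    def test_linear_trend_gives_zero_raman(self):
        x = np.linspace(800.0, 1800.0, 501)
        y = 3.0 * x + 17.0
        raman, baseline = bubblefill_baseline(x, y)
        np.testing.assert_allclose(raman, 0.0, atol=1e-9)
        np.testing.assert_allclose(baseline, y, atol=1e-9)

    def test_offset_invariance(self):
        x = np.linspace(800.0, 1800.0, 1001)
        y = 2000 * np.exp(-((x - 1300) / 500) ** 2) + 400 * _voigt(x, 1449)
        r1, _ = bubblefill_baseline(x, y)
        r2, _ = bubblefill_baseline(x, y + 12345.0)
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_narrow_peak_survives_broad_structure_absorbed(self):
        x = np.linspace(800.0, 1800.0, 1001)
        narrow = 500 * _voigt(x, 1128, fwhm=15.0)
        broad = 500 * np.exp(-4 * np.log(2) * ((x - 1300) / 300.0) ** 2)
        raman, baseline = bubblefill_baseline(x, narrow + broad + 2000.0)
        i = int(np.argmin(np.abs(x - 1128.0)))
        assert raman[i] > 0.5 * 500  # narrow band kept in the signal
        # the 300 cm^-1-wide structure is mostly attributed to the baseline
        j = int(np.argmin(np.abs(x - 1300.0)))
        assert raman[j] < 0.35 * 500

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            bubblefill_baseline(np.arange(5.0), np.arange(5.0), bubble_min_width=0)


class TestSmoothing:
    def test_window_one_is_exact_noop(self, rng):
        y = rng.normal(size=200)
        np.testing.assert_array_equal(smooth_sg(y, order=3, window=1), y)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_sg(np.ones(10), window=4)

    def test_window_must_exceed_order(self):
        with pytest.raises(ParameterError):
            smooth_sg(np.ones(10), order=3, window=3)

    def test_smoothing_reduces_noise(self, rng):
        x = np.linspace(0, 6, 500)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.3, size=500)
        out = smooth_sg(noisy, order=3, window=21)
        assert np.std(out - clean) < np.std(noisy - clean)


class TestTruncate:
    def test_one_wavenumber_grid_keeps_1001_bins(self):
        axis = SpectralAxis(np.linspace(400.0, 2000.0, 1601))
        sub, y = truncate(axis, np.arange(1601.0))
        assert len(sub) == 1001
        assert sub.shifts[0] == pytest.approx(800.0)
        assert sub.shifts[-1] == pytest.approx(1800.0)
        assert y[0] == pytest.approx(400.0)  # values follow their bins

    def test_disjoint_window_raises(self):
        axis = SpectralAxis(np.linspace(2000.0, 2500.0, 100))
        with pytest.raises(RangeError):
            truncate(axis, np.zeros(100))


class TestSNV:
    def test_hand_computed_values(self):
        out = snv(np.array([1.0, 2.0, 3.0]))
        sd = np.sqrt(2.0 / 3.0)  # population convention
        np.testing.assert_allclose(out, np.array([-1.0, 0.0, 1.0]) / sd)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            snv(np.full(10, 3.0))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(0.1, 100.0),
        b=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).normal(size=64)
        ref = snv(x)
        np.testing.assert_allclose(snv(a * x + b), ref, atol=1e-7)
        assert abs(ref.mean()) < 1e-10 and abs(ref.std() - 1.0) < 1e-10


class TestEndToEnd:
    def test_processed_records_meet_all_contracts(self, processed_ds, raw_ds):
        assert len(processed_ds) == len(raw_ds)
        for rec in processed_ds.records[:30]:
            assert len(rec.axis) == 1001
            assert rec.axis.shifts[0] >= 800.0 - 1e-6
            assert rec.axis.shifts[-1] <= 1800.0 + 1e-6
            assert abs(rec.intensities.mean()) < 1e-8
            assert abs(rec.intensities.std() - 1.0) < 1e-8

    def test_stage_tagging_on_failure(self, raw_ds):
        bad = CalibrationSet(
            [100.0, 500.0, 900.0],
            [800.0, 1500.0, 900.0],
            np.ones(raw_ds.records[0].axis_pixels),
        )
        with pytest.raises(CalibrationError, match="axis_calibration"):
            preprocess(raw_ds.records[0], bad)


class TestSNVNormalizer:
    def test_rows_normalized(self, rng):
        X = rng.normal(10.0, 5.0, size=(6, 40))
        out = SNVNormalizer().fit_transform(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-10)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clone(SNVNormalizer())
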