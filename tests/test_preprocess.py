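"""Tests of the time-course cleaning chain."""

import numpy as np
import pytest

from dfcstates import (MotionParams, despike_spline, detrend_poly,
                       framewise_displacement, lowpass, regress_nuisance)

from conftest import make_panel


class TestDetrend:
    def test_cubic_annihilated(self):
        t = np.arange(100, dtype=float)
        col = t ** 3 - 2 * t
        out = detrend_poly(make_panel(col[:, None]), max_order=3)
        assert np.abs(out.data).max() < 1e-8 * np.abs(col).max()

    def test_projection_contracts_variance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 3))
        out = detrend_poly(make_panel(x), max_order=3)
        assert np.all(out.data.var(axis=0) <= x.var(axis=0) + 1e-12)

    def test_matches_normal_equations_oracle(self):
        t = np.arange(150, dtype=float)
        col = 0.3 * t ** 3 - t ** 2 + np.sin(2 * np.pi * t / 25)
        out = detrend_poly(make_panel(col[:, None]), max_order=3)
        # independent oracle: explicit least-squares on the monomial basis
        X = np.vander(t, 4, increasing=True)
        beta, *_ = np.linalg.lstsq(X, col, rcond=None)
        expected = col - X @ beta
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-8)

    def test_orthogonal_to_basis(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((120, 2))
        out = detrend_poly(make_panel(x), max_order=2)
        t = np.arange(120, dtype=float)
        for order in range(3):
            proj = np.abs((t ** order) @ out.data)
            assert np.all(proj < 1e-6 * np.linalg.norm(t ** order)
                          * np.linalg.norm(out.data, axis=0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly(make_panel(np.zeros((4, 1))), max_order=3)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.standard_normal((90, 2)))
        once = detrend_poly(panel, 3)
        twice = detrend_poly(once, 3)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-6)


class TestLowpass:
    def test_dc_preserved(self):
        panel = make_panel(np.full((120, 1), 3.7), tr=2.0)
        out = lowpass(panel, 0.15)
        np.testing.assert_allclose(out.data, panel.data, atol=1e-6)

    def test_stopband_attenuation(self):
        # 0.24 Hz is aliased-free at TR=2 s (Nyquist 0.25 Hz) but above the
        # 0.15 Hz cutoff: RMS must drop by over 90%
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.24 * t)
        out = lowpass(make_panel(x[:, None], tr=2.0), 0.15)
        assert np.sqrt((out.data ** 2).mean()) < 0.1 * np.sqrt((x ** 2).mean())

    def test_passband_preserved(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = lowpass(make_panel(x[:, None], tr=2.0), 0.15)
        rms_in = np.sqrt((x ** 2).mean())
        rms_out = np.sqrt((out.data ** 2).mean())
        assert abs(rms_out - rms_in) < 0.05 * rms_in

    def test_zero_phase(self):
        """A passband sinusoid must come back with zero lag."""
        t = np.arange(500) * 2.0
        x = np.sin(2 * np.pi * 0.03 * t)
        out = lowpass(make_panel(x[:, None], tr=2.0), 0.15)
        y = out.data[:, 0]
        inner = slice(20, 480)
        lags = range(-3, 4)
        xcorr = [np.dot(y[inner], np.roll(x, lag)[inner]) for lag in lags]
        assert lags[int(np.argmax(xcorr))] == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(make_panel(np.zeros((50, 1)), tr=2.0), 0.3)


class TestNuisanceRegression:
    def test_perfect_fit_removed(self):
        rng = np.random.default_rng(3)
        reg = rng.standard_normal((100, 1))
        out = regress_nuisance(make_panel(reg.copy()), reg)
        assert np.abs(out.data).max() < 1e-10

    def test_zero_regressors_demean_only(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((80, 2)) + 5.0
        with pytest.warns(UserWarning):
            out = regress_nuisance(make_panel(x), np.zeros((80, 2)))
        np.testing.assert_allclose(out.data, x - x.mean(axis=0), atol=1e-10)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        R = rng.standard_normal((200, 6))
        beta = rng.standard_normal((6, 1))
        y = R @ beta + 0.1 * rng.standard_normal((200, 1))
        out = regress_nuisance(make_panel(y), R)
        X = np.column_stack([np.ones(200), R])
        bb, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(out.data, y - X @ bb, atol=1e-8)

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(6)
        R = rng.standard_normal((150, 4))
        out = regress_nuisance(make_panel(rng.standard_normal((150, 2))), R)
        assert np.abs(R.T @ out.data).max() < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        R = rng.standard_normal((100, 3))
        once = regress_nuisance(make_panel(rng.standard_normal((100, 2))), R)
        twice = regress_nuisance(once, R)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-6)


class TestDespike:
    @staticmethod
    def _slow_wave(T=200):
        return np.sin(2 * np.pi * np.arange(T) / 60.0)

    def test_clean_series_untouched(self):
        rng = np.random.default_rng(8)
        x = self._slow_wave() + 0.1 * rng.standard_normal(200)
        out, mask = despike_spline(make_panel(x[:, None]))
        assert mask.sum() == 0
        np.testing.assert_array_equal(out.data[:, 0], x)

    def test_single_spike_replaced(self):
        rng = np.random.default_rng(9)
        clean = self._slow_wave()
        noisy = clean + 0.05 * rng.standard_normal(200)
        x = noisy.copy()
        x[90] += 10 * 0.05 * 10  # +10 sigma-scale spike
        out, mask = despike_spline(make_panel(x[:, None]))
        assert mask[90, 0]
        assert abs(out.data[90, 0] - clean[90]) < 0.1
        untouched = ~mask[:, 0]
        np.testing.assert_array_equal(out.data[untouched, 0], x[untouched])

    def test_two_adjacent_spikes(self):
        rng = np.random.default_rng(10)
        x = self._slow_wave() + 0.05 * rng.standard_normal(200)
        x[100] += 4.0
        x[101] += 4.0
        out, mask = despike_spline(make_panel(x[:, None]))
        assert mask[:, 0].sum() == 2
        assert mask[100, 0] and mask[101, 0]

    def test_unusable_column_rejected(self):
        rng = np.random.default_rng(11)
        x = 0.01 * rng.standard_normal(60)
        x[::2] += 100.0  # more than half the points are spikes
        with pytest.raises(ValueError, match="50%"):
            despike_spline(make_panel(x[:, None]))

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        x = self._slow_wave() + 0.05 * rng.standard_normal(200)
        x[50] += 5.0
        once, _ = despike_spline(make_panel(x[:, None]))
        twice, _ = despike_spline(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-6)


class TestCleanerChain:
    def test_full_chain_preserves_shape_and_flags_spikes(self):
        from dfcstates import TimeCourseCleaner
        rng = np.random.default_rng(13)
        T = 200
        t = np.arange(T, dtype=float)
        data = rng.standard_normal((T, 3)) + 0.01 * t[:, None]
        data[60, 1] += 8.0
        panel = make_panel(data)
        motion = MotionParams(np.cumsum(
            rng.normal(0, 0.01, size=(T, 6)), axis=0))
        cleaner = TimeCourseCleaner()
        out = cleaner.fit(panel).transform(panel, motion)
        assert out.data.shape == (T, 3)
        assert np.isfinite(out.data).all()
        assert cleaner.outlier_mask_.shape == (T, 3)

    def test_stage_toggles(self):
        from dfcstates import TimeCourseCleaner
        rng = np.random.default_rng(14)
        panel = make_panel(rng.standard_normal((100, 2)))
        cleaner = TimeCourseCleaner(detrend=False, filter=False,
                                    regress_motion=False, despike=False)
        out = cleaner.fit(panel).transform(panel)
        np.testing.assert_array_equal(out.data, panel.data)

    def test_sklearn_param_interface(self):
        from dfcstates import TimeCourseCleaner
        c = TimeCourseCleaner(cutoff_hz=0.1)
        assert c.get_params()["cutoff_hz"] == 0.1
        c.set_params(mad_thresh=4.0)
        assert c.mad_thresh == 4.0


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd, mean_fd = framewise_displacement(MotionParams(np.zeros((50, 6))))
        assert fd.shape == (49,)
        assert mean_fd == 0.0

    def test_translation_step(self):
        m = np.zeros((3, 6))
        m[1:, 0] = 1.0  # one 1 mm x-translation step
        fd, _ = framewise_displacement(MotionParams(m))
        np.testing.assert_allclose(fd, [1.0, 0.0])

    def test_rotation_step_on_sphere(self):
        m = np.zeros((3, 6))
        m[1:, 3] = 0.02  # 0.02 rad on a 50 mm sphere -> 1 mm
        fd, _ = framewise_displacement(MotionParams(m))
        np.testing.assert_allclose(fd, [1.0, 0.0])

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            MotionParams(np.zeros((10, 5)))
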