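"""Signal-level preprocessing: discard, despike, scaling, regression,
band-pass, surface smoothing, z-normalization, and the state machine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connvar as cv
from connvar.core import (STATE_BANDPASSED, STATE_CLEANED, STATE_SMOOTHED,
                          STATE_ZNORMALIZED, ProcessingStateError)
from connvar.preprocess import NuisanceDesign
from conftest import make_session


class TestDiscard:
    def test_drops_requested_volumes(self, rng):
        ts = make_session(rng.standard_normal((5, 300)), state="raw")
        out = cv.discard_initial(ts, 5)
        assert out.n_timepoints == 295

    def test_zero_is_identity(self, rng):
        ts = make_session(rng.standard_normal((5, 20)), state="raw")
        assert cv.discard_initial(ts, 0) is ts

    def test_retained_columns_shift(self, rng):
        data = rng.standard_normal((3, 10))
        out = cv.discard_initial(make_session(data, state="raw"), 3)
        assert np.array_equal(out.data[:, 0], data[:, 3])

    def test_rejects_dropping_everything(self, rng):
        ts = make_session(rng.standard_normal((3, 10)), state="raw")
        with pytest.raises(ValueError):
            cv.discard_initial(ts, 10)


class TestDespike:
    def test_clean_series_untouched(self, rng):
        ts = make_session(rng.standard_normal((10, 100)), state="raw")
        out, mask = cv.despike(ts, 8.0)
        assert not mask.any()
        assert np.array_equal(out.data, ts.data)

    def test_single_spike_interpolated(self):
        x = np.sin(np.linspace(0, 6 * np.pi, 100))[None, :].repeat(2, axis=0)
        x[0, 50] += 40.0
        out, mask = cv.despike(make_session(x, state="raw"), 5.0)
        assert mask[0, 50] and mask.sum() == 1
        expected = 0.5 * (x[0, 49] + x[0, 51])
        assert out.data[0, 50] == pytest.approx(expected)

    def test_recall_of_injected_spikes(self, rng):
        x = rng.standard_normal((4, 200))
        locations = [(0, 10), (2, 100), (3, 199)]
        for v, t in locations:
            x[v, t] += 30.0
        _, mask = cv.despike(make_session(x, state="raw"), 5.0)
        for v, t in locations:
            assert mask[v, t]

    def test_all_flagged_vertex_left_untouched(self):
        # two huge alternating values: MAD flags everything -> keep original
        x = np.array([[0.0, 1.0, 0.0, 1.0, 0.0, 1.0]])
        out, mask = cv.despike(make_session(x, state="raw"), 0.1)
        assert np.array_equal(out.data, x)


class TestGlobalScaling:
    def test_reaches_target(self, rng):
        ts = make_session(rng.uniform(500, 1500, (8, 50)), state="raw")
        out = cv.scale_global_mean(ts, 10_000.0)
        assert out.data.mean() == pytest.approx(10_000.0, rel=1e-10)

    def test_identity_when_already_at_target(self):
        ts = make_session(np.full((3, 4), 10_000.0), state="raw")
        out = cv.scale_global_mean(ts, 10_000.0)
        assert np.allclose(out.data, ts.data, rtol=1e-12)

    def test_constant_scaling(self):
        ts = make_session(np.full((2, 3), 5.0), state="raw")
        assert np.allclose(cv.scale_global_mean(ts, 10.0).data, 10.0)

    def test_nonpositive_mean_rejected(self):
        ts = make_session(np.full((2, 3), -1.0), state="raw")
        with pytest.raises(ValueError):
            cv.scale_global_mean(ts, 10.0)


class TestMotionRegressors:
    def test_zero_motion(self):
        f24, fd = cv.motion_regressors(np.zeros((10, 6)), 50.0)
        assert f24.shape == (10, 24)
        assert np.all(f24 == 0) and fd == 0.0

    def test_translation_step_fd(self):
        m = np.zeros((2, 6))
        m[1, 0] = 1.0                      # 1 mm x-translation step
        _, fd = cv.motion_regressors(m, 50.0)
        assert fd == pytest.approx(1.0)

    def test_rotation_step_fd(self):
        m = np.zeros((2, 6))
        m[1, 3] = 0.02                     # 0.02 rad * 50 mm = 1 mm
        _, fd = cv.motion_regressors(m, 50.0)
        assert fd == pytest.approx(1.0)

    def test_friston24_layout(self, rng):
        m = rng.standard_normal((6, 6))
        f24, _ = cv.motion_regressors(m)
        assert np.array_equal(f24[:, :6], m)
        assert np.array_equal(f24[:, 6:12], m ** 2)
        assert np.all(f24[0, 12:] == 0)
        assert np.array_equal(f24[1:, 12:18], m[:-1])

    def test_nonfinite_rejected(self):
        m = np.zeros((4, 6))
        m[2, 1] = np.nan
        with pytest.raises(ValueError):
            cv.motion_regressors(m)


class TestNuisanceRegression:
    def _design(self, rng, T, p=5):
        X = np.column_stack([np.ones(T), rng.standard_normal((T, p - 1))])
        return NuisanceDesign(X, tuple(f"c{i}" for i in range(p)))

    def test_residuals_orthogonal_to_design(self, rng):
        ts = make_session(rng.standard_normal((12, 80)), state="raw")
        design = self._design(rng, 80)
        out = cv.regress_nuisance(ts, design)
        dots = np.abs(design.matrix.T @ out.data.T)
        scale = (np.linalg.norm(design.matrix, axis=0)[:, None]
                 * np.linalg.norm(out.data, axis=1)[None, :] + 1e-300)
        assert (dots / scale).max() < 1e-8
        assert out.state == STATE_CLEANED

    def test_design_column_regressed_to_zero(self, rng):
        design = self._design(rng, 60)
        ts = make_session(np.tile(design.matrix[:, 2], (3, 1)), state="raw")
        out = cv.regress_nuisance(ts, design)
        assert np.abs(out.data).max() < 1e-10

    def test_intercept_only_centers(self, rng):
        ts = make_session(rng.standard_normal((4, 30)), state="raw")
        design = NuisanceDesign(np.ones((30, 1)), ("intercept",))
        out = cv.regress_nuisance(ts, design)
        expected = ts.data - ts.data.mean(axis=1, keepdims=True)
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        ts = make_session(rng.standard_normal((6, 50)), state="raw")
        design = self._design(rng, 50)
        out = cv.regress_nuisance(ts, design)
        X = design.matrix
        beta = np.linalg.solve(X.T @ X, X.T @ ts.data.T)
        oracle = ts.data.T - X @ beta
        assert np.allclose(out.data, oracle.T, atol=1e-8)

    def test_idempotent(self, rng):
        ts = make_session(rng.standard_normal((5, 40)), state="raw")
        design = self._design(rng, 40)
        once = cv.regress_nuisance(ts, design)
        twice = cv.regress_nuisance(once, design)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng):
        X = rng.standard_normal((40, 3))
        X = np.column_stack([X, X[:, 0] * 2.0])
        design = NuisanceDesign(X, ("a", "b", "c", "dup"))
        ts = make_session(rng.standard_normal((3, 40)), state="raw")
        with pytest.warns(UserWarning):
            out = cv.regress_nuisance(ts, design)
        assert np.all(np.isfinite(out.data))


class TestBandpass:
    def _sinusoid(self, f, T=240, dt=2.0):
        t = np.arange(T) * dt
        return np.cos(2 * np.pi * f * t)[None, :]

    def test_stopband_sinusoid_removed(self):
        ts = make_session(self._sinusoid(0.2))
        out = cv.bandpass(ts, 0.01, 0.1)
        assert np.abs(out.data).max() < 1e-10
        assert out.state == STATE_BANDPASSED

    def test_passband_sinusoid_preserved(self):
        ts = make_session(self._sinusoid(0.05))   # 0.05 Hz = bin 24 of 240
        out = cv.bandpass(ts, 0.01, 0.1)
        assert np.allclose(out.data, ts.data, atol=1e-10)

    def test_white_noise_variance_fraction(self, rng):
        T, dt = 200, 2.0
        freqs = np.fft.rfftfreq(T, dt)
        keep = (freqs >= 0.01) & (freqs <= 0.1)
        q = keep.sum() / (T / 2)          # fraction of spectral mass retained
        x = rng.standard_normal((100, T))
        out = cv.bandpass(make_session(x, dt=dt), 0.01, 0.1)
        ratio = out.data.var() / x.var()
        assert ratio == pytest.approx(q, rel=0.05)

    def test_invalid_band_rejected(self, rng):
        ts = make_session(rng.standard_normal((2, 40)))
        with pytest.raises(ValueError):
            cv.bandpass(ts, 0.1, 0.01)
        with pytest.raises(ValueError):
            cv.bandpass(ts, 0.01, 0.4)       # above Nyquist for dt=2

    def test_commutes_with_vertex_permutation(self, rng):
        x = rng.standard_normal((9, 60))
        perm = rng.permutation(9)
        a = cv.bandpass(make_session(x), 0.01, 0.1).data[perm]
        b = cv.bandpass(make_session(x[perm]), 0.01, 0.1).data
        assert np.allclose(a, b, atol=1e-12)


class TestSmoothing:
    def test_constant_preserved(self, ico1):
        x = np.full(ico1.vertex_count, 3.7)
        assert np.allclose(cv.smooth_on_mesh(x, ico1, 6.0), 3.7)

    def test_zero_fwhm_is_identity(self, ico1, rng):
        x = rng.standard_normal(ico1.vertex_count)
        assert np.array_equal(cv.smooth_on_mesh(x, ico1, 0.0), x)

    @pytest.mark.parametrize("fwhm", [4.0, 6.0, 12.0])
    def test_impulse_sum_preserved_and_max_decreasing(self, ico1, fwhm):
        x = np.zeros(ico1.vertex_count)
        x[0] = 1.0
        out = cv.smooth_on_mesh(x, ico1, fwhm)
        assert out.sum() == pytest.approx(1.0, abs=1e-8)
        assert out.max() < 1.0
        wider = cv.smooth_on_mesh(x, ico1, 2 * fwhm)
        assert wider.max() < out.max()

    def test_smooth_session_sets_state(self, ico1, rng):
        ts = make_session(rng.standard_normal((ico1.vertex_count, 20)))
        out = cv.smooth_session(ts, ico1, 6.0)
        assert out.state == STATE_SMOOTHED


class TestZNormalize:
    def test_moments(self, bandpassed_session):
        out = cv.znormalize(bandpassed_session)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12
        assert np.abs(out.data.var(axis=1) - 1).max() < 1e-12
        assert out.state == STATE_ZNORMALIZED

    def test_known_values_population_divisor(self):
        ts = make_session(np.array([[1.0, 2.0, 3.0, 4.0]]),
                          state=STATE_BANDPASSED)
        out = cv.znormalize(ts)
        expected = np.array([-1.342, -0.447, 0.447, 1.342])
        assert np.allclose(out.data[0], expected, atol=5e-4)

    def test_idempotent(self, bandpassed_session):
        once = cv.znormalize(bandpassed_session)
        twice = cv.znormalize(once.with_data(once.data,
                                             state=STATE_BANDPASSED))
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_series_zeroed_with_warning(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        ts = make_session(x, state=STATE_BANDPASSED)
        with pytest.warns(UserWarning):
            out = cv.znormalize(ts)
        assert np.all(out.data[0] == 0)


class TestStateMachine:
    def test_metrics_refuse_wrong_state(self, ico1, rng):
        raw = make_session(rng.standard_normal((ico1.vertex_count, 40)),
                           state="raw")
        with pytest.raises(ProcessingStateError):
            cv.amplitude_metrics(raw)
        with pytest.raises(ProcessingStateError):
            cv.reho(raw, ico1, 1)
        with pytest.raises(ProcessingStateError):
            cv.sfc(raw, cv.SeedDefinition(np.array([0])))
        with pytest.raises(ProcessingStateError):
            cv.dual_regression(raw, rng.standard_normal((ico1.vertex_count, 3)))
        with pytest.raises(ProcessingStateError):
            cv.correlation_graph(raw)

    def test_bandpass_requires_cleaned_or_raw(self, rng):
        smoothed = make_session(rng.standard_normal((4, 40)),
                                state=STATE_SMOOTHED)
        with pytest.raises(ProcessingStateError):
            cv.bandpass(smoothed, 0.01, 0.1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_znormalize_commutes_with_permutation(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((6, 32))
    perm = rng.permutation(6)
    ts = make_session(x, state=STATE_BANDPASSED)
    tsp = make_session(x[perm], state=STATE_BANDPASSED)
    assert np.allclose(cv.znormalize(ts).data[perm],
                       cv.znormalize(tsp).data, atol=1e-12)
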