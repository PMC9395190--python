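import numpy as np
import pytest
from hypothesis import given, strategies as st

from dipolecycle import oscillation
from dipolecycle.fields import CellGeometrySeries, VectorFieldSeries
from dipolecycle.oscillation import (Correlogram, autocorrelate, cross_correlate,
                                     divergence_field, extract_trace, find_period,
                                     kymograph, phase_shift, speed_series)
from dipolecycle.synthetic import DipoleFieldParams, gen_dipole_field, pinch_divergence


def make_field(vec_fn, extent=10.0, n_side=21, n_frames=1, dt=1.0):
    ax = np.linspace(-extent, extent, n_side)
    gx, gy = np.meshgrid(ax, ax)
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    u, v = vec_fn(pos[:, 0], pos[:, 1])
    frames = [dict(x=pos[:, 0], y=pos[:, 1], u=u, v=v) for _ in range(n_frames)]
    return VectorFieldSeries.from_frames(frames, dt=dt)


class TestDivergenceField:
    def test_uniform_field_has_zero_divergence(self):
        fs = make_field(lambda x, y: (np.full_like(x, 0.7), np.full_like(y, -0.3)))
        _, _, div = divergence_field(fs, grid_spacing=1.0)
        assert np.nanmax(np.abs(div)) < 1e-10

    def test_pure_dilation_gives_2k(self):
        k = 0.05
        fs = make_field(lambda x, y: (k * x, k * y))
        _, _, div = divergence_field(fs, grid_spacing=1.0)
        assert np.nanmean(div) == pytest.approx(2 * k, rel=1e-6)

    def test_gaussian_sink_matches_closed_form(self):
        sigma = 5.0
        params = DipoleFieldParams(center_a=(0.0, 0.0), center_b=(60.0, 60.0),
                                   kernel_width=sigma, noise_sd=0.0, amplitude=1.0,
                                   anisotropy=0.0, duration=1.0, dt=1.0,
                                   sampling="grid", n_samples=3600, extent=15.0)
        fs = gen_dipole_field(params)
        xs, ys, div = divergence_field(fs, grid_spacing=sigma / 4)
        gx, gy = np.meshgrid(xs, ys)
        pos = np.column_stack([gx.ravel(), gy.ravel()])
        rate = params.amplitude * np.pi / params.period
        expected = rate * pinch_divergence(pos, np.zeros(2), sigma)
        got = div[0].ravel()
        # the radial sink diverges like -1/r at the center; compare away from it
        r = np.hypot(pos[:, 0], pos[:, 1])
        ok = np.isfinite(got) & (r > 2.0) & (r < 12.0)
        rms = np.sqrt(np.mean((got[ok] - expected[ok]) ** 2))
        scale = np.max(np.abs(expected[ok]))  # peak divergence magnitude
        assert rms / scale < 0.05

    def test_degenerate_geometry_rejected(self):
        n = 30
        frames = [dict(x=np.linspace(0, 1, n), y=np.zeros(n),
                       u=np.zeros(n), v=np.zeros(n))]
        fs = VectorFieldSeries.from_frames(frames, dt=1.0)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            divergence_field(fs)


class TestCorrelograms:
    def test_autocorrelation_normalization_and_symmetry(self, rng):
        x = rng.normal(size=200)
        c = autocorrelate(x, dt=1.0)
        i0 = np.argmin(np.abs(c.lags))
        assert c.values[i0] == pytest.approx(1.0)
        np.testing.assert_allclose(c.values, c.values[::-1], atol=1e-12)
        assert np.max(np.abs(c.values)) <= 1.0 + 1e-12

    def test_white_noise_correlations_are_small(self):
        n = 400
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=n)
            _, vals = autocorrelate(x, dt=1.0).positive()
            assert np.mean(np.abs(vals) < 3 / np.sqrt(n)) > 0.95

    def test_cosine_peak_at_period(self):
        t = np.arange(0, 100)
        c = autocorrelate(np.cos(2 * np.pi * t / 10), dt=1.0)
        lags, vals = c.positive()
        first_peak = lags[
            next(i for i in range(1, len(vals) - 1)
                 if vals[i] > vals[i - 1] and vals[i] >= vals[i + 1])
        ]
        assert first_peak == 10

    def test_constant_trace_is_handled(self):
        c = autocorrelate(np.full(50, 3.7), dt=1.0)
        est = find_period(c)
        assert not est.found

    def test_cross_correlation_symmetry(self, rng):
        f = rng.normal(size=120)
        g = rng.normal(size=120)
        cf = oscillation._corr(f, g, 1.0)
        cg = oscillation._corr(g, f, 1.0)
        np.testing.assert_allclose(cf.values, cg.values[::-1], atol=1e-12)


class TestFindPeriod:
    def test_cosine_period_recovered(self):
        t = np.arange(0, 60)
        est = find_period(autocorrelate(np.cos(2 * np.pi * t / 10), dt=1.0))
        assert est.period == pytest.approx(10.0)

    def test_white_noise_false_positive_rate(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            x = np.random.default_rng(10_000 + seed).normal(size=72)
            if find_period(autocorrelate(x, dt=0.5)).found:
                hits += 1
        assert hits / n_rep < 0.10

    def test_noisy_period_recovery(self):
        from dipolecycle.synthetic import gen_divergence_trace

        for seed in range(20):
            _, v = gen_divergence_trace(5.0, amplitude=1.0, noise_sd=0.2,
                                        duration=36.0, dt=0.5, seed=seed)
            est = find_period(autocorrelate(v, dt=0.5))
            assert est.found and est.period == pytest.approx(5.0, abs=0.5)

    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-5.0, 5.0))
    def test_invariant_to_scaling_and_offset(self, scale, offset):
        t = np.arange(0, 80)
        x = np.cos(2 * np.pi * t / 8) + 0.1 * np.sin(2 * np.pi * t / 3.1)
        base = find_period(autocorrelate(x, dt=1.0))
        mod = find_period(autocorrelate(scale * x + offset, dt=1.0))
        assert mod.period == base.period


class TestCrossCorrelateLag:
    def test_identical_traces_zero_lag(self, rng):
        x = rng.normal(size=100)
        lag, _ = cross_correlate(x, x, dt=1.0)
        assert lag == 0.0

    def test_shifted_trace_lag(self, rng):
        x = rng.normal(size=100)
        y = np.roll(x, 4)  # y repeats x four samples later -> x leads
        lag, _ = cross_correlate(x, y, dt=1.0, max_lag=20)
        assert lag == pytest.approx(4.0)

    @pytest.mark.parametrize("lag_true", [0.0, 2.0, -2.0])
    def test_sinusoid_lag_sign(self, lag_true):
        t = np.arange(0, 48, 0.5)
        front = np.cos(2 * np.pi * t / 8)
        back = np.cos(2 * np.pi * (t - lag_true) / 8)
        lag, _ = cross_correlate(front, back, dt=0.5, max_lag=4.0)
        assert lag == pytest.approx(lag_true, abs=0.5)


class TestPhaseShift:
    @pytest.mark.parametrize(
        "lag,period,expected",
        [(0.0, 8.0, 0.0), (4.0, 8.0, np.pi), (2.0, 8.0, np.pi / 2),
         (-2.0, 8.0, -np.pi / 2), (6.0, 8.0, -np.pi / 2)],
    )
    def test_wrapping(self, lag, period, expected):
        assert phase_shift(lag, period) == pytest.approx(expected)

    def test_rejects_bad_period(self):
        with pytest.raises(ValueError):
            phase_shift(1.0, 0.0)


class TestKymograph:
    def test_in_phase_dipoles_give_stationary_alternating_bands(self):
        params = DipoleFieldParams(phase_shift=0.0, noise_sd=0.0, duration=16.0,
                                   dt=1.0, n_samples=400, sampling="grid", extent=25.0)
        fs = gen_dipole_field(params)
        from dipolecycle.pipeline import _geometry_for

        geom = _geometry_for(params, fs.n_frames)
        kymo = kymograph(divergence_field(fs, grid_spacing=2.0), geom, dt=1.0)
        front = extract_trace(kymo, 7.5)
        # sign flips every half period: values T/2 apart anticorrelate
        half = int(params.period / 2)
        prod = front.values[:-half] * front.values[half:]
        assert np.mean(prod) < 0
        # and the two bands are synchronous (in phase)
        back = extract_trace(kymo, -7.5)
        lag, _ = cross_correlate(front, back, max_lag=params.period / 2)
        assert lag == pytest.approx(0.0, abs=1.0)

    def test_empty_region_rejected(self):
        kymo = oscillation.Kymograph(
            positions=np.arange(-5.0, 6.0), times=np.arange(4.0),
            values=np.zeros((11, 4)),
        )
        with pytest.raises(ValueError, match="empty region"):
            extract_trace(kymo, 40.0)


class TestSpeedSeries:
    def test_constant_velocity_track(self):
        t = np.arange(20)
        pos = np.column_stack([0.3 * t, np.zeros_like(t, dtype=float)])
        s = speed_series(pos, axis=(1, 0), dt=1.0)
        np.testing.assert_allclose(s.instantaneous, 0.3, atol=1e-12)
        assert s.persistent_speed == pytest.approx(0.3)

    def test_back_and_forth_has_zero_persistent_speed(self):
        t = np.arange(0, 32.5, 0.5)  # whole number of periods, ends where it began
        pos = np.column_stack([np.sin(2 * np.pi * t / 8), np.zeros_like(t)])
        s = speed_series(pos, axis=(1, 0), dt=0.5)
        assert s.persistent_speed < 1e-10
        assert s.period.found and s.period.period == pytest.approx(8.0, abs=0.5)
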