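import numpy as np
import pytest
from hypothesis import given, strategies as st

from dipolecycle import multipole
from dipolecycle.fields import CellGeometrySeries
from dipolecycle.multipole import (cycle_area, dipole_alignment, dipole_tensor,
                                   dq_trajectory, principal_components,
                                   quadrupole_tensor, shoelace_area)
from dipolecycle.pipeline import _geometry_for
from dipolecycle.synthetic import DipoleFieldParams, gen_dipole_field


class TestHandSummableMoments:
    """Worked 2-4 point fields, expected values from explicit summation."""

    def test_isotropic_contraction(self):
        pos = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        rates = -0.1 * pos
        s = dipole_tensor(pos, rates, (0.0, 0.0))
        np.testing.assert_allclose(s, np.diag([-0.2, -0.2]), atol=1e-15)

    def test_rigid_rotation_has_zero_symmetrized_dipole(self):
        pos = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        omega = 0.3
        rates = omega * np.column_stack([-pos[:, 1], pos[:, 0]])  # w x Delta
        s = dipole_tensor(pos, rates, (0.0, 0.0))
        np.testing.assert_allclose(s, 0.0, atol=1e-15)

    def test_mirror_symmetric_pinch(self):
        pos = np.array([[2.0, 0.0], [-2.0, 0.0]])
        rates = np.array([[-0.1, 0.0], [0.1, 0.0]])
        s = dipole_tensor(pos, rates, (0.0, 0.0))
        q = quadrupole_tensor(pos, rates, (0.0, 0.0))
        assert s[0, 0] == pytest.approx(-0.4)
        assert q[0, 0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_off_center_pinch(self):
        pos = np.array([[1.0, 0.0], [3.0, 0.0]])
        rates = np.array([[0.1, 0.0], [-0.1, 0.0]])
        s = dipole_tensor(pos, rates, (0.0, 0.0))
        q = quadrupole_tensor(pos, rates, (0.0, 0.0))
        assert s[0, 0] == pytest.approx(-0.2)
        assert q[0, 0, 0] == pytest.approx(-0.8)

    def test_zero_field_zero_moments(self):
        pos = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]])
        z = np.zeros_like(pos)
        np.testing.assert_array_equal(dipole_tensor(pos, z, (0, 0)), 0.0)
        np.testing.assert_array_equal(quadrupole_tensor(pos, z, (0, 0)), 0.0)

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dipole_tensor(np.empty((0, 2)), np.empty((0, 2)), (0, 0))


class TestTensorProperties:
    def make(self, seed, n=40):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-5, 5, (n, 2))
        rates = rng.normal(size=(n, 2))
        return pos, rates

    def test_dipole_exactly_symmetric(self):
        pos, rates = self.make(0)
        s = dipole_tensor(pos, rates, (1.0, -2.0))
        assert s[0, 1] == s[1, 0]

    def test_translation_covariance(self):
        pos, rates = self.make(1)
        t = np.array([3.3, -7.1])
        s0 = dipole_tensor(pos, rates, (0.5, 0.5))
        s1 = dipole_tensor(pos + t, rates, np.array([0.5, 0.5]) + t)
        np.testing.assert_allclose(s0, s1, atol=1e-10)
        q0 = quadrupole_tensor(pos, rates, (0.5, 0.5))
        q1 = quadrupole_tensor(pos + t, rates, np.array([0.5, 0.5]) + t)
        np.testing.assert_allclose(q0, q1, atol=1e-9)

    def test_linearity_in_the_field(self):
        pos, ra = self.make(2)
        _, rb = self.make(3)
        sa = dipole_tensor(pos, ra, (0, 0))
        sb = dipole_tensor(pos, rb, (0, 0))
        sab = dipole_tensor(pos, ra + rb, (0, 0))
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)

    @given(lam=st.floats(0.1, 10.0))
    def test_field_scaling(self, lam):
        pos, rates = self.make(4)
        s1 = dipole_tensor(pos, rates, (0, 0))
        s2 = dipole_tensor(pos, lam * rates, (0, 0))
        np.testing.assert_allclose(s2, lam * s1, rtol=1e-12)
        q1 = quadrupole_tensor(pos, rates, (0, 0))
        q2 = quadrupole_tensor(pos, lam * rates, (0, 0))
        np.testing.assert_allclose(q2, lam * q1, rtol=1e-12)


class TestPrincipalComponents:
    def test_anisotropic_dipole(self):
        s = np.diag([-5.0, 1.0])
        d, q, axis, _, degen = principal_components(s, np.zeros((2, 2, 2)), (1, 0))
        assert d == -5.0
        np.testing.assert_allclose(np.abs(axis), [1.0, 0.0], atol=1e-12)
        assert not degen

    def test_signed_rule(self):
        s = np.diag([-5.0, 1.0])
        d, *_ = principal_components(s, np.zeros((2, 2, 2)), (1, 0), eigen_rule="signed")
        assert d == 1.0

    def test_isotropic_dipole_flagged_degenerate(self):
        s = -2.0 * np.eye(2)
        d, _, _, _, degen = principal_components(s, np.zeros((2, 2, 2)), (1, 0))
        assert abs(d) == pytest.approx(2.0)
        assert degen

    def test_quadrupole_contraction_along_axis(self):
        q = np.zeros((2, 2, 2))
        q[0, 0, 0] = -0.8
        _, qval, _, _, _ = principal_components(np.eye(2), q, (1, 0))
        assert qval == pytest.approx(-0.8)

    def test_synthetic_dipole_axis_matches_center_line(self):
        # frames within the contraction half-cycle, where the pinches are active
        params = DipoleFieldParams(noise_sd=0.01, duration=1.0, dt=0.5,
                                   n_samples=600, seed=8)
        fs = gen_dipole_field(params)
        geom = _geometry_for(params, fs.n_frames)
        frames = next(iter(dq_trajectory(fs, geom).values()))
        line = np.array(params.center_a) - np.array(params.center_b)
        line = line / np.hypot(*line)
        for fr in frames:
            ang = np.degrees(np.arccos(abs(np.clip(fr.dipole_axis @ line, -1, 1))))
            assert ang < 10.0


class TestDipoleAlignment:
    def test_parallel_and_perpendicular(self):
        fr = lambda ax: multipole.MultipoleFrame(
            s=np.eye(2), q_tensor=np.zeros((2, 2, 2)), main_dipole=1.0,
            main_quadrupole=0.0, dipole_axis=np.asarray(ax, float),
            quadrupole_axis=np.array([1.0, 0.0]), center=np.zeros(2),
        )
        angles = dipole_alignment([fr((1, 0)), fr((0, 1))], (1, 0))
        assert angles[0] == pytest.approx(0.0)
        assert angles[1] == pytest.approx(90.0)


class TestCycleArea:
    def test_ellipse_area(self):
        t = np.linspace(0, 2 * np.pi, 101)[:-1]  # 100 samples/cycle
        a, b = 3.0, 0.7
        res = cycle_area(a * np.cos(t), b * np.sin(t), period=100.0, dt=1.0)
        assert res.absolute_area == pytest.approx(np.pi * a * b, rel=0.01)
        assert 0 <= res.normalized_area <= 100

    def test_collinear_trajectory_zero_area(self):
        d = np.linspace(-1, 1, 50)
        res = cycle_area(d, 2.5 * d, period=50.0, dt=1.0)
        assert res.absolute_area == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cycle_area(np.arange(3.0), np.arange(3.0), period=3.0, dt=1.0)

    def test_area_scales_quadratically_with_field(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        d, q = np.cos(t), np.sin(t)
        a1 = cycle_area(d, q, 64.0, dt=1.0).absolute_area
        a2 = cycle_area(3 * d, 3 * q, 64.0, dt=1.0).absolute_area
        assert a2 == pytest.approx(9 * a1, rel=1e-9)

    def test_shoelace_square(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert shoelace_area(x, y) == pytest.approx(1.0)
        assert shoelace_area(x[::-1], y[::-1]) == pytest.approx(-1.0)


class TestDQTrajectory:
    def test_in_phase_field_quadrupole_stays_small(self):
        params = DipoleFieldParams(phase_shift=0.0, noise_sd=0.0, duration=8.0,
                                   dt=0.5, n_samples=800, sampling="grid", seed=2)
        fs = gen_dipole_field(params)
        geom = _geometry_for(params, fs.n_frames)
        frames = next(iter(dq_trajectory(fs, geom).values()))
        d = np.array([f.main_dipole for f in frames])
        q = np.array([f.main_quadrupole for f in frames])
        # symmetric in-phase pinches: Q vanishes relative to D x length scale
        assert np.max(np.abs(q)) < 0.05 * np.max(np.abs(d)) * params.separation

    def test_phase_shifted_field_opens_a_cycle(self):
        common = dict(noise_sd=0.0, duration=16.0, dt=1.0, n_samples=400,
                      sampling="grid", seed=2)
        areas = {}
        for psi in (0.0, np.pi / 2):
            params = DipoleFieldParams(phase_shift=psi, **common)
            fs = gen_dipole_field(params)
            geom = _geometry_for(params, fs.n_frames)
            frames = next(iter(dq_trajectory(fs, geom).values()))
            d = np.array([f.main_dipole for f in frames])
            q = np.array([f.main_quadrupole for f in frames])
            areas[psi] = cycle_area(d, q, params.period, dt=params.dt).normalized_area
        assert areas[np.pi / 2] > 5 * areas[0.0]

    def test_cutoff_radius_limits_samples(self):
        params = DipoleFieldParams(noise_sd=0.0, duration=2.0, dt=1.0,
                                   n_samples=500, seed=5)
        fs = gen_dipole_field(params)
        geom = _geometry_for(params, fs.n_frames)
        dq = dq_trajectory(fs, geom, cutoff_radii=[10.0, 30.0])
        d10 = dq[10.0][0].main_dipole
        d30 = dq[30.0][0].main_dipole
        assert d10 != d30  # fewer samples inside the smaller radius

    def test_single_frame_single_point(self):
        params = DipoleFieldParams(noise_sd=0.0, duration=0.5, dt=1.0, n_samples=100)
        fs = gen_dipole_field(params)
        geom = _geometry_for(params, fs.n_frames)
        frames = next(iter(dq_trajectory(fs, geom).values()))
        assert len(frames) == 1
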