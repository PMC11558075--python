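"""Unit and property tests for the deterministic circuit model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pdcircuit as pc


def sigmoid_reference(u, m, b):
    """Independent scalar evaluation of the activation closed form."""
    import math

    return m * b / ((m - b) * math.exp(-4.0 * u / m) + b)


class TestActivation:
    def test_zero_input_returns_baseline(self):
        assert pc.activation(0.0, 300.0, 25.0) == pytest.approx(25.0)
        assert pc.activation(0.0, 400.0, 65.0) == pytest.approx(65.0)

    def test_saturates_at_maximum(self):
        assert pc.activation(1e6, 300.0, 25.0) == pytest.approx(300.0, rel=1e-12)

    def test_matches_scalar_reference(self):
        # frozen against the independent closed-form evaluation
        assert pc.activation(50.0, 300.0, 25.0) == pytest.approx(
            sigmoid_reference(50.0, 300.0, 25.0), rel=1e-12
        )
        assert sigmoid_reference(50.0, 300.0, 25.0) == pytest.approx(45.12915, abs=1e-4)

    @given(st.floats(-1e3, 1e3))
    def test_output_strictly_inside_range(self, u):
        # beyond |u| ~ 1e3 the closed form saturates to M in float arithmetic
        f = pc.activation(u, 300.0, 25.0)
        assert 0.0 < f < 300.0

    @given(st.floats(-500.0, 500.0), st.floats(1e-3, 10.0))
    def test_strictly_increasing(self, u, step):
        assert pc.activation(u + step, 300.0, 25.0) > pc.activation(u, 300.0, 25.0)

    @given(st.floats(-300.0, 300.0))
    def test_slope_matches_finite_difference(self, u):
        eps = 1e-5
        numeric = (pc.activation(u + eps, 300.0, 25.0) - pc.activation(u - eps, 300.0, 25.0)) / (
            2 * eps
        )
        assert pc.activation_slope(u, 300.0, 25.0) == pytest.approx(numeric, rel=1e-5, abs=1e-10)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            pc.activation(np.nan, 300.0, 25.0)
        with pytest.raises(ValueError):
            pc.activation(0.0, 25.0, 300.0)


class TestDrift:
    def test_matches_hand_coded_equations(self):
        # independent evaluation of the rate equations at (27, 41)
        w, c = pc.HEALTHY, pc.DEFAULT_CONSTANTS
        u_s = w.w_ss * 27.0 - w.w_sg * 41.0 + w.w_sc * c.crx
        u_g = w.w_gs * 27.0 - w.w_gg * 41.0 - w.input_str
        expected = np.array(
            [
                (-27.0 + sigmoid_reference(u_s, 300.0, 25.0)) / 0.006,
                (-41.0 + sigmoid_reference(u_g, 400.0, 65.0)) / 0.004,
            ]
        )
        np.testing.assert_allclose(pc.drift((27.0, 41.0), w), expected, rtol=1e-12)

    def test_positive_from_origin(self):
        d = pc.drift((0.0, 0.0), pc.HEALTHY)
        assert d[0] > 0 and d[1] > 0

    def test_vanishes_at_fixed_point(self):
        root = pc.fixed_point(pc.HEALTHY)
        assert np.linalg.norm(pc.drift(root, pc.HEALTHY)) < 1e-8


class TestFixedPoint:
    def test_agrees_with_long_time_simulation(self):
        root = pc.fixed_point(pc.HEALTHY)
        traj = pc.simulate_deterministic(pc.HEALTHY, t_end=3.0)
        np.testing.assert_allclose(
            [traj.x_s[-1], traj.x_g[-1]], root, atol=1e-4
        )

    def test_healthy_fixed_point_is_stable(self):
        root = pc.fixed_point(pc.HEALTHY)
        eig = pc.jacobian_eigenvalues(pc.HEALTHY, at=root)
        assert eig[0].real < 0 and eig[1].real < 0

    def test_multistart_finds_all_pd_roots(self):
        roots = pc.find_fixed_points(pc.PARKINSONIAN)
        # only one (unstable) fixed point survives beyond the fold
        assert len(roots) == 1
        eig = pc.jacobian_eigenvalues(pc.PARKINSONIAN, at=roots[0])
        assert eig[0].real > 0


class TestJacobian:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        w = pc.ConnectionWeights.from_array(10 ** rng.uniform(-1, 1.5, 6))
        at = rng.uniform([5, 5], [200, 300])
        analytic = pc.jacobian(w, at=at)
        eps = 1e-6
        numeric = np.empty((2, 2))
        for j in range(2):
            hi = at.copy()
            lo = at.copy()
            hi[j] += eps
            lo[j] -= eps
            numeric[:, j] = (pc.drift(hi, w) - pc.drift(lo, w)) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-4)


class TestSimulation:
    def test_healthy_is_monostable_non_oscillatory(self):
        for x0 in [(5.0, 5.0), (150.0, 200.0), (280.0, 380.0)]:
            traj = pc.simulate_deterministic(pc.HEALTHY, x0=x0, t_end=2.0)
            met = pc.oscillation_metrics(traj)
            assert not met.is_oscillatory
            root = pc.fixed_point(pc.HEALTHY)
            np.testing.assert_allclose([traj.x_s[-1], traj.x_g[-1]], root, atol=1e-3)

    def test_pd_limit_cycle_in_beta_band(self, pd_deterministic_trajectory):
        met = pc.oscillation_metrics(pd_deterministic_trajectory)
        assert met.is_oscillatory
        assert 12.0 <= met.frequency <= 30.0
        assert met.amplitude_g > 10.0

    def test_constant_when_started_at_fixed_point(self):
        root = pc.fixed_point(pc.HEALTHY)
        traj = pc.simulate_deterministic(pc.HEALTHY, x0=root, t_end=1.5)
        assert np.abs(traj.x_s - root[0]).max() < 1e-3
        assert np.abs(traj.x_g - root[1]).max() < 1e-3

    def test_states_respect_bounds(self, pd_deterministic_trajectory):
        c = pc.DEFAULT_CONSTANTS
        t = pd_deterministic_trajectory
        assert t.x_s.min() >= 0 and t.x_s.max() <= c.m_s
        assert t.x_g.min() >= 0 and t.x_g.max() <= c.m_g


class TestOscillationMetrics:
    def test_constant_trajectory(self):
        times = np.arange(0, 3, 1e-3)
        traj = pc.Trajectory(times, np.full_like(times, 20.0), np.full_like(times, 60.0))
        met = pc.oscillation_metrics(traj)
        assert not met.is_oscillatory
        assert np.isnan(met.frequency)
        assert met.amplitude_s == 0.0 and met.amplitude_g == 0.0

    def test_recovers_injected_sinusoid_frequency(self):
        dt = 1e-3
        times = np.arange(0, 5, dt)
        x = 50 + 10 * np.sin(2 * np.pi * 20.0 * times)
        traj = pc.Trajectory(times, x, x)
        met = pc.oscillation_metrics(traj)
        assert met.is_oscillatory
        bin_width = 1.0 / (4.0 - dt)
        assert abs(met.frequency - 20.0) < bin_width

    def test_too_short_raises(self):
        times = np.arange(0, 1.5, 1e-3)
        traj = pc.Trajectory(times, times, times)
        with pytest.raises(ValueError):
            pc.oscillation_metrics(traj, transient=1.0)


class TestTrajectory:
    def test_csv_round_trip(self, tmp_path):
        traj = pc.simulate_deterministic(pc.HEALTHY, t_end=0.1, dt_out=1e-3)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = pc.Trajectory.from_csv(path)
        np.testing.assert_allclose(back.x_g, traj.x_g, rtol=1e-12)

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            pc.Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros(3), np.zeros(3))
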