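"""Tests of the Langevin simulator, stationary Fokker-Planck solve, flux and
entropy production, against closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

import pdcircuit as pc


def rotational_ou(a=3.0, omega=6.0, d=0.5):
    """Linear system with a rotational (detailed-balance-breaking) drift.

    Everything about it is available in closed form: stationary covariance
    from the Lyapunov equation, flux velocity (A + D S^-1) x, and
    EPR = tr(M^T M S) / D with M = A + D S^-1.
    """
    a_mat = np.array([[-a, -omega], [omega, -a]])
    sigma = solve_continuous_lyapunov(a_mat, -2 * d * np.eye(2))
    m = a_mat + d * np.linalg.inv(sigma)
    epr = float(np.trace(m.T @ m @ sigma) / d)
    drift = lambda x, y: (a_mat[0, 0] * x + a_mat[0, 1] * y, a_mat[1, 0] * x + a_mat[1, 1] * y)
    return drift, sigma, epr, d


class TestLangevin:
    def test_same_seed_bitwise_identical(self):
        a = pc.simulate_langevin(pc.HEALTHY, t_end=0.5, seed=11)
        b = pc.simulate_langevin(pc.HEALTHY, t_end=0.5, seed=11)
        assert np.array_equal(a.x_s, b.x_s) and np.array_equal(a.x_g, b.x_g)
        c = pc.simulate_langevin(pc.HEALTHY, t_end=0.5, seed=12)
        assert not np.array_equal(a.x_g, c.x_g)

    def test_vanishing_noise_recovers_deterministic_path(self):
        # compare after the fast initial relaxation (where the fixed-step
        # Euler scheme and the adaptive reference differ at any D)
        det = pc.simulate_deterministic(pc.HEALTHY, t_end=1.0, dt_out=5e-4)
        dev = []
        for d in (1e-2, 1e-6):
            sto = pc.simulate_langevin(pc.HEALTHY, noise=pc.NoiseModel(d), t_end=1.0, seed=3)
            dev.append(np.abs(sto.x_g[-1000:] - det.x_g[-1000:]).max())
        assert dev[1] < dev[0]
        assert dev[1] < 0.01

    def test_mean_matches_fixed_point(self):
        root = pc.fixed_point(pc.HEALTHY)
        traj = pc.simulate_langevin(pc.HEALTHY, t_end=6.0, seed=21).after(1.0)
        assert abs(traj.x_s.mean() - root[0]) < 0.1
        assert abs(traj.x_g.mean() - root[1]) < 0.1

    def test_paths_respect_reflecting_bounds(self):
        traj = pc.simulate_langevin(
            pc.PARKINSONIAN, noise=pc.NoiseModel(50.0), t_end=2.0, seed=5
        )
        c = pc.DEFAULT_CONSTANTS
        assert traj.x_s.min() >= 0 and traj.x_s.max() <= c.m_s
        assert traj.x_g.min() >= 0 and traj.x_g.max() <= c.m_g

    def test_step_size_guard(self):
        with pytest.raises(ValueError):
            pc.simulate_langevin(pc.HEALTHY, dt=0.01)


class TestStationaryDensity:
    def test_boltzmann_closed_form_double_well(self):
        d = 0.5
        drift = lambda x, y: (-4 * x * (x**2 - 1), -2 * y)
        grid = pc.GridSpec(-2, 2, 100, -2, 2, 100)
        p = pc.stationary_density(drift, grid, d)
        X, Y = grid.meshgrid()
        v = (X**2 - 1) ** 2 + Y**2
        boltz = np.exp(-v / d)
        boltz /= boltz.sum()
        assert np.abs(p - boltz).sum() < 0.01  # L1 distance between mass arrays

    def test_healthy_density_unimodal_at_fixed_point(self, healthy_landscape):
        density, _, _ = healthy_landscape
        root = pc.fixed_point(pc.HEALTHY)
        i, j = np.unravel_index(np.argmax(density.p_ss), density.p_ss.shape)
        assert abs(density.grid.xs[i] - root[0]) < 5 * density.grid.hx
        assert abs(density.grid.ys[j] - root[1]) < 5 * density.grid.hy
        assert density.p_ss.min() >= 0
        assert density.p_ss.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pd_density_concentrates_on_ring(self, pd_landscape):
        density, _, _ = pd_landscape
        # probability at the (unstable) interior fixed point is far below
        # the ridge of the limit-cycle ring
        root = pc.find_fixed_points(pc.PARKINSONIAN)[0]
        grid = density.grid
        i = int((root[0] - grid.x_min) / grid.hx)
        j = int((root[1] - grid.y_min) / grid.hy)
        assert density.p_ss[i, j] < 0.01 * density.p_ss.max()
        # extended support: mass spread over hundreds of cells
        assert (density.p_ss > 1e-6).sum() > 500

    def test_potential_is_minus_log_density(self, healthy_landscape):
        density, _, _ = healthy_landscape
        mask = density.p_ss > 1e-9
        np.testing.assert_allclose(
            density.u[mask], -np.log(density.density[mask]), rtol=1e-10
        )

    def test_coverage_validation_rejects_tiny_window(self):
        grid = pc.GridSpec(100.0, 110.0, 10, 100.0, 110.0, 10)
        with pytest.raises(ValueError):
            pc.steady_state_density(pc.HEALTHY, grid=grid, validate_coverage=True)

    def test_langevin_histogram_matches_fokker_planck(self):
        """Oracle equivalence: JS divergence between the discretised
        stationary solve and a long Langevin histogram below 0.05."""
        auto = pc.steady_state_density(pc.HEALTHY)
        grid = pc.GridSpec(
            auto.grid.x_min, auto.grid.x_max, 100, auto.grid.y_min, auto.grid.y_max, 100
        )
        density = pc.steady_state_density(pc.HEALTHY, grid=grid)
        times, s, g = pc.simulate_langevin_ensemble(
            pc.HEALTHY, t_end=21.0, seed=9, n_realizations=10, stride=4
        )
        keep = times > 1.0
        hist = pc.histogram_density(s[keep], g[keep], grid)
        js = pc.js_divergence(pc.coarsen(density.p_ss, (50, 50)), pc.coarsen(hist, (50, 50)))
        assert js < 0.05


class TestFluxAndEntropy:
    def test_equilibrium_system_has_no_flux_or_dissipation(self, equilibrium_landscape):
        _, flux, thermo = equilibrium_landscape
        assert thermo.epr >= 0
        assert thermo.mean_flux < 1.0
        assert thermo.epr < 1.0

    def test_equilibrium_negligible_against_pd(self, equilibrium_landscape, pd_landscape):
        _, _, eq = equilibrium_landscape
        _, _, pd = pd_landscape
        assert eq.epr < 0.01 * pd.epr
        assert eq.mean_flux < 0.01 * pd.mean_flux

    def test_epr_nonnegative_and_stationary_entropy_balance(
        self, healthy_landscape, pd_landscape
    ):
        for _, _, thermo in (healthy_landscape, pd_landscape):
            assert thermo.epr >= 0
            # at stationarity the system entropy rate vanishes: EPR ~ S_env
            assert abs(thermo.s_sys_rate) < 0.02 * thermo.epr

    def test_pd_flux_circulates_consistently(self, pd_landscape):
        density, flux, _ = pd_landscape
        X, Y = density.grid.meshgrid()
        cx = (X * density.p_ss).sum()
        cy = (Y * density.p_ss).sum()
        angular = (X - cx) * flux.j_g - (Y - cy) * flux.j_s
        consistency = abs(angular.sum()) / np.abs(angular).sum()
        assert consistency > 0.8  # one dominant rotation direction on the ring

    def test_divergence_free_on_resolved_system(self):
        drift, sigma, _, d = rotational_ou()
        sd = np.sqrt(np.diag(sigma))
        grid = pc.GridSpec(-6 * sd[0], 6 * sd[0], 120, -6 * sd[1], 6 * sd[1], 120)
        p = pc.stationary_density(drift, grid, d)
        density = pc.GridDensity(grid, p, -np.log(np.maximum(p / grid.cell_area, 1e-300)))
        flux = pc.flux_field(density, drift_fn=drift, noise=pc.NoiseModel(d))
        div = pc.flux_divergence(flux)[3:-3, 3:-3]
        scale = flux.magnitude.max() / min(grid.hx, grid.hy)
        assert np.abs(div).max() < 0.02 * scale

    def test_epr_grid_vs_analytic_and_trajectory(self):
        """Three routes to the EPR of the rotational OU system agree:
        the grid formula, the closed form, and a Monte-Carlo average of
        |J/P|^2 / D along a long simulated path."""
        drift, sigma, epr_exact, d = rotational_ou()
        sd = np.sqrt(np.diag(sigma))
        grid = pc.GridSpec(-6 * sd[0], 6 * sd[0], 120, -6 * sd[1], 6 * sd[1], 120)
        p = pc.stationary_density(drift, grid, d)
        density = pc.GridDensity(grid, p, -np.log(np.maximum(p / grid.cell_area, 1e-300)))
        flux = pc.flux_field(density, drift_fn=drift, noise=pc.NoiseModel(d))
        thermo = pc.entropy_production_rate(density, flux, pc.NoiseModel(d))
        assert thermo.epr == pytest.approx(epr_exact, rel=0.05)
        _, x, y = pc.simulate_sde(drift, d, (0.0, 0.0), 150.0, 1e-3, seed=4)
        ix = np.clip(((x - grid.x_min) / grid.hx).astype(int), 0, grid.nx - 1)
        iy = np.clip(((y - grid.y_min) / grid.hy).astype(int), 0, grid.ny - 1)
        rho = density.density[ix, iy]
        ok = rho > 1e-12
        mc = np.mean(
            (flux.j_s[ix, iy][ok] ** 2 + flux.j_g[ix, iy][ok] ** 2) / rho[ok] ** 2
        ) / d
        assert mc == pytest.approx(epr_exact, rel=0.10)

    def test_circuit_epr_matches_linearisation_at_small_k(self, healthy_landscape):
        _, _, thermo = healthy_landscape
        assert thermo.epr == pytest.approx(pc.linearized_epr(pc.HEALTHY), rel=0.15)

    def test_mean_flux_stable_under_grid_refinement(self):
        coarse = pc.steady_state_density(
            pc.PARKINSONIAN, grid=pc.GridSpec(0, 300, 120, 0, 400, 160)
        )
        fine = pc.steady_state_density(
            pc.PARKINSONIAN, grid=pc.GridSpec(0, 300, 150, 0, 400, 200)
        )
        j_coarse = pc.mean_flux(coarse, pc.flux_field(coarse, pc.PARKINSONIAN))
        j_fine = pc.mean_flux(fine, pc.flux_field(fine, pc.PARKINSONIAN))
        assert j_coarse == pytest.approx(j_fine, rel=0.10)
        # the point attractor's location in U is grid-stable (the ring's
        # ridge peak is degenerate along the cycle, so the healthy state
        # is the meaningful location check)
        auto = pc.steady_state_density(pc.HEALTHY)
        win = auto.grid
        peaks = []
        for cells in (100, 150):
            grid = pc.GridSpec(win.x_min, win.x_max, cells, win.y_min, win.y_max, cells)
            dens = pc.steady_state_density(pc.HEALTHY, grid=grid)
            i, j = np.unravel_index(np.argmax(dens.p_ss), dens.p_ss.shape)
            peaks.append((grid.xs[i], grid.ys[j], grid.hx, grid.hy))
        (x1, y1, hx1, hy1), (x2, y2, _, _) = peaks
        assert abs(x1 - x2) <= hx1 and abs(y1 - y2) <= hy1

    def test_unweighted_mean_flux_option(self, pd_landscape):
        density, flux, _ = pd_landscape
        weighted = pc.mean_flux(density, flux, weighted=True)
        unweighted = pc.mean_flux(density, flux, weighted=False)
        assert weighted > 0 and unweighted > 0 and weighted != unweighted
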