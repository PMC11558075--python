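"""Non-equilibrium steady state of the stochastic circuit.

The stochastic dynamics are the Langevin equations dx/dt = F(x) + zeta with
Gaussian white noise of intensity 2D (isotropic).  The associated
Fokker-Planck equation has the stationary form

    div( F(x) P_ss(x) ) - D laplace( P_ss(x) ) = 0

with no-flux (reflecting) boundaries: firing rates cannot leave
[0, M_S] x [0, M_G].  From the stationary density this module derives

* the potential landscape  U = -ln P_ss,
* the probability flux     J = F P_ss - D grad P_ss  (divergence-free at
  stationarity; non-zero J is the signature of broken detailed balance),
* the entropy production rate  EPR = integral (J . J) / (D P_ss) dx  and the
  entropy flow to the environment  S_env = integral (J . F) / D dx,
* a scalar "mean flux", defined as integral |J| dx, i.e. the
  probability-weighted mean speed of the probability current.

Discretisation note: the stationary solve uses a finite-volume scheme with
Scharfetter-Gummel (exponential-fitting) face fluxes.  The drift here is
large compared with D on any affordable mesh (cell Peclet numbers in the
thousands), where central differencing produces negative masses and plain
upwinding is over-diffusive; exponential fitting remains positive and is
exact for one-dimensional gradient systems, so the Boltzmann limit is
recovered to discretisation error.

At the default noise level the fluctuations around a strongly stable fixed
point have sub-spikes/s standard deviation, far below any full-domain cell
size.  ``steady_state_density`` therefore zooms its mesh onto a window
around the fixed point (sized from the linearised covariance) whenever the
deterministic system is non-oscillatory, and falls back to the full state
box when a limit cycle is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import solve_continuous_lyapunov

from .model_core import (
    DEFAULT_CONSTANTS,
    ConnectionWeights,
    NucleusConstants,
    Trajectory,
    fixed_point,
    find_fixed_points,
    jacobian,
    make_drift_field,
)

__all__ = [
    "NoiseModel",
    "GridSpec",
    "GridDensity",
    "FluxField",
    "ThermoSummary",
    "simulate_langevin",
    "simulate_langevin_ensemble",
    "simulate_sde",
    "stationary_density",
    "steady_state_density",
    "flux_field",
    "flux_divergence",
    "mean_flux",
    "entropy_production_rate",
    "linearized_covariance",
    "linearized_epr",
    "histogram_density",
    "js_divergence",
    "coarsen",
]


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic diffusion coefficient D (spikes^2/s^3) per state dimension."""

    d: float = 5.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("diffusion coefficient must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular mesh of cell centers over a state-space window."""

    x_min: float
    x_max: float
    nx: int
    y_min: float
    y_max: float
    ny: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid window must have positive extent")
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid needs at least 4 cells per dimension")

    @property
    def hx(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def hy(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def xs(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.hx

    @property
    def ys(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.hy

    @property
    def cell_area(self) -> float:
        return self.hx * self.hy

    def meshgrid(self):
        return np.meshgrid(self.xs, self.ys, indexing="ij")

    @classmethod
    def full_state_space(
        cls, c: NucleusConstants = DEFAULT_CONSTANTS, nx: int = 150, ny: int = 200
    ) -> "GridSpec":
        return cls(0.0, c.m_s, nx, 0.0, c.m_g, ny)


@dataclass
class GridDensity:
    """Stationary probability mass per cell and the potential U = -ln P."""

    grid: GridSpec
    p_ss: np.ndarray  # probability mass per cell, sums to 1
    u: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def density(self) -> np.ndarray:
        """Probability density (mass / cell area)."""
        return self.p_ss / self.grid.cell_area


@dataclass
class FluxField:
    """Probability-flux components and the drift field on the same mesh."""

    grid: GridSpec
    j_s: np.ndarray
    j_g: np.ndarray
    f_s: np.ndarray
    f_g: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.j_s, self.j_g)


@dataclass(frozen=True)
class ThermoSummary:
    """Entropy budget of the non-equilibrium steady state (natural-log units, 1/s)."""

    epr: float
    s_env_rate: float
    s_sys_rate: float
    mean_flux: float
    excluded_mass: float


# ---------------------------------------------------------------------------
# Langevin simulation
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)  # guards rare double-crossings at large noise


def simulate_langevin_ensemble(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    x0: Sequence[float] | None = None,
    t_end: float = 10.0,
    dt: float = 5e-4,
    seed: int = 0,
    n_realizations: int = 1,
    stride: int = 1,
):
    """Euler-Maruyama integration of ``n_realizations`` independent paths.

    Reflecting boundaries keep rates inside [0, M].  Returns
    ``(times, x_s, x_g)`` with channel arrays of shape (n_samples,
    n_realizations).  Bitwise reproducible for a given seed.
    """
    if dt > c.tau_g / 4:
        raise ValueError("dt must satisfy dt <= tau_g / 4 for a stable scheme")
    if x0 is None:
        x0 = (c.b_s, c.b_g)
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    sqrt_term = np.sqrt(2.0 * noise.d * dt)
    field = make_drift_field(w, c)
    xs = np.full(n_realizations, float(x0[0]))
    xg = np.full(n_realizations, float(x0[1]))
    n_out = n_steps // stride
    out_s = np.empty((n_out, n_realizations))
    out_g = np.empty((n_out, n_realizations))
    times = np.empty(n_out)
    j = 0
    for i in range(n_steps):
        f_s, f_g = field(xs, xg)
        xs = _reflect(xs + dt * f_s + sqrt_term * rng.standard_normal(n_realizations), 0.0, c.m_s)
        xg = _reflect(xg + dt * f_g + sqrt_term * rng.standard_normal(n_realizations), 0.0, c.m_g)
        if (i + 1) % stride == 0:
            out_s[j] = xs
            out_g[j] = xg
            times[j] = (i + 1) * dt
            j += 1
    return times[:j], out_s[:j], out_g[:j]


def simulate_langevin(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    x0: Sequence[float] | None = None,
    t_end: float = 10.0,
    dt: float = 5e-4,
    seed: int = 0,
    stride: int = 1,
) -> Trajectory:
    """Single stochastic trajectory of the circuit (see ensemble variant)."""
    times, out_s, out_g = simulate_langevin_ensemble(
        w, c, noise, x0, t_end, dt, seed, n_realizations=1, stride=stride
    )
    meta = {"kind": "langevin", "seed": seed, "d": noise.d, "dt": dt}
    return Trajectory(times, out_s[:, 0], out_g[:, 0], meta)


def simulate_sde(
    drift_fn: Callable,
    d: float,
    x0: Sequence[float],
    t_end: float,
    dt: float,
    seed: int = 0,
    bounds: tuple | None = None,
):
    """Euler-Maruyama for an arbitrary 2-D drift (oracle systems in tests).

    ``drift_fn(x, y) -> (fx, fy)`` must accept arrays.  ``bounds`` is
    ((x_lo, x_hi), (y_lo, y_hi)) for reflecting boundaries, or None for an
    unbounded system.  Returns (times, x, y).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    s = np.sqrt(2.0 * d * dt)
    x, y = float(x0[0]), float(x0[1])
    xa = np.empty(n_steps)
    ya = np.empty(n_steps)
    noise = rng.standard_normal((n_steps, 2))
    for i in range(n_steps):
        fx, fy = drift_fn(x, y)
        x = x + dt * fx + s * noise[i, 0]
        y = y + dt * fy + s * noise[i, 1]
        if bounds is not None:
            (xlo, xhi), (ylo, yhi) = bounds
            x = float(_reflect(np.asarray(x), xlo, xhi))
            y = float(_reflect(np.asarray(y), ylo, yhi))
        xa[i] = x
        ya[i] = y
    return dt * (1 + np.arange(n_steps)), xa, ya


# ---------------------------------------------------------------------------
# Stationary Fokker-Planck solve
# ---------------------------------------------------------------------------


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (exp(z) - 1), numerically stable for all z."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-8
    out[small] = 1.0 - z[small] / 2.0
    big = z > 500.0
    out[big] = 0.0
    neg = z < -500.0
    out[neg] = -z[neg]
    mid = ~(small | big | neg)
    out[mid] = z[mid] / np.expm1(z[mid])
    return out


def stationary_density(drift_fn: Callable, grid: GridSpec, d: float) -> np.ndarray:
    """Stationary probability mass per cell of dx = F dt + sqrt(2D) dW.

    Finite-volume discretisation with Scharfetter-Gummel face fluxes and
    no-flux boundaries; the one-dimensional null space of the discrete
    generator is obtained from a direct sparse solve with the
    normalisation sum(P) = 1 replacing one redundant row.
    """
    nx, ny, hx, hy = grid.nx, grid.ny, grid.hx, grid.hy
    xs, ys = grid.xs, grid.ys
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    fx_face, _ = drift_fn((X[:-1, :] + X[1:, :]) / 2.0, Y[:-1, :])
    _, fy_face = drift_fn(X[:, :-1], (Y[:, :-1] + Y[:, 1:]) / 2.0)
    wx = np.asarray(fx_face) * hx / d
    wy = np.asarray(fy_face) * hy / d

    bxm, bxp = _bernoulli(-wx), _bernoulli(wx)
    bym, byp = _bernoulli(-wy), _bernoulli(wy)

    index = np.arange(nx * ny).reshape(nx, ny)
    rows, cols, vals = [], [], []

    # x-faces: flux_(i+1/2,j) = (D/hx) * (B(-w) P_i - B(w) P_{i+1});
    # generator entries are +-flux/hx into the two adjacent cells.
    left = index[:-1, :].ravel()
    right = index[1:, :].ravel()
    cx = d / hx / hx
    rows += [left, left, right, right]
    cols += [left, right, left, right]
    vals += [-cx * bxm.ravel(), cx * bxp.ravel(), cx * bxm.ravel(), -cx * bxp.ravel()]

    lower = index[:, :-1].ravel()
    upper = index[:, 1:].ravel()
    cy = d / hy / hy
    rows += [lower, lower, upper, upper]
    cols += [lower, upper, lower, upper]
    vals += [-cy * bym.ravel(), cy * byp.ravel(), cy * bym.ravel(), -cy * byp.ravel()]

    gen = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    ).tolil()
    gen[-1, :] = 1.0
    rhs = np.zeros(nx * ny)
    rhs[-1] = 1.0
    p = spla.spsolve(gen.tocsc(), rhs)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("stationary solve produced non-finite values")
    neg_mass = -p[p < 0].sum()
    if neg_mass > 1e-6:
        raise RuntimeError(f"stationary solve produced negative mass {neg_mass:.2e}")
    p = np.maximum(p, 0.0)
    p /= p.sum()
    return p.reshape(nx, ny)


def _auto_grid(
    w: ConnectionWeights,
    c: NucleusConstants,
    noise: NoiseModel,
    zoom_cells: int = 120,
    zoom_sigmas: float = 10.0,
) -> GridSpec:
    """Window selection: zoom onto a stable fixed point, else the full box."""
    stable = None
    for root in find_fixed_points(w, c):
        eig = np.linalg.eigvals(jacobian(w, c, root))
        if eig.real.max() < 0:
            stable = root
            break
    if stable is None:
        return GridSpec.full_state_space(c)
    a = jacobian(w, c, stable)
    sigma = solve_continuous_lyapunov(a, -2.0 * noise.d * np.eye(2))
    sd = np.sqrt(np.abs(np.diag(sigma)))
    half = np.maximum(zoom_sigmas * sd, 1.0)
    return GridSpec(
        max(stable[0] - half[0], 0.0),
        min(stable[0] + half[0], c.m_s),
        zoom_cells,
        max(stable[1] - half[1], 0.0),
        min(stable[1] + half[1], c.m_g),
        zoom_cells,
    )


def steady_state_density(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    grid: GridSpec | None = None,
    p_floor: float = 1e-12,
    validate_coverage: bool = False,
) -> GridDensity:
    """Stationary density, potential U = -ln P_ss for the circuit.

    With ``grid=None`` the mesh is chosen automatically (zoom window
    around a stable fixed point, full state box otherwise).  Optionally a
    short pilot Langevin run checks that the grid covers the attractor.
    """
    if grid is None:
        grid = _auto_grid(w, c, noise)
    field = make_drift_field(w, c)
    if validate_coverage:
        _, ps, pg = simulate_langevin_ensemble(
            w, c, noise, t_end=2.0, seed=7, n_realizations=4, stride=10
        )
        tail_s, tail_g = ps[len(ps) // 2 :], pg[len(pg) // 2 :]
        inside = (
            (tail_s >= grid.x_min) & (tail_s <= grid.x_max)
            & (tail_g >= grid.y_min) & (tail_g <= grid.y_max)
        )
        if inside.mean() < 0.99:
            raise ValueError(
                f"grid covers only {inside.mean():.1%} of a pilot run; enlarge the window"
            )
    p = stationary_density(field, grid, noise.d)
    u = -np.log(np.maximum(p / grid.cell_area, p_floor))
    meta = {"d": noise.d, "weights": w.as_array().tolist()}
    return GridDensity(grid, p, u, meta)


# ---------------------------------------------------------------------------
# Flux, entropy production
# ---------------------------------------------------------------------------


def flux_field(
    density: GridDensity,
    w: ConnectionWeights | None = None,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    drift_fn: Callable | None = None,
) -> FluxField:
    """Probability flux J = F P - D grad P by central differences.

    ``P`` here is the probability *density*; supply either circuit weights
    or an arbitrary ``drift_fn``.
    """
    if drift_fn is None:
        if w is None:
            raise ValueError("provide either weights or a drift function")
        drift_fn = make_drift_field(w, c)
    grid = density.grid
    X, Y = grid.meshgrid()
    f_s, f_g = drift_fn(X, Y)
    rho = density.density
    j_s = f_s * rho - noise.d * np.gradient(rho, grid.xs, axis=0)
    j_g = f_g * rho - noise.d * np.gradient(rho, grid.ys, axis=1)
    return FluxField(grid, j_s, j_g, np.asarray(f_s, float), np.asarray(f_g, float))


def flux_divergence(flux: FluxField) -> np.ndarray:
    """Discrete divergence of the flux field (should vanish in the interior)."""
    return np.gradient(flux.j_s, flux.grid.xs, axis=0) + np.gradient(
        flux.j_g, flux.grid.ys, axis=1
    )


def mean_flux(density: GridDensity, flux: FluxField, weighted: bool = True) -> float:
    """Scalar flux magnitude.

    ``weighted=True`` (default): integral |J| dx, the probability-weighted
    mean speed of the probability current (units 1/s after the spikes/s
    state scale).  ``weighted=False``: unweighted grid mean of |J|.
    """
    mag = flux.magnitude
    if weighted:
        return float(mag.sum() * flux.grid.cell_area)
    return float(mag.mean())


def entropy_production_rate(
    density: GridDensity,
    flux: FluxField,
    noise: NoiseModel = NoiseModel(),
    p_floor: float = 1e-12,
) -> ThermoSummary:
    """Entropy budget from the stationary density and flux.

    EPR = integral (J.J)/(D P) dx, the total dissipation rate; the
    environmental flow is integral (J.F)/D dx and the system entropy rate
    is their difference (approximately zero at stationarity).  Cells with
    density below ``p_floor`` are excluded and the excluded probability
    mass reported.
    """
    grid = density.grid
    rho = density.density
    mask = rho > p_floor
    area = grid.cell_area
    j2 = flux.j_s**2 + flux.j_g**2
    epr = float((j2[mask] / (noise.d * rho[mask])).sum() * area)
    s_env = float(
        ((flux.j_s * flux.f_s + flux.j_g * flux.f_g)[mask] / noise.d).sum() * area
    )
    if epr < 0:
        raise AssertionError("entropy production rate came out negative")
    excluded = float(density.p_ss[~mask].sum())
    return ThermoSummary(
        epr=epr,
        s_env_rate=s_env,
        s_sys_rate=epr - s_env,
        mean_flux=mean_flux(density, flux),
        excluded_mass=excluded,
    )


# ---------------------------------------------------------------------------
# Small-noise (Ornstein-Uhlenbeck) references
# ---------------------------------------------------------------------------


def linearized_covariance(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    at: Sequence[float] | None = None,
) -> np.ndarray:
    """Stationary covariance of the linearisation around a stable fixed point.

    Solves the Lyapunov equation A S + S A^T = -2D I.
    """
    if at is None:
        at = fixed_point(w, c)
    a = jacobian(w, c, at)
    if np.linalg.eigvals(a).real.max() >= 0:
        raise ValueError("linearized covariance requires a stable fixed point")
    return solve_continuous_lyapunov(a, -2.0 * noise.d * np.eye(2))


def linearized_epr(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    at: Sequence[float] | None = None,
) -> float:
    """Closed-form EPR of the linearised (Ornstein-Uhlenbeck) system.

    For dx = A x dt + sqrt(2D) dW with stationary covariance S, the flux
    velocity is (A + D S^-1) x and EPR = tr(M^T M S) / D with
    M = A + D S^-1.  Exact for the linear system; a small-noise reference
    for the full circuit.
    """
    if at is None:
        at = fixed_point(w, c)
    a = jacobian(w, c, at)
    s = linearized_covariance(w, c, noise, at)
    m = a + noise.d * np.linalg.inv(s)
    return float(np.trace(m.T @ m @ s) / noise.d)


# ---------------------------------------------------------------------------
# Density comparison helpers
# ---------------------------------------------------------------------------


def histogram_density(x: np.ndarray, y: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Empirical probability mass per grid cell from trajectory samples."""
    ex = np.linspace(grid.x_min, grid.x_max, grid.nx + 1)
    ey = np.linspace(grid.y_min, grid.y_max, grid.ny + 1)
    h, _, _ = np.histogram2d(np.ravel(x), np.ravel(y), bins=(ex, ey))
    total = h.sum()
    if total == 0:
        raise ValueError("no samples fall inside the grid")
    return h / total


def coarsen(p: np.ndarray, shape: tuple) -> np.ndarray:
    """Block-sum a mass array down to ``shape`` (factors must divide)."""
    nx, ny = p.shape
    cx, cy = shape
    if nx % cx or ny % cy:
        raise ValueError("coarse shape must divide the fine shape")
    return p.reshape(cx, nx // cx, cy, ny // cy).sum(axis=(1, 3))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between two mass arrays."""
    p = np.ravel(p) / np.sum(p)
    q = np.ravel(q) / np.sum(q)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
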