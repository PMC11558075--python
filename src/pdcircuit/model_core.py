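"""Mean-field firing-rate model of the STN-GPe circuit.

The model reduces the basal-ganglia beta-oscillation generator to two
coupled populations: the glutamatergic subthalamic nucleus (STN) and the
GABAergic external globus pallidus (GPe).  Each population is described by
its average firing rate, relaxing toward a sigmoidal activation of its net
synaptic input with a membrane-scale time constant:

    tau_S dx_S/dt = -x_S + f_S(w_SS x_S - w_SG x_G + w_SC Crx)
    tau_G dx_G/dt = -x_G + f_G(w_GS x_S - w_GG x_G - Input_Str)

``Crx`` is a constant cortical drive and ``Input_Str`` a constant
inhibitory striatal input to GPe (it therefore enters with a minus sign).
The activation function

    f(u) = M B / ((M - B) exp(-4 u / M) + B)

maps net input to a rate in (0, M) with ``f(0) = B``, the autonomous rate
at zero input.

Two fitted weight sets are shipped as module constants: ``HEALTHY``
produces a stable fixed point with no oscillation, ``PARKINSONIAN`` a
relaxation limit cycle in the low beta band (~13 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "NucleusConstants",
    "ConnectionWeights",
    "Trajectory",
    "OscillationMetrics",
    "DEFAULT_CONSTANTS",
    "HEALTHY",
    "PARKINSONIAN",
    "WEIGHT_NAMES",
    "activation",
    "activation_slope",
    "drift",
    "make_drift_field",
    "simulate_deterministic",
    "fixed_point",
    "find_fixed_points",
    "jacobian",
    "jacobian_eigenvalues",
    "oscillation_metrics",
    "dominant_frequency",
]

#: Order of the six connection parameters in array form.
WEIGHT_NAMES = ("w_sg", "w_sc", "w_gs", "w_gg", "input_str", "w_ss")


@dataclass(frozen=True)
class NucleusConstants:
    """Fixed physiological constants of the two nuclei.

    Rates are in spikes/s, time constants in seconds.  ``m_*`` are maximum
    firing rates, ``b_*`` the autonomous rates at zero net input, and
    ``crx`` the constant cortical firing rate driving the STN.
    """

    m_s: float = 300.0
    m_g: float = 400.0
    b_s: float = 25.0
    b_g: float = 65.0
    tau_s: float = 0.006
    tau_g: float = 0.004
    crx: float = 4.8

    def __post_init__(self) -> None:
        for name in ("m_s", "m_g", "b_s", "b_g", "tau_s", "tau_g", "crx"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.b_s < self.m_s:
            raise ValueError("b_s must be below m_s")
        if not self.b_g < self.m_g:
            raise ValueError("b_g must be below m_g")


DEFAULT_CONSTANTS = NucleusConstants()


@dataclass(frozen=True)
class ConnectionWeights:
    """The six fitted circuit parameters (dimensionless gains on rates).

    ``w_sg``: GPe -> STN inhibition; ``w_sc``: cortex -> STN excitation;
    ``w_gs``: STN -> GPe excitation; ``w_gg``: GPe self-inhibition;
    ``input_str``: lumped inhibitory striatal input to GPe;
    ``w_ss``: STN self-excitation.  Signs live in the drift equations; all
    values here are non-negative.
    """

    w_sg: float
    w_sc: float
    w_gs: float
    w_gg: float
    input_str: float
    w_ss: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("connection weights must be finite")
        if np.any(arr < 0):
            raise ValueError("connection weights must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in WEIGHT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ConnectionWeights":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError("expected exactly six weights")
        return cls(**dict(zip(WEIGHT_NAMES, values)))

    def replace(self, **changes: float) -> "ConnectionWeights":
        return dataclasses.replace(self, **changes)


#: Fitted healthy-state weights.
HEALTHY = ConnectionWeights(
    w_sg=5.55, w_sc=63.15, w_gs=6.37, w_gg=1.92, input_str=0.15, w_ss=1.97
)

#: Fitted Parkinsonian-state weights (all STN-GPe couplings strengthened).
PARKINSONIAN = ConnectionWeights(
    w_sg=28.37, w_sc=73.40, w_gs=9.68, w_gg=8.27, input_str=0.2, w_ss=28.04
)


def activation(u, m: float, b: float):
    """Sigmoidal rate activation f(u) = M B / ((M-B) e^(-4u/M) + B).

    Strictly increasing in ``u`` with range (0, M) and f(0) = B.
    Accepts scalars or arrays.
    """
    if not (m > b > 0):
        raise ValueError("activation requires m > b > 0")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("activation input must be finite")
    expo = np.clip(-4.0 * u / m, -700.0, 700.0)
    out = m * b / ((m - b) * np.exp(expo) + b)
    return float(out) if out.ndim == 0 else out


def activation_slope(u, m: float, b: float):
    """Derivative of :func:`activation` with respect to its input."""
    u = np.asarray(u, dtype=float)
    expo = np.clip(-4.0 * u / m, -700.0, 700.0)
    e = (m - b) * np.exp(expo)
    out = 4.0 * b * e / (e + b) ** 2
    return float(out) if out.ndim == 0 else out


def _inputs(x_s, x_g, w: ConnectionWeights, c: NucleusConstants):
    u_s = w.w_ss * x_s - w.w_sg * x_g + w.w_sc * c.crx
    u_g = w.w_gs * x_s - w.w_gg * x_g - w.input_str
    return u_s, u_g


def drift(state, w: ConnectionWeights, c: NucleusConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Deterministic rate of change (dx_S/dt, dx_G/dt) at ``state``."""
    x_s, x_g = float(state[0]), float(state[1])
    u_s, u_g = _inputs(x_s, x_g, w, c)
    return np.array(
        [
            (-x_s + activation(u_s, c.m_s, c.b_s)) / c.tau_s,
            (-x_g + activation(u_g, c.m_g, c.b_g)) / c.tau_g,
        ]
    )


def make_drift_field(
    w: ConnectionWeights, c: NucleusConstants = DEFAULT_CONSTANTS
) -> Callable[[np.ndarray, np.ndarray], tuple]:
    """Vectorised drift (F_S, F_G) over meshgrid arrays of (x_S, x_G)."""

    def field(x_s, x_g):
        u_s = w.w_ss * x_s - w.w_sg * x_g + w.w_sc * c.crx
        u_g = w.w_gs * x_s - w.w_gg * x_g - w.input_str
        f_s = (-x_s + activation(u_s, c.m_s, c.b_s)) / c.tau_s
        f_g = (-x_g + activation(u_g, c.m_g, c.b_g)) / c.tau_g
        return f_s, f_g

    return field


@dataclass
class Trajectory:
    """Time-stamped two-channel rate series with provenance metadata."""

    times: np.ndarray
    x_s: np.ndarray
    x_g: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x_s = np.asarray(self.x_s, dtype=float)
        self.x_g = np.asarray(self.x_g, dtype=float)
        if not (len(self.times) == len(self.x_s) == len(self.x_g)):
            raise ValueError("times and channels must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def states(self) -> np.ndarray:
        """(n, 2) array of (x_S, x_G) states."""
        return np.column_stack([self.x_s, self.x_g])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def after(self, transient: float) -> "Trajectory":
        """Copy with the first ``transient`` seconds discarded."""
        keep = self.times >= self.times[0] + transient
        return Trajectory(self.times[keep], self.x_s[keep], self.x_g[keep], dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "x_s": self.x_s, "x_g": self.x_g})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["x_s"].to_numpy(), df["x_g"].to_numpy(), meta or {})


def simulate_deterministic(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    x0: Sequence[float] | None = None,
    t_end: float = 2.0,
    dt_out: float = 1e-3,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the noise-free rate equations.

    Uses an adaptive, stiff-capable solver internally and resamples the
    solution to a uniform output step ``dt_out``.  The default initial
    condition is the zero-input baseline (B_S, B_G).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if x0 is None:
        x0 = (c.b_s, c.b_g)
    t_eval = np.arange(0.0, t_end, dt_out)
    sol = solve_ivp(
        lambda t, x: drift(x, w, c),
        (0.0, t_end),
        np.asarray(x0, dtype=float),
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    meta = {"kind": "deterministic", "method": method, "x0": tuple(map(float, x0))}
    return Trajectory(sol.t, sol.y[0], sol.y[1], meta)


def fixed_point(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    guess: Sequence[float] | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Locate a root of the drift near ``guess``.

    Falls back to a coarse multi-start over the state box when the single
    guess does not converge; raises ``RuntimeError`` if no root is found.
    """
    if guess is None:
        guess = (c.b_s, c.b_g)
    root, _, ier, _ = fsolve(
        lambda x: drift(x, w, c),
        np.asarray(guess, dtype=float),
        fprime=lambda x: jacobian(w, c, x),
        full_output=True,
    )
    if ier == 1 and np.linalg.norm(drift(root, w, c)) < 1e-6:
        return root
    roots = find_fixed_points(w, c)
    if not roots:
        raise RuntimeError("no fixed point found for the given weights")
    guess = np.asarray(guess, dtype=float)
    return min(roots, key=lambda r: np.linalg.norm(r - guess))


def find_fixed_points(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    n_grid: int = 12,
    atol: float = 1e-2,
) -> list:
    """All distinct drift roots found from a coarse grid of starts."""
    roots: list = []
    for xs0 in np.linspace(1.0, c.m_s - 1.0, n_grid):
        for xg0 in np.linspace(1.0, c.m_g - 1.0, n_grid):
            cand, _, ier, _ = fsolve(
                lambda x: drift(x, w, c),
                [xs0, xg0],
                fprime=lambda x: jacobian(w, c, x),
                full_output=True,
            )
            if ier != 1 or np.linalg.norm(drift(cand, w, c)) > 1e-6:
                continue
            if not (-atol <= cand[0] <= c.m_s + atol and -atol <= cand[1] <= c.m_g + atol):
                continue
            if not any(np.allclose(cand, r, atol=atol) for r in roots):
                roots.append(cand)
    return roots


def jacobian(
    w: ConnectionWeights, c: NucleusConstants = DEFAULT_CONSTANTS, at: Sequence[float] = (0.0, 0.0)
) -> np.ndarray:
    """Analytic 2x2 Jacobian of the drift at state ``at``."""
    x_s, x_g = float(at[0]), float(at[1])
    u_s, u_g = _inputs(x_s, x_g, w, c)
    ds = activation_slope(u_s, c.m_s, c.b_s)
    dg = activation_slope(u_g, c.m_g, c.b_g)
    return np.array(
        [
            [(-1.0 + ds * w.w_ss) / c.tau_s, -ds * w.w_sg / c.tau_s],
            [dg * w.w_gs / c.tau_g, (-1.0 - dg * w.w_gg) / c.tau_g],
        ]
    )


def jacobian_eigenvalues(
    w: ConnectionWeights, c: NucleusConstants = DEFAULT_CONSTANTS, at: Sequence[float] = (0.0, 0.0)
) -> np.ndarray:
    """Eigenvalues of the Jacobian at ``at``, sorted by real part descending."""
    eig = np.linalg.eigvals(jacobian(w, c, at))
    return eig[np.argsort(-eig.real)]


@dataclass(frozen=True)
class OscillationMetrics:
    is_oscillatory: bool
    frequency: float  # Hz; NaN when not oscillatory
    amplitude_s: float  # half peak-to-trough, spikes/s
    amplitude_g: float


def dominant_frequency(values: np.ndarray, dt: float) -> float:
    """Dominant spectral peak of a mean-removed signal, in Hz.

    Hann-windowed FFT with parabolic interpolation of the log-power peak
    for sub-bin resolution.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    win = np.hanning(len(x))
    power = np.abs(np.fft.rfft(x * win)) ** 2
    freqs = np.fft.rfftfreq(len(x), dt)
    i = int(np.argmax(power[1:])) + 1  # skip DC
    if 0 < i < len(power) - 1 and power[i - 1] > 0 and power[i + 1] > 0:
        la, lb, lc = np.log(power[i - 1 : i + 2])
        denom = la - 2 * lb + lc
        shift = 0.5 * (la - lc) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    return float(freqs[i] + shift * (freqs[1] - freqs[0]))


def oscillation_metrics(
    traj: Trajectory, transient: float = 1.0, amplitude_threshold: float = 1.0
) -> OscillationMetrics:
    """Classify a trajectory as oscillatory and measure frequency/amplitude.

    The first ``transient`` seconds are discarded.  A trajectory counts as
    oscillatory when the post-transient peak-to-trough swing of the GPe
    rate exceeds ``amplitude_threshold`` (spikes/s), which separates limit
    cycles (tens of spikes/s) from numerical ripple.
    """
    tail = traj.after(transient)
    if len(tail.times) < 2 or tail.times[-1] - tail.times[0] < 1.0 - 2 * (
        tail.times[1] - tail.times[0]
    ):
        raise ValueError("trajectory too short after transient removal (need >= 1 s)")
    amp_s = 0.5 * (tail.x_s.max() - tail.x_s.min())
    amp_g = 0.5 * (tail.x_g.max() - tail.x_g.min())
    oscillatory = bool(2.0 * amp_g > amplitude_threshold)
    freq = dominant_frequency(tail.x_g, tail.dt) if oscillatory else float("nan")
    return OscillationMetrics(oscillatory, freq, float(amp_s), float(amp_g))
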