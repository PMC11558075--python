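"""Disease progression, bifurcation localisation and circuit interventions.

Disease progression is modelled as a linear interpolation of the six
connection weights between the fitted healthy and Parkinsonian sets,

    w(k) = w_h + k (w_PD - w_h),        k in [0, 1],

with ``k`` the progression value.  Interventions multiply a chosen subset
of weights by a blocking coefficient gamma in [0, 1] (gamma = 1: no
intervention, gamma = 0: full block), and their benefit is scored by the
error function

    error(w) = J^2 + sum_i ((H_i^e - x_i^s) / H_i^sigma)^2

where J is the mean non-equilibrium flux of the stochastic circuit at the
intervened weights and x_i^s the simulated post-transient mean rates; a
lower error means a state closer (in both rates and dissipation) to the
healthy one.

On the transition mechanism: along the fitted progression path the stable
healthy-branch fixed point does not cross the imaginary axis smoothly;
around k ~ 0.985 a saddle/node pair is born elsewhere in state space and
at k ~ 0.996 the healthy fixed point is annihilated against the saddle,
leaving the beta-band limit cycle as the only attractor.
``bifurcation_scan`` therefore brackets the smallest k at which the
continued healthy branch either loses linear stability or ceases to
exist, which is the operative onset of pathological oscillation either
way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .model_core import (
    DEFAULT_CONSTANTS,
    HEALTHY,
    PARKINSONIAN,
    WEIGHT_NAMES,
    ConnectionWeights,
    NucleusConstants,
    Trajectory,
    drift,
    jacobian,
    simulate_deterministic,
)
from .fitting import DEFAULT_TARGETS, ExperimentalTargets
from .landscape_flux import (
    GridSpec,
    NoiseModel,
    flux_field,
    mean_flux,
    simulate_langevin_ensemble,
    steady_state_density,
)

__all__ = [
    "ProgressionPath",
    "DEFAULT_PATH",
    "interpolate_weights",
    "BifurcationResult",
    "bifurcation_scan",
    "InterventionStrategy",
    "STRATEGY_PRESETS",
    "preset_strategy",
    "apply_intervention",
    "restoring_strategy",
    "error_function",
    "evaluate_strategies",
    "TimecourseResult",
    "early_intervention_timecourse",
]


@dataclass(frozen=True)
class ProgressionPath:
    """Linear path in weight space from healthy to Parkinsonian."""

    w_h: ConnectionWeights = HEALTHY
    w_pd: ConnectionWeights = PARKINSONIAN

    def weights_at(self, k: float) -> ConnectionWeights:
        return interpolate_weights(self, k)


DEFAULT_PATH = ProgressionPath()


def interpolate_weights(path: ProgressionPath, k: float) -> ConnectionWeights:
    """Component-wise w_h + k (w_PD - w_h); exact at both endpoints."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("progression value k must lie in [0, 1]")
    if k == 0.0:
        return path.w_h
    if k == 1.0:
        return path.w_pd
    a, b = path.w_h.as_array(), path.w_pd.as_array()
    return ConnectionWeights.from_array(a + k * (b - a))


@dataclass
class BifurcationResult:
    found: bool
    k_star: float  # NaN when no transition in [0, 1]
    k_values: np.ndarray
    rate_s: np.ndarray  # fixed-point rates along the healthy branch
    rate_g: np.ndarray
    leading_real: np.ndarray
    leading_eigenvalue: complex  # at the last stable point of the branch


def _track_branch(path, c, k, guess, jump_tol=10.0):
    """Continue the healthy fixed-point branch to progression value k.

    Returns (ok, root, eigenvalues): ok is False when the root search
    fails, jumps to a distant branch, or the root is linearly unstable.
    """
    w = path.weights_at(k)
    root, _, ier, _ = fsolve(
        lambda x: drift(x, w, c),
        np.asarray(guess, float),
        fprime=lambda x: jacobian(w, c, x),
        full_output=True,
    )
    eig = np.linalg.eigvals(jacobian(w, c, root))
    # residual tolerance is relative to the drift scale (|x|/tau ~ 1e4)
    ok = (
        np.linalg.norm(drift(root, w, c)) < 1e-4
        and np.linalg.norm(root - np.asarray(guess, float)) < jump_tol
        and eig.real.max() < 0
    )
    return ok, root, eig[np.argsort(-eig.real)]


def bifurcation_scan(
    path: ProgressionPath = DEFAULT_PATH,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    k_resolution: float = 1e-3,
    refine_tol: float = 1e-4,
) -> BifurcationResult:
    """Locate the progression value where the healthy state destabilises.

    Marches the healthy-branch fixed point along k with continuation at
    ``k_resolution`` steps, then bisects the first step on which the
    branch loses stability or disappears down to ``refine_tol``.  Also
    records the branch rates (the phase-diagram curves).
    """
    ks = np.arange(0.0, 1.0 + 0.5 * k_resolution, k_resolution)
    guess = np.array([c.b_s, c.b_g])
    ok0, root, eig = _track_branch(path, c, 0.0, guess, jump_tol=100.0)
    if not ok0:
        raise RuntimeError("no stable fixed point at k = 0; not a healthy baseline")
    rates_s, rates_g, lead = [], [], []
    k_lost = None
    last_eig = eig
    for k in ks:
        ok, root_k, eig = _track_branch(path, c, k, root)
        if not ok:
            k_lost = k
            break
        root = root_k
        last_eig = eig
        rates_s.append(root[0])
        rates_g.append(root[1])
        lead.append(eig[0].real)
    n = len(rates_s)
    result_arrays = (ks[:n], np.array(rates_s), np.array(rates_g), np.array(lead))
    if k_lost is None:
        return BifurcationResult(False, float("nan"), *result_arrays, last_eig[0])
    lo, hi = k_lost - k_resolution, k_lost
    root_lo = root
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        ok, root_mid, eig = _track_branch(path, c, mid, root_lo)
        if ok:
            lo, root_lo = mid, root_mid
            last_eig = eig
        else:
            hi = mid
    return BifurcationResult(True, 0.5 * (lo + hi), *result_arrays, last_eig[0])


@dataclass(frozen=True)
class InterventionStrategy:
    """Multiplicative down-regulation of a subset of connection weights.

    ``gamma`` may be a single blocking coefficient applied to every target
    or a mapping from target name to a per-target coefficient.
    """

    name: str
    targets: tuple
    gamma: float | Mapping[str, float] = 1.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("strategy needs at least one target weight")
        for t in self.targets:
            if t not in WEIGHT_NAMES:
                raise ValueError(f"unknown connection weight {t!r}")
        gammas = (
            list(self.gamma.values()) if isinstance(self.gamma, Mapping) else [self.gamma]
        )
        for g in gammas:
            if not 0.0 <= g <= 1.0:
                raise ValueError("blocking coefficient must lie in [0, 1]")

    def gamma_for(self, target: str) -> float:
        if isinstance(self.gamma, Mapping):
            return float(self.gamma[target])
        return float(self.gamma)

    def with_gamma(self, gamma) -> "InterventionStrategy":
        return InterventionStrategy(self.name, self.targets, gamma)


#: Target sets of the six preset strategies.  Strategies 1 and 6 follow the
#: canonical definitions (cortex->STN alone; all connections strengthened by
#: dopamine loss).  Strategies 2-5 are reconstructions chosen to span
#: single- and multi-edge excitatory targets, with 1-4 acting on STN
#: excitation; they are configurable, not canonical.
STRATEGY_PRESETS = {
    "intervention1": ("w_sc",),
    "intervention2": ("w_gs",),
    "intervention3": ("w_ss",),
    "intervention4": ("w_sc", "w_ss"),
    "intervention5": ("w_sg", "w_gs"),
    "intervention6": ("w_sg", "w_sc", "w_gs", "w_gg", "w_ss"),
}


def preset_strategy(name: str, gamma=1.0) -> InterventionStrategy:
    return InterventionStrategy(name, STRATEGY_PRESETS[name], gamma)


def apply_intervention(w: ConnectionWeights, strategy: InterventionStrategy) -> ConnectionWeights:
    """Scale the strategy's target weights by gamma; others untouched."""
    changes = {t: strategy.gamma_for(t) * getattr(w, t) for t in strategy.targets}
    return w.replace(**changes)


def restoring_strategy(
    base_w: ConnectionWeights,
    reference_w: ConnectionWeights = HEALTHY,
    targets: Sequence[str] = STRATEGY_PRESETS["intervention6"],
    name: str = "restore",
) -> InterventionStrategy:
    """Per-target gammas that return each target exactly to its reference value.

    Targets whose reference exceeds the base value (nothing to block) get
    gamma = 1.
    """
    gammas = {}
    for t in targets:
        base, ref = getattr(base_w, t), getattr(reference_w, t)
        gammas[t] = min(ref / base, 1.0) if base > 0 else 1.0
    return InterventionStrategy(name, tuple(targets), gammas)


def error_function(
    w: ConnectionWeights,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    targets: ExperimentalTargets = DEFAULT_TARGETS,
    grid: GridSpec | None = None,
    t_end: float = 3.0,
    transient: float = 1.0,
    rates: Sequence[float] | None = None,
    return_terms: bool = False,
):
    """Treatment-outcome score J^2 + healthy-rate deviation (lower is better).

    ``rates`` may supply externally measured mean rates (e.g. from a
    recorded post-intervention window); otherwise the noise-free model is
    simulated.  The flux term always derives from the stationary density
    at the given weights.
    """
    if rates is None:
        tail = simulate_deterministic(w, c, t_end=t_end).after(transient)
        rates = (tail.x_s.mean(), tail.x_g.mean())
    density = steady_state_density(w, c, noise, grid)
    flux = flux_field(density, w, c, noise)
    j = mean_flux(density, flux)
    rate_term = (
        ((targets.h_rate_s - rates[0]) / targets.h_sigma_s) ** 2
        + ((targets.h_rate_g - rates[1]) / targets.h_sigma_g) ** 2
    )
    total = j**2 + rate_term
    if return_terms:
        return float(total), float(j), float(rate_term)
    return float(total)


def evaluate_strategies(
    strategies: Sequence[InterventionStrategy] | None = None,
    gamma_grid: Sequence[float] | None = None,
    base_w: ConnectionWeights = PARKINSONIAN,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    targets: ExperimentalTargets = DEFAULT_TARGETS,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Full factorial sweep of error vs blocking coefficient per strategy.

    Returns a tidy frame (strategy, gamma, error, j_term, rate_term)
    sufficient to re-plot the treatment-effectiveness curves.
    """
    if strategies is None:
        strategies = [preset_strategy(n) for n in STRATEGY_PRESETS]
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, 1.0, 11)
    records = []
    for strat in strategies:
        for gamma in gamma_grid:
            w = apply_intervention(base_w, strat.with_gamma(float(gamma)))
            err, j, rate = error_function(
                w, c, noise, targets, grid, return_terms=True
            )
            records.append(
                {
                    "strategy": strat.name,
                    "gamma": float(gamma),
                    "error": err,
                    "j_term": j**2,
                    "rate_term": rate,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class TimecourseResult:
    trajectory: Trajectory
    t_intervene: float
    w_before: ConnectionWeights
    w_after: ConnectionWeights
    restored: bool
    tail_mean_s: float
    tail_mean_g: float
    tail_range_g: float  # central-95% range of the tail GPe rate
    error_before: float
    error_after: float


def early_intervention_timecourse(
    k_start: float,
    strategy: InterventionStrategy,
    t_intervene: float = 2.0,
    total_t: float = 6.0,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    path: ProgressionPath = DEFAULT_PATH,
    targets: ExperimentalTargets = DEFAULT_TARGETS,
    grid: GridSpec | None = None,
    dt: float = 5e-4,
    tail_window: float = 2.0,
) -> TimecourseResult:
    """Apply an intervention mid-recording at progression value ``k_start``.

    The noisy circuit runs at the interpolated weights until
    ``t_intervene`` and at the intervened weights afterwards (k is frozen
    within the simulated seconds: degeneration is slow compared to circuit
    dynamics).  The final ``tail_window`` seconds are scored: ``restored``
    requires a non-oscillatory tail whose mean rates are within one
    healthy sigma of the healthy targets; ``error_after`` is the error
    function with the empirical tail rates.
    """
    if not t_intervene < total_t:
        raise ValueError("t_intervene must precede total_t")
    w_before = path.weights_at(k_start)
    w_after = apply_intervention(w_before, strategy)
    times1, s1, g1 = simulate_langevin_ensemble(
        w_before, c, noise, t_end=t_intervene, dt=dt, seed=seed
    )
    times2, s2, g2 = simulate_langevin_ensemble(
        w_after, c, noise, x0=(s1[-1, 0], g1[-1, 0]), t_end=total_t - t_intervene,
        dt=dt, seed=seed + 1,
    )
    traj = Trajectory(
        np.concatenate([times1, t_intervene + times2]),
        np.concatenate([s1[:, 0], s2[:, 0]]),
        np.concatenate([g1[:, 0], g2[:, 0]]),
        {"kind": "timecourse", "k_start": k_start, "t_intervene": t_intervene,
         "strategy": strategy.name, "seed": seed},
    )
    tail = traj.after(total_t - tail_window)
    lo, hi = np.percentile(tail.x_g, [2.5, 97.5])
    tail_range = float(hi - lo)
    mean_s, mean_g = float(tail.x_s.mean()), float(tail.x_g.mean())
    # noise-aware oscillation call: a restored state shows only small
    # fluctuation around the fixed point, not a tens-of-spikes/s swing
    non_oscillatory = tail_range < 10.0
    near_healthy = (
        abs(mean_s - targets.h_rate_s) < targets.h_sigma_s
        and abs(mean_g - targets.h_rate_g) < targets.h_sigma_g
    )
    pre = traj.after(max(t_intervene - tail_window, 0.0))
    pre_keep = pre.times <= t_intervene
    pre_rates = (pre.x_s[pre_keep].mean(), pre.x_g[pre_keep].mean())
    error_before = error_function(w_before, c, noise, targets, grid, rates=pre_rates)
    error_after = error_function(w_after, c, noise, targets, grid, rates=(mean_s, mean_g))
    return TimecourseResult(
        trajectory=traj,
        t_intervene=t_intervene,
        w_before=w_before,
        w_after=w_after,
        restored=bool(non_oscillatory and near_healthy),
        tail_mean_s=mean_s,
        tail_mean_g=mean_g,
        tail_range_g=tail_range,
        error_before=error_before,
        error_after=error_after,
    )
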