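"""Time-irreversibility early-warning indicator and comparators.

A system obeying detailed balance is statistically time-reversible: the
cross-correlation of two of its state variables is the same forward and
backward in time.  A non-equilibrium system breaks that symmetry, and the
forward-backward cross-correlation difference

    dC(tau) = < x_S(t) x_G(t + tau) > - < x_G(t) x_S(t + tau) >

(computed on mean-centred series) is a direct, data-only measure of the
broken symmetry.  As the circuit approaches the oscillation onset the
rotational (flux) component of its dynamics grows, so a scalar summary of
dC rises with disease progression and serves as an early-warning signal —
earlier, relative to its baseline, than the classical critical-slowing-down
comparator (variance inflation).

Indicators are computed from synthetic *recordings* (sampled at an
acquisition rate, with observation noise) rather than from privileged
model internals, so the pipeline mimics analysis of recorded data.
Scalar dC reported per realization is |mean over tau in [0, max_lag]| of
dC(tau); the signed mean is retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import DEFAULT_CONSTANTS, NucleusConstants
from .landscape_flux import (
    GridSpec,
    NoiseModel,
    entropy_production_rate,
    flux_field,
    steady_state_density,
)
from .intervention import DEFAULT_PATH, ProgressionPath
from .synthetic_recordings import RecordingSpec, generate_recording_ensemble

__all__ = [
    "delta_C_curve",
    "IndicatorEstimate",
    "VarianceEstimate",
    "delta_C_indicator",
    "variance_indicator",
    "IndicatorSeries",
    "warning_scan",
]


def _cross_products(a: np.ndarray, b: np.ndarray, n_lags: int, method: str) -> np.ndarray:
    """c[m] = sum_t a[t] b[t+m] for m = 0..n_lags, FFT or direct."""
    n = len(a)
    if method == "direct":
        return np.array([np.dot(a[: n - m], b[m:]) for m in range(n_lags + 1)])
    if method != "fft":
        raise ValueError("method must be 'fft' or 'direct'")
    size = 1
    while size < 2 * n:
        size *= 2
    fa = np.fft.rfft(a, size)
    fb = np.fft.rfft(b, size)
    return np.fft.irfft(np.conj(fa) * fb, size)[: n_lags + 1]


def delta_C_curve(
    series_a: np.ndarray,
    series_b: np.ndarray,
    dt: float,
    max_lag: float,
    center: bool = True,
    method: str = "fft",
):
    """Forward-backward cross-correlation difference dC(tau).

    dC(tau) = <a(t) b(t+tau)> - <b(t) a(t+tau)> with empirical
    (unbiased-count) time averages; dC(0) = 0 by construction and
    dC is antisymmetric under swapping the two series.

    Returns (lags, dC) for tau in [0, max_lag].
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be one-dimensional and equal length")
    n_lags = int(round(max_lag / dt))
    if len(a) < 2 * n_lags:
        raise ValueError("series shorter than twice the maximum lag")
    if center:
        a = a - a.mean()
        b = b - b.mean()
    counts = len(a) - np.arange(n_lags + 1)
    c_ab = _cross_products(a, b, n_lags, method) / counts
    c_ba = _cross_products(b, a, n_lags, method) / counts
    return dt * np.arange(n_lags + 1), c_ab - c_ba


@dataclass(frozen=True)
class IndicatorEstimate:
    """Ensemble mean and standard error of a scalar indicator."""

    value: float
    se: float
    signed_value: float
    signed_se: float
    n: int


@dataclass(frozen=True)
class VarianceEstimate:
    var_s: float
    var_g: float
    se_s: float
    se_g: float
    n: int


def _recording_ensemble(
    k, c, noise, duration, n_realizations, seed, fs, obs_noise_sd, path, dt=5e-4
):
    spec = RecordingSpec(
        k=k, d=noise.d, fs=fs, duration=duration, obs_noise_sd=obs_noise_sd, seed=seed, dt=dt
    )
    return generate_recording_ensemble(spec, path, c, n_realizations=n_realizations)


def delta_C_indicator(
    k: float,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    duration: float = 10.0,
    max_lag: float = 0.15,
    n_realizations: int = 200,
    seed: int = 0,
    fs: float = 200.0,
    obs_noise_sd: float = 0.5,
    path: ProgressionPath = DEFAULT_PATH,
    dt: float = 5e-4,
) -> IndicatorEstimate:
    """Ensemble-averaged scalar dC at progression value ``k``.

    Each realization is an independent synthetic recording; its dC(tau)
    curve is averaged over tau and the absolute tau-mean is the per-
    realization scalar.  Returns the ensemble mean with its standard
    error (and the signed version alongside).
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    times, s, g = _recording_ensemble(
        k, c, noise, duration, n_realizations, seed, fs, obs_noise_sd, path, dt
    )
    dt_out = float(times[1] - times[0])
    scalars = np.empty(n_realizations)
    signed = np.empty(n_realizations)
    for j in range(n_realizations):
        _, curve = delta_C_curve(s[:, j], g[:, j], dt_out, max_lag)
        signed[j] = curve.mean()
        scalars[j] = abs(signed[j])
    root_n = np.sqrt(n_realizations)
    return IndicatorEstimate(
        value=float(scalars.mean()),
        se=float(scalars.std(ddof=1) / root_n) if n_realizations > 1 else float("nan"),
        signed_value=float(signed.mean()),
        signed_se=float(signed.std(ddof=1) / root_n) if n_realizations > 1 else float("nan"),
        n=n_realizations,
    )


def variance_indicator(
    k: float,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    duration: float = 10.0,
    n_realizations: int = 200,
    seed: int = 0,
    fs: float = 200.0,
    obs_noise_sd: float = 0.5,
    path: ProgressionPath = DEFAULT_PATH,
    dt: float = 5e-4,
) -> VarianceEstimate:
    """Ensemble-averaged per-channel sample variance (critical-slowing-down
    comparator)."""
    times, s, g = _recording_ensemble(
        k, c, noise, duration, n_realizations, seed, fs, obs_noise_sd, path, dt
    )
    vs = s.var(axis=0, ddof=1)
    vg = g.var(axis=0, ddof=1)
    root_n = np.sqrt(n_realizations)
    return VarianceEstimate(
        var_s=float(vs.mean()),
        var_g=float(vg.mean()),
        se_s=float(vs.std(ddof=1) / root_n) if n_realizations > 1 else float("nan"),
        se_g=float(vg.std(ddof=1) / root_n) if n_realizations > 1 else float("nan"),
        n=n_realizations,
    )


@dataclass
class IndicatorSeries:
    """Early-warning indicators as functions of the progression value."""

    k_values: np.ndarray
    delta_c: np.ndarray
    delta_c_se: np.ndarray
    delta_c_signed: np.ndarray
    var_s: np.ndarray
    var_g: np.ndarray
    var_s_se: np.ndarray
    var_g_se: np.ndarray
    epr: np.ndarray | None
    mean_flux: np.ndarray | None
    n_realizations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        data = {
            "k": self.k_values,
            "delta_c": self.delta_c,
            "delta_c_se": self.delta_c_se,
            "delta_c_signed": self.delta_c_signed,
            "var_s": self.var_s,
            "var_g": self.var_g,
            "var_s_se": self.var_s_se,
            "var_g_se": self.var_g_se,
        }
        if self.epr is not None:
            data["epr"] = self.epr
        if self.mean_flux is not None:
            data["mean_flux"] = self.mean_flux
        return pd.DataFrame(data)


def warning_scan(
    k_grid,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    noise: NoiseModel = NoiseModel(),
    duration: float = 10.0,
    max_lag: float = 0.15,
    n_realizations: int = 200,
    seed: int = 0,
    fs: float = 200.0,
    obs_noise_sd: float = 0.5,
    path: ProgressionPath = DEFAULT_PATH,
    compute_thermo: bool = False,
    grid: GridSpec | None = None,
) -> IndicatorSeries:
    """Scan all indicators across progression values.

    dC and variance are estimated from recording ensembles (per-k seeds
    derived from the master seed); optionally the landscape EPR and mean
    flux are computed at each k from the stationary Fokker-Planck solve.
    Everything needed to re-plot the indicator-versus-progression curves
    is recorded.
    """
    k_grid = [float(k) for k in k_grid]
    if any(not 0.0 <= k < 1.0 for k in k_grid):
        raise ValueError("warning scan expects progression values in [0, 1)")
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(k_grid)) % (2**31)
    dc, dcse, dcsig = [], [], []
    vs, vg, vsse, vgse = [], [], [], []
    eprs, fluxes = [], []
    for i, k in enumerate(k_grid):
        est = delta_C_indicator(
            k, c, noise, duration, max_lag, n_realizations, int(seeds[2 * i]), fs,
            obs_noise_sd, path,
        )
        var = variance_indicator(
            k, c, noise, duration, n_realizations, int(seeds[2 * i + 1]), fs,
            obs_noise_sd, path,
        )
        dc.append(est.value)
        dcse.append(est.se)
        dcsig.append(est.signed_value)
        vs.append(var.var_s)
        vg.append(var.var_g)
        vsse.append(var.se_s)
        vgse.append(var.se_g)
        if compute_thermo:
            w = path.weights_at(k)
            density = steady_state_density(w, c, noise, grid)
            flux = flux_field(density, w, c, noise)
            thermo = entropy_production_rate(density, flux, noise)
            eprs.append(thermo.epr)
            fluxes.append(thermo.mean_flux)
    return IndicatorSeries(
        k_values=np.array(k_grid),
        delta_c=np.array(dc),
        delta_c_se=np.array(dcse),
        delta_c_signed=np.array(dcsig),
        var_s=np.array(vs),
        var_g=np.array(vg),
        var_s_se=np.array(vsse),
        var_g_se=np.array(vgse),
        epr=np.array(eprs) if compute_thermo else None,
        mean_flux=np.array(fluxes) if compute_thermo else None,
        n_realizations=n_realizations,
        seed=seed,
    )
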