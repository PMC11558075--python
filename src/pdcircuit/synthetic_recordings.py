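"""Synthetic two-channel rate recordings from the stochastic circuit.

Stand-in for implanted-microelectrode rate recordings of STN and GPe: the
stochastic circuit is simulated at the weights of a chosen progression
value, resampled to an acquisition rate, and corrupted with independent
Gaussian observation noise per channel.  Ground truth (progression value,
weights, seeds) travels in the trajectory metadata so that downstream
indicator estimates can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import DEFAULT_CONSTANTS, NucleusConstants, Trajectory
from .landscape_flux import NoiseModel, simulate_langevin_ensemble
from .intervention import DEFAULT_PATH, ProgressionPath

__all__ = [
    "RecordingSpec",
    "generate_recording",
    "generate_recording_ensemble",
    "generate_progression_dataset",
]


@dataclass(frozen=True)
class RecordingSpec:
    """Acquisition settings for one synthetic recording.

    ``fs`` must be Nyquist-safe for beta-band work (>= 60 Hz) and the
    recording must contain at least a thousand samples.  ``settle``
    seconds are simulated and discarded before acquisition starts so the
    recorded stretch is stationary.
    """

    k: float
    d: float = 5.0
    fs: float = 200.0
    duration: float = 10.0
    obs_noise_sd: float = 0.5
    seed: int = 0
    settle: float = 1.0
    dt: float = 5e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("progression value k must lie in [0, 1]")
        if self.fs < 60.0:
            raise ValueError("sampling rate below 60 Hz cannot resolve the beta band")
        if self.duration * self.fs < 1e3:
            raise ValueError("recording needs at least 1000 samples")
        if self.obs_noise_sd < 0:
            raise ValueError("observation noise must be non-negative")
        stride = 1.0 / (self.fs * self.dt)
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("fs must be an integer divisor of the simulation rate 1/dt")

    @property
    def stride(self) -> int:
        return int(round(1.0 / (self.fs * self.dt)))


def generate_recording_ensemble(
    spec: RecordingSpec,
    path: ProgressionPath = DEFAULT_PATH,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    n_realizations: int = 1,
):
    """``n_realizations`` independent recordings at the same settings.

    Returns (times, x_s, x_g) with channels of shape (n_samples,
    n_realizations); all randomness (dynamical and observational) derives
    from ``spec.seed``.
    """
    w = path.weights_at(spec.k)
    times, s, g = simulate_langevin_ensemble(
        w,
        c,
        NoiseModel(spec.d),
        t_end=spec.settle + spec.duration,
        dt=spec.dt,
        seed=spec.seed,
        n_realizations=n_realizations,
        stride=spec.stride,
    )
    keep = times > spec.settle
    times, s, g = times[keep] - spec.settle, s[keep], g[keep]
    if spec.obs_noise_sd > 0:
        obs_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,))
        )
        s = s + spec.obs_noise_sd * obs_rng.standard_normal(s.shape)
        g = g + spec.obs_noise_sd * obs_rng.standard_normal(g.shape)
    return times, s, g


def generate_recording(
    spec: RecordingSpec,
    path: ProgressionPath = DEFAULT_PATH,
    c: NucleusConstants = DEFAULT_CONSTANTS,
) -> Trajectory:
    """One synthetic recording with ground truth in the metadata."""
    times, s, g = generate_recording_ensemble(spec, path, c, n_realizations=1)
    w = path.weights_at(spec.k)
    meta = {
        "kind": "synthetic_recording",
        "k": spec.k,
        "d": spec.d,
        "fs": spec.fs,
        "obs_noise_sd": spec.obs_noise_sd,
        "seed": spec.seed,
        "weights": w.as_array().tolist(),
    }
    return Trajectory(times, s[:, 0], g[:, 0], meta)


def generate_progression_dataset(
    k_grid,
    template: RecordingSpec | None = None,
    n_per_k: int = 1,
    seed: int = 0,
    path: ProgressionPath = DEFAULT_PATH,
    c: NucleusConstants = DEFAULT_CONSTANTS,
    out_dir=None,
):
    """A recording collection across progression values, with a manifest.

    Per-recording seeds are derived deterministically from the master
    ``seed``; the same master seed reproduces the dataset byte for byte.
    When ``out_dir`` is given, recordings are written as tidy CSVs next to
    a JSON manifest.

    Returns (recordings, manifest) where manifest is a tidy DataFrame with
    one row per recording (file, k, realization, seed).
    """
    k_grid = [float(k) for k in k_grid]
    if any(not 0.0 <= k <= 1.0 for k in k_grid):
        raise ValueError("all progression values must lie in [0, 1]")
    if template is None:
        template = RecordingSpec(k=0.0)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(k_grid) * n_per_k) % (2**31)]
    recordings, rows = [], []
    idx = 0
    for k in k_grid:
        for r in range(n_per_k):
            spec = RecordingSpec(
                k=k,
                d=template.d,
                fs=template.fs,
                duration=template.duration,
                obs_noise_sd=template.obs_noise_sd,
                seed=child_seeds[idx],
                settle=template.settle,
                dt=template.dt,
            )
            rec = generate_recording(spec, path, c)
            recordings.append(rec)
            fname = f"recording_k{k:.3f}_r{r}.csv"
            rows.append({"file": fname, "k": k, "realization": r, "seed": spec.seed})
            idx += 1
    manifest = pd.DataFrame.from_records(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, rows):
            rec.to_csv(out / row["file"])
        payload = {
            "master_seed": seed,
            "n_per_k": n_per_k,
            "template": {
                "d": template.d,
                "fs": template.fs,
                "duration": template.duration,
                "obs_noise_sd": template.obs_noise_sd,
            },
            "recordings": rows,
        }
        (out / "manifest.json").write_text(json.dumps(payload, indent=2))
    return recordings, manifest
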