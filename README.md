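# pdcircuit

Non-equilibrium dynamics of the STN–GPe circuit in Parkinson's disease:
circuit fitting, landscape/flux analysis, early-warning indicators and
quantitative intervention evaluation.

## The problem

Parkinson's disease is diagnosed late: by the time motor symptoms appear,
most of the dopaminergic input to the basal ganglia is already gone, and the
circuit has spent years compensating. The subthalamic nucleus (STN) and the
external globus pallidus (GPe) form the loop in which the pathological
beta-band (12–30 Hz) oscillation — the electrophysiological biomarker of the
parkinsonian state — is generated. This package implements a complete
computational account of that transition for researchers in computational
neuroscience and systems biology: *how* the circuit drifts from a healthy
fixed point into a beta limit cycle, *what* early-warning statistics move
before the transition, and *which* circuit-level interventions best restore
the healthy state.

## The model

Population firing rates `x_S` (STN, glutamatergic) and `x_G` (GPe,
GABAergic) obey mean-field rate equations

```
tau_S dx_S/dt = -x_S + f_S( w_SS x_S - w_SG x_G + w_SC Crx )
tau_G dx_G/dt = -x_G + f_G( w_GS x_S - w_GG x_G - Input_Str )
f_i(u)        =  M_i B_i / ((M_i - B_i) e^(-4u/M_i) + B_i)
```

with `Crx` a constant cortical drive, `Input_Str` a constant inhibitory
striatal input, and sigmoidal activations saturating at `M_i` with baseline
`B_i`. Two fitted weight sets ship with the package: `HEALTHY` (stable
fixed point, GPe ≈ 65 spikes/s) and `PARKINSONIAN` (all STN–GPe couplings
strengthened; limit cycle at ≈ 13 Hz). Disease progression is the linear
path `w(k) = w_h + k (w_PD − w_h)`, `k ∈ [0, 1]`.

On top of the deterministic skeleton sit four analyses:

* **Fitting** (`pdcircuit.fitting`) — a constrained cost (rate and frequency
  deviations from experimental targets, plus penalties encoding blockade
  experiments) minimised by simulated annealing over the 12-parameter pair.
* **Landscape and flux** (`pdcircuit.landscape_flux`) — the stationary
  Fokker–Planck density of the noisy circuit, the potential `U = −ln P_ss`,
  the probability flux `J = F P_ss − D ∇P_ss`, the entropy production rate
  `EPR = ∫ (J·J)/(D P_ss) dx` and a scalar mean flux `∫ |J| dx`.
* **Early warning** (`pdcircuit.early_warning`) — the forward–backward
  cross-correlation difference
  `ΔC(τ) = ⟨x_S(t) x_G(t+τ)⟩ − ⟨x_G(t) x_S(t+τ)⟩`, a direct measure of
  time-reversal-symmetry breaking, against the classical variance
  (critical-slowing-down) comparator.
* **Intervention** (`pdcircuit.intervention`) — blocking coefficients
  `γ ∈ [0, 1]` on chosen weights, scored by the error function
  `J² + Σ_i ((H_i^e − x_i^s)/H_i^σ)²`.

Synthetic two-channel "recordings" (`pdcircuit.synthetic_recordings`)
emulate implanted-electrode rate data: Langevin simulation, resampling to an
acquisition rate, additive Gaussian observation noise. All indicator
estimates run on this observation pathway, not on model internals.

## Worked example

```python
import pdcircuit as pc

# 1. the two regimes
traj = pc.simulate_deterministic(pc.PARKINSONIAN, t_end=5.0, dt_out=5e-4)
met = pc.oscillation_metrics(traj, transient=1.0)
print(f"PD frequency: {met.frequency:.2f} Hz, GPe amplitude {met.amplitude_g:.1f} spikes/s")
# PD frequency: 12.76 Hz, GPe amplitude 66.0 spikes/s

root = pc.fixed_point(pc.HEALTHY)
print(f"healthy fixed point: ({root[0]:.1f}, {root[1]:.1f}) spikes/s")
# healthy fixed point: (19.7, 65.1) spikes/s

# 2. where the healthy state is lost
res = pc.bifurcation_scan(k_resolution=1e-3)
print(f"transition at k = {res.k_star:.4f}")
# transition at k = 0.9961

# 3. the fitted pair satisfies the annealing stop criterion (cost < 1)
print(f"cost = {pc.cost_function(pc.HEALTHY, pc.PARKINSONIAN):.4f}")
# cost = 0.0185

# 4. early-warning indicators across progression
scan = pc.warning_scan([0.0, 0.5, 0.95], n_realizations=50, seed=1,
                       compute_thermo=True)
print(scan.to_frame()[["k", "delta_c", "var_s", "epr", "mean_flux"]])
#       k   delta_c     var_s           epr   mean_flux
# 0  0.00  0.001263  0.272111   2042.576569   87.026875
# 1  0.50  0.001699  0.325270   2633.822877   96.579158
# 2  0.95  0.011516  1.138398  49787.978758  328.637704
```

The healthy circuit sits at a stable spiral (19.7, 65.1 spikes/s); the
parkinsonian weights produce a ~13 Hz relaxation oscillation. The healthy
branch survives essentially until the end of the progression path
(k ≈ 0.996) — the dynamical signature of clinical compensation — while all
four early-warning statistics (ΔC, variance, entropy production, mean flux)
rise well before it. Relative to its baseline, ΔC moves faster than the
variance at mid-progression: irreversibility is the earlier signal.

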