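# Methods

## Model

The circuit is a two-population mean-field (Wilson–Cowan-type) rate model of
the subthalamic nucleus (STN) and the external globus pallidus (GPe):

```
tau_S dx_S/dt = -x_S + f_S( w_SS x_S - w_SG x_G + w_SC Crx )
tau_G dx_G/dt = -x_G + f_G( w_GS x_S - w_GG x_G - Input_Str )
f_i(u)        =  M_i B_i / ((M_i - B_i) e^(-4u/M_i) + B_i)
```

States are population-average firing rates in spikes/s; time is in seconds
throughout (the membrane-scale constants are stored as `tau_S = 6 ms`,
`tau_G = 4 ms` converted to seconds). The activation `f_i` is strictly
increasing with range `(0, M_i)` and `f_i(0) = B_i`, the autonomous rate at
zero input. Fixed physiology: `M_S = 300`, `M_G = 400`, `B_S = 25`,
`B_G = 65` spikes/s, cortical drive `Crx = 4.8` spikes/s. The six free
parameters are the connection gains `w_SG, w_SC, w_GS, w_GG, w_SS` and the
lumped striatal input `Input_Str`. Signs live in the drift: GPe inhibits
STN (`-w_SG x_G`), STN excites GPe (`+w_GS x_S`), the striatal input is
inhibitory to GPe and therefore enters with a minus sign — consistent with
its physiological identity and with the lineage of STN–GPe rate models this
one descends from.

The model deliberately omits synaptic transmission delays; the oscillatory
instability is carried instead by the STN self-excitation term `w_SS x_S`.
Striatum, GPi, thalamus and cortex appear only as constant effective
inputs.

### Experimental targets

The fitting targets encode the canonical rate changes after dopamine
depletion: GPe slows (healthy ≈ 65.2 → parkinsonian ≈ 41.2 spikes/s) while
STN accelerates (19.7 → 27.3 spikes/s), with standard deviations
(10.5, 22.4) and (9.5, 25.9) respectively, and a parkinsonian oscillation
frequency of 13.7 Hz normalised by 8 Hz in the cost. With this orientation
the fitted healthy set reproduces the healthy rates at its stable fixed
point and the parkinsonian set reproduces the parkinsonian rates as
limit-cycle means, which is also the physiologically correct direction
(GPe autonomous activity is high and falls in PD).

## Dynamical structure of the progression path

Progression is the linear interpolation `w(k) = w_h + k (w_PD − w_h)`.
Continuation of the healthy fixed point along `k` shows:

* the branch deforms smoothly (GPe rate falling from 65 to ~26 spikes/s)
  and remains a stable spiral up to `k ≈ 0.996`;
* around `k ≈ 0.985` a saddle/node pair is born elsewhere in state space;
* at `k* ≈ 0.9961` the healthy fixed point annihilates against the saddle
  (a fold), leaving the beta-band relaxation limit cycle as the only
  attractor.

The destabilisation is therefore located by `bifurcation_scan` as the
smallest `k` at which the continued healthy branch either loses linear
stability or ceases to exist (continuation at step `1e-3`, bisection to
`1e-4`). Just before the fold the branch eigenvalues are a weakly damped
complex pair (≈ −29 ± 13i s⁻¹), so the approach to the transition looks
like a slowing spiral even though the final event is a fold rather than a
smooth eigenvalue crossing. Near `k = 1` the parkinsonian state is barely
past the fold: removing even the small striatal input (0.2) moves the
deterministic system back to the stable side. Physiological noise erases
that distinction (see the blockade constraint below).

## Numerical choices

* **Deterministic integration**: `scipy.integrate.solve_ivp` with LSODA,
  `rtol 1e-6`, `atol 1e-8`, resampled to a uniform output step. Default
  initial condition is the zero-input baseline `(B_S, B_G)`.
* **Oscillation detection**: a trajectory is oscillatory when the
  post-transient GPe peak-to-trough exceeds 1 spike/s (limit cycles swing
  by tens of spikes/s; numerical ripple is orders of magnitude below).
  Frequency is the dominant peak of a Hann-windowed FFT of the
  mean-removed GPe rate with parabolic log-power interpolation (sub-bin
  resolution on the 2–4 s windows used). Default transient: 1 s, i.e.
  >100 relaxation times.
* **Fixed points / stability**: Newton iterations with the analytic 2×2
  Jacobian (chain rule through `f_i`); multi-start on a coarse grid for
  root inventories. Residual tolerances are set relative to the drift
  scale (|x|/tau ~ 1e4 spikes/s²).
* **Stochastic dynamics**: Euler–Maruyama with additive isotropic noise of
  intensity `2D`, reflecting boundaries at the physical rate bounds
  `[0, M_i]`, default `dt = 0.5 ms`. At this step the scheme inflates
  stationary variances by O(|lambda| dt / 2) ≈ 15% at the strongly damped
  healthy state; analyses that compare against closed forms use
  `dt = 0.1 ms`.

## Noise level

The diffusion coefficient is a free parameter of the analysis; `D = 5
spikes²/s³` per dimension is the package default and every scan reports the
`D` it used. At this level the healthy-state fluctuations have sub-spikes/s
standard deviation (the fixed point is strongly damped, |Re lambda| ≈ 300
s⁻¹), the noisy circuit sustains near-full-amplitude oscillations slightly
beyond the deterministic fold, and all indicator trends are well resolved
at desk-scale ensembles. Absolute values of EPR, flux and ΔC scale with
`D`; trends in `k` and orderings between conditions are what the package
asserts.

## Stationary Fokker–Planck solve

`steady_state_density` discretises the stationary equation
`div(F P) − D lap(P) = 0` with a finite-volume scheme and
Scharfetter–Gummel (exponential-fitting) face fluxes. The drift is huge
compared with `D` on any affordable mesh (cell Peclet numbers in the
thousands); exponential fitting keeps the solution non-negative and is
exact for one-dimensional gradient systems, so the double-well Boltzmann
oracle is recovered to discretisation error. The one-dimensional null
space of the discrete generator is found by a direct sparse solve with the
normalisation row replacing one (redundant) balance equation. Boundaries
are no-flux everywhere, matching the reflecting Langevin bounds.

Mesh selection: when the deterministic system has a stable fixed point the
mesh is a window of ±max(10 sigma_lin, 1 spikes/s) around it (sigma_lin
from the Lyapunov equation of the linearisation), 120² cells; otherwise
the full state box `[0, 300] × [0, 400]` at 150×200 cells. The full box is
used for oscillatory states because the parkinsonian cycle spans
`x_S ∈ [12, 151]`, `x_G ∈ [26, 158]` spikes/s and any tighter window
creates spurious boundary attractors where the outward drift is blocked.
The potential uses a probability floor of `1e-12` before the logarithm.

Flux is evaluated as `J = F P − D grad P` by central differences; EPR and
the entropy flow to the environment as cell sums of `(J·J)/(D P)` and
`(J·F)/D` (cells below the floor excluded and their mass reported). On the
well-resolved rotational Ornstein–Uhlenbeck benchmark the grid EPR, the
closed form `tr(MᵀM S)/D` with `M = A + D S⁻¹`, and a Monte-Carlo path
average of `|J/P|²/D` agree within a few percent; at the healthy circuit
fixed point the grid EPR matches the linearised closed form to ~2%.

The scalar "mean flux" is `∫|J| dx` — the probability-weighted mean speed
of the probability current (an unweighted grid mean of |J| is available as
an option). Note that the healthy state itself is rotational (complex
eigenvalues), so its mean flux is small but far from zero; the error
function's floor therefore lies below the healthy value, and all
intervention comparisons are orderings, not absolute scales.

## Fitting

The cost is defined over the 12-parameter pair (both conditions jointly):
squared z-scores of the healthy mean rates, the parkinsonian mean rates
and the parkinsonian frequency (denominator 8 Hz), plus `+100` for each
violated constraint — far above the stop criterion of 1 so that a single
violation dominates all smooth terms. Constraints:

1. severing the STN–GPe loop (`w_SG = w_GS = 0`) must abolish the
   oscillation (checked on the noise-free system);
2. blocking striatal input (`Input_Str = 0`) must not reduce the GPe
   oscillation amplitude. Because the parkinsonian state sits just past a
   fold, the noise-free check is misleading (an infinitesimally small
   parameter change crosses the fold); the check therefore runs on the
   stochastic circuit at `D = 5` with a fixed internal seed, comparing
   central-95% amplitudes with 20% slack. The cost remains a
   deterministic function of the weights;
3. the STN and GPe oscillation amplitudes must agree within 50% of the
   larger (the deterministic cycle gives 5%).

Cost simulations use a 3 s horizon with a 1 s transient (0.5 Hz raw
frequency resolution, refined by peak interpolation). The shipped pair
evaluates to ≈ 0.0185.

Simulated annealing uses Gaussian proposals in log10-weight space within
the box `[1e-2, 100]`, Metropolis acceptance with geometric cooling, and
stops below the target cost or at the evaluation budget. The landscape is
harshly non-convex — small perturbations of the parkinsonian set fall off
the narrow oscillatory region onto a flat penalty plateau — so production
fits need generous budgets and hot starts, while the test suite exercises
parameter recovery from gentle perturbations with a cold, greedy schedule
(budget 300 evaluations). The fit is degenerate: many pairs reach cost < 1
without matching the shipped parameter values; recovery is asserted on the
simulated statistics, not the weights.

## Early-warning indicators

`ΔC(τ) = ⟨x_S(t) x_G(t+τ)⟩ − ⟨x_G(t) x_S(t+τ)⟩` is computed on
mean-centred series (a covariance convention: the raw-moment version
scales with the large, k-dependent mean rates and measures offsets rather
than irreversibility), with empirical averages normalised per lag count;
`ΔC(0) = 0` identically and swapping the channels flips the sign. The
per-realization scalar is `|mean of ΔC(τ) over τ ∈ [0, 0.15 s]|`
(~2 beta periods; the signed mean is stored alongside). For a sinusoid
pair with phase lag φ the curve is `sin(ωτ) sin(φ)` — the closed-form
oracle in the tests; for any detailed-balance system it vanishes in
expectation.

Indicators are estimated from synthetic recordings: 10 s at 200 Hz with
additive Gaussian observation noise of 0.5 spikes/s per channel — the
pipeline sees only what an implanted electrode would provide. Ensembles
default to 200 realizations per progression value in the shipped scans
(standard errors are reported and all trend assertions are
standard-error-aware); production-scale runs simply raise
`n_realizations`. The observation-noise floor enters both indicators: it
adds 0.25 spikes²/s² to every variance and a small positive bias to the
absolute-valued ΔC; the "detected earlier" comparison (relative growth of
ΔC above its baseline versus that of either channel variance at mid
progression) is made under exactly these recording conditions.

## Interventions

An intervention multiplies a target set of weights by `γ ∈ [0, 1]`
(`γ = 1` no intervention, `γ = 0` full block; `γ` may undershoot the
healthy value). Preset target sets: `intervention1 = {w_SC}` and
`intervention6 = {w_SG, w_SC, w_GS, w_GG, w_SS}` (all connections
strengthened by dopamine loss) are canonical; presets 2–5
(`{w_GS}`, `{w_SS}`, `{w_SC, w_SS}`, `{w_SG, w_GS}`) are package
reconstructions spanning single- and multi-edge excitatory targets, with
1–4 acting on STN excitation. `Input_Str` is interpolated with `k` but is
never an intervention target. `restoring_strategy` builds per-target
coefficients that return each weight exactly to its healthy value.

The error function `J² + Σ((H^e − x^s)/H^σ)²` combines the mean flux at
the intervened weights with the deviation of simulated mean rates from the
healthy targets. In the early-intervention time course the circuit runs
noisily at `w(k_start)` until the intervention time, then at the
intervened weights (k frozen within the simulated seconds — degeneration
and circuit dynamics are on separated timescales); the final 2 s window is
scored with empirical rates, and "restored" requires a non-oscillatory
tail (central-95% GPe range < 10 spikes/s) within one healthy sigma of
the healthy rates.

## Problem sizes

Default scans use 120²–150×200 grid cells, 200-realization ensembles of
10 s recordings, 300-evaluation annealing recoveries and 1e-3/1e-4
continuation/bisection steps; these resolve every asserted trend with
reported standard errors. All of them are parameters, and larger values
only sharpen the estimates.

## Limitations

* Absolute EPR/flux/ΔC values scale with the unobservable noise intensity
  `D`; only trends and orderings are meaningful.
* At `D = 5` the stationary density at strongly stable fixed points is
  narrower than any affordable full-domain cell, so full-box landscapes
  localise such states to ~1 cell; the zoomed windows exist for exactly
  this reason, and EPR at small `k` is validated against the linearised
  closed form rather than grid refinement.
* The synthetic recordings share the generating model's dynamics; passing
  indicator tests demonstrates the statistical machinery under the model's
  own assumptions (additive Gaussian noise, stationarity within a
  recording), not robustness to real electrode artefacts, nonstationarity
  or model mismatch.
* The transition is a fold of the healthy fixed point, not a smooth
  eigenvalue crossing; the reported `k*` is the branch-disappearance
  point, and agreement with direct-simulation onset is asserted to 0.005
  in `k`.
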