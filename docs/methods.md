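# Methods

## The model

`thalcort` implements a four-population neural-mass model of the
thalamocortical loop implicated in absence epilepsy.  The state
`(PY, IN, TC, RE)` holds the mean fractional firing activity of cortical
pyramidal cells, cortical interneurons, thalamocortical relay cells and the
thalamic reticular nucleus:

    dPY/dt = tau_e (h_e - PY + c_ee f[PY] - c_ei f[IN] + c_et f[TC])
    dIN/dt = tau_i (h_i - IN + c_ie f[PY])
    dTC/dt = tau_t (h_t - TC + c_te f[PY] - c_tr s[RE])
    dRE/dt = tau_r (h_r - RE + c_re f[PY] + c_rt s[TC] - c_rr s[RE])

with the steep cortical sigmoid `f[x] = 1/(1 + eps^-x)` (eps = 2e5, computed
as `expit(x ln eps)` to avoid overflow) and the linear thalamic activation
`s[x] = a x + b` (a = 2.8, b = 0.5).  The simulated EEG is
`y = c1 PY + c2 IN` with `c1 = c2 = 0.5`.  Defaults for every symbol are in
`ModelParameters`; the two couplings of interest are the top-down cortical
drive `c_te` (PY→TC) and the feedforward reticular inhibition `c_tr`
(RE→TC).

Units: the rate constants `tau_*` are interpreted as 1/s, which puts the
spike-and-wave rhythm at 3 Hz on a 1 ms grid — the frequency observed
clinically and reproduced by the package's own measurements.  State
variables are dimensionless ("fractional activity"); all amplitudes quoted
below are in those units.

## Simulation protocol

Classical fixed-step RK4 at dt = 1 ms is the reference protocol; no adaptive
or stiff solvers.  All exogenous inputs — stimulation pulses, background
noise, control signals — are held constant over the four stages of a step
(zero-order hold) and **add directly to the state derivative**
(`dx/dt = F(x) + u + d`).  This keeps the control channel at unit gain, which
is what the tracking-error dynamics of the controller design assume.  An
input of amplitude A on RE for 20 ms therefore displaces RE by roughly
0.02 A.

Background noise is a Gaussian value redrawn once per 1 ms step (default
mean 0, sd 1, on RE).  The sd is in derivative units per step and is *not*
scaled by sqrt(dt): halving the step would halve the effective noise power.
This zero-order-hold convention keeps RK4 valid and matches the qualitative
role of the noise; it is a modelling choice, not an SDE discretisation.

`simulate_ensemble` integrates many initial states (and many parameter
points) in one vectorised pass; all parameter-plane machinery is built on
it.  Seeded `numpy` generators make every stochastic path bit-reproducible.

## Regime classification

Noise-free probe trajectories are classified from the observed EEG after a
transient discard (default 10 s; convergence onto the two-spike cycle at
(c_tr, c_te) = (0.45, 3) takes ~8 s):

1. **Steady** if the analysis window's peak-to-peak is below 1e-3; LS vs HS
   by comparing the level with 0.35 (midpoint of the measured LS level 0.174
   at (0.15, 2.3) and HS level 0.528 at (0.15, 3)).
2. **Transient guard**: if the last quarter-window peak-to-peak falls below
   0.8x the first quarter's, the trace is a decaying transient and is
   reported UNRESOLVED, never guessed.  For any sustained cycle every
   quarter-window spans at least one period, so its peak-to-peak equals the
   full amplitude and the guard never fires; slowly decaying ringing near a
   supercritical Hopf (critical slowing) is exactly what it catches.
3. **Fundamental frequency** from the autocorrelation: the first peak whose
   (overlap-corrected) height is within 10 % of the tallest.  The tallest-
   family rule matters because the FFT-dominant frequency of a
   spike-and-wave cycle is often a harmonic — the spike train carries more
   power than the cycle rate (e.g. the SWD at (1.5, 3.5): cycle 4.74 Hz,
   FFT peak 9.5 Hz).  `dominant_frequency` (plain FFT argmax) is what gets
   *reported*, matching the conventional measurement; the fundamental is
   what the classifier *segments* by.
4. **TO** if the fundamental is at or above 10 Hz.  Measured gap: tonic
   oscillations run at >= 15 Hz, everything else at <= 4.8 Hz; 10 Hz bisects
   it.  (The tonic rate dips toward 15 Hz as the TO cycle dies, so a 15 Hz
   floor would sit exactly on the boundary.)
5. Otherwise count **narrow prominent maxima per cycle**: prominence
   >= 0.03x peak-to-peak, width < 0.3x the cycle.  Measured spike widths are
   0.04–0.24 of the cycle; broad wave crests are >= 0.36.  The modal count m
   over complete cycles gives **m-SWD**; zero narrow spikes gives **CO**.
   This narrow/broad split is the SWD-vs-CO discriminator: a clonic
   oscillation is a large slow wave without a sharp spike.

The thresholds were calibrated once against the published waveform anchors
at c_tr = 0.15 (5/4/3/2-spike discharges at c_te = 2.36–2.65, TO at 1.0,
LS at 2.3, HS at 3.0) and then frozen; all are exposed in
`ClassificationConfig`.

## Equilibria, continuation and bifurcations

At a fixed point the IN equation is explicit in PY and the TC/RE equations
are linear in (TC, RE), so the equilibrium problem reduces *exactly* to one
scalar equation in PY.  `find_equilibria` scans that residual over
PY ∈ [-6, 3], bisects every sign change, reassembles the state in closed
form and polishes with Newton — deterministic and exhaustive, which matters
because the background state's basin can be far too small for random
probing to find (see below).

`continue_equilibria` follows a branch in one parameter by pseudo-arclength
continuation (secant tangent, orthogonal corrector), recording the Jacobian
spectrum; `detect_hopf` bisects sign changes of the leading complex-pair
real part to 1e-4 in the parameter and reports the crossing frequency
|Im λ|/2π.  Real-eigenvalue crossings are classified separately.

Stable limit cycles are tracked by attractor following (slow parameter ramp
reusing the final state), not by collocation or shooting.  A fold of cycles
(`estimate_double_cycle`) is reported where the cycle's amplitude drops
discontinuously (> 0.05) during an up- or down-ramp, refined by bisection;
a supercritical Hopf, where the amplitude shrinks smoothly to zero, produces
none.  Unstable cycles are not tracked — only the hysteresis edges they
cause are visible, which is sufficient to locate the folds.

## Multistability probing

Random initial states in the box [-4, 1]^4 find the large-basin attractors
but systematically miss the background state in the multistable regimes —
at (0.45, 3) even 300 random states in [-6, 2]^4 all reach the two-spike
cycle although a stable LS equilibrium exists.  `multistability_probe`
therefore combines three sources: (1) n seeded random states (prefix-stable
in n under a fixed seed, so discovery is monotone); (2) every stable
equilibrium from the exhaustive scan; (3) one round of 20 ms pulses on RE
(amplitudes ±5, ±10, ±15) applied at 12 phases of each oscillatory attractor
found — the same protocol that switches states in the pulse-stimulation
experiments.  Attractors are de-duplicated by label kind, spike count, and
(for steady states) level.

With this probe the strong-coupling point (1.5, 3.5) yields the three
coexisting states LS, SWD and CO.  At (0.45, 3) the probe finds exactly two
attractors, LS and 2-SWD; the larger single-spike oscillation seen there in
short segments is a ~8 s transient that always settles into the 2-SWD (also
at dt = 0.25 ms), so the package reports bi-, not tri-, stability at that
point.

## The coupling-plane region map

`two_param_map` probes every cell of a (c_tr, c_te) grid with n random
states plus the cell's stable equilibria, labels the cell with the set of
coexisting state kinds (spike counts are not distinguished at this level),
and merges cells with identical sets into regions.  `n_regions` counts
distinct coexistence sets — the number of qualitatively different regimes —
which is robust to a region being split into several spatial patches;
`patches()` gives the spatial components.  The default domain
[0, 1.6] × [0.8, 4.0] covers all published anchor points.  On a 25×25 grid
with 5 probes per cell the census finds 11 distinct regions, including a
genuine TO+LS bistable strip at near-zero feedforward inhibition (confirmed
with 46 s probes).  Finer grids reveal two more rare boundary sets (among
them the tri-stable LS+SWD+CO cells), so the census grows slowly with
resolution; treat the count as a structural summary, not an invariant.

## Controllers

Tracking formulation: force `y` to follow a desired normal trace `y_d`.
The sliding variable is the raw error, `s = e = y - y_d` (the plant is
first-order in the observation, so no error derivative is needed).  The
four laws, all applied identically to PY and IN (`u1 = u2 = u`,
`u3 = u4 = 0`):

| method         | law                                   |
|----------------|---------------------------------------|
| `feedback`     | u = -λ s                              |
| `feedback+rbf` | u = -λ s - θ̂ᵀφ(s)                    |
| `feedback+smc` | u = -λ s - ρ z                        |
| `hybrid`       | u = -λ s - θ̂ᵀφ(s) - ρ z              |

φ(s) is a vector of m Gaussian bumps (default m = 11, centers uniform on
[-1, 1], width p = 1 — the error is O(1) before control) approximating the
unknown lumped drift of the error dynamics.  The weight adaptation is

    dθ̂/dt = γ s φ(s) - k_c γ |s| θ̂        (γ = 10, k_c = 1)

— a gradient term plus sigma-modification leakage.  The gradient term's sign
is fixed by the Lyapunov argument: with `V = s²/2 + θ̃ᵀθ̃/(2γ)` the weight-
error cross-term cancels only for `+γsφ`; the opposite sign turns the RBF
channel into positive feedback (numerically: the loop locks at a large
constant error).  γ is not critical — closed-loop suppression holds for
γ ∈ {1, 10, 100} (tested) — and explicit Euler at the 1 ms plant step is
adequate for that range.

The switching term uses the convention sign(0) = +1 and is low-pass filtered
(τ = 10 ms, exact exponential update, so the filter is dt-independent) to
remove chattering; the raw-sign variant is kept for comparison and the mean
|Δu| chattering metric of the filtered law is verified lower.  Discrete-time
loop order: measure → update filter and weights → compute u → one RK4 plant
step with u held constant.  Before the switch-on time (default 4 s) the
controller is inert.

Because u has unit gain into dPY/dt and dIN/dt while the cortical rates are
τ_e = 26, τ_i = 32.5 /s, λ = 1 is *weak* proportional feedback — which is
why the RBF and switching terms contribute visibly and the four methods
separate (hybrid < smc < rbf < feedback in tracking RMS, hybrid costs the
most control energy).

`lyapunov_diagnostics` returns `s²/2` and the estimable functional
`s²/2 + θ̂ᵀθ̂/(2γ)` (the ideal weights being unknowable); tests assert
ultimate boundedness on these, not asymptotic convergence — with persistent
noise and disturbances the error is uniformly ultimately bounded, not zero.

## Variance-triggered on-demand control

The seizure detector is the moving-window variance of y (window 0.5 s,
slide 0.05 s).  Background activity with sd-1 noise on RE keeps the windowed
variance near 3e-5; a spike-and-wave state sits near 1.5e-2; the threshold
0.002 separates them by two orders of magnitude.  When the variance exceeds
the threshold continuously for 0.1 s, plain feedback control engages for
1 s.  If the state has not re-entered the background basin after an action,
the variance remains high and the trigger re-arms — with λ = 1 the typical
pulse-induced seizure needs ~3 consecutive actions before capture.  Events
are logged as timed on/off pairs.

## Reference signals

*Background reference* (`generate_background_reference`): the model itself
at the control point, started exactly on the stable LS equilibrium with
sd-1 noise on RE.  *Alpha surrogate* (`generate_alpha_surrogate`):
band-passed Gaussian noise (4th-order Butterworth, default 12 ± 1.5 Hz),
scaled to a requested peak-to-peak (default 0.3, roughly three times the
background trace's excursion) — a stand-in for a clinical alpha-band scalp
channel with the right spectrum but none of a real recording's artifacts,
nonstationarity or amplitude drift.  `load_reference_from_file` accepts a
(t, value) CSV or, when `mne` is installed, an EDF channel, resampled
linearly to the plant grid.  How a clinical trace should be scaled into
model units is a free choice; `rescale_ptp` exposes it.

## What the synthetic data does and does not show

Everything here is simulation of the stated equations: there is no
observation model of scalp EEG beyond `y = (PY + IN)/2`, the noise is white
and stationary, disturbances are rectangular pulses, and the alpha surrogate
is spectrally — not physiologically — realistic.  Passing tests show the
dynamical and control claims hold for the model; they say nothing about
electrode noise, artifacts, patient variability or the safety of actual
stimulation.

## Problem sizes and numerical defaults

Tests and the acceptance script run the protocol at desk scale, chosen to
keep every measured quantity converged: 16–24 s trajectories at 1 ms for
single runs, a 25×25 coupling grid with 5 random probes + equilibrium seeds
per cell (30 s settle), 50-initial multistability probes, 10 disturbance
seeds for the boundedness check.  Equilibrium residual tolerance 1e-10;
Hopf localisation 1e-4 in the parameter; fold-of-cycles amplitude
discontinuity threshold 0.05 with 1e-4 bisection; probe box [-4, 1]^4.
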