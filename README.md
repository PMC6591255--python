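# thalcort

Thalamocortical neural-mass dynamics of absence epilepsy, and closed-loop
control strategies for abating spike-and-wave discharges — for computational
neuroscientists studying seizure dynamics and control engineers prototyping
responsive neurostimulation in silico.

## The model

Absence seizures show as 2.5–4 Hz spike-and-wave discharges (SWD) in the
EEG, generated by the loop between cortex and thalamus.  `thalcort`
implements a four-population neural-mass model of that loop — cortical
pyramidal cells (PY) and interneurons (IN), thalamocortical relay cells (TC)
and the reticular nucleus (RE):

```
dPY/dt = τ_e (h_e − PY + c_ee f[PY] − c_ei f[IN] + c_et f[TC])
dIN/dt = τ_i (h_i − IN + c_ie f[PY])
dTC/dt = τ_t (h_t − TC + c_te f[PY] − c_tr s[RE])
dRE/dt = τ_r (h_r − RE + c_re f[PY] + c_rt s[TC] − c_rr s[RE])
```

with sigmoid cortical activation `f[x] = 1/(1+ε^−x)`, linear thalamic
activation `s[x] = ax + b`, and simulated EEG `y = c₁·PY + c₂·IN`.
Depending on the top-down drive `c_te` and the feedforward inhibition
`c_tr`, the model produces normal background activity (LS), saturated
states (HS), fast tonic (TO) and slow clonic (CO) oscillations, and m-spike
SWDs — often several of these coexisting, so that a single pulse can flip
the brain state between them.

On top of the simulator the package provides:

- **Dynamics analysis** — regime classification, attractor censuses over
  one- and two-parameter sweeps, multistability probing, equilibrium
  continuation with Hopf detection, and fold-of-cycles (hysteresis-edge)
  estimation.
- **Closed-loop control** — seizure abatement cast as tracking a normal
  reference EEG, with the sliding variable `s = e = y − y_d` and four laws:
  plain feedback `u = −λs`, RBF-network adaptive `u = −λs − θ̂ᵀφ(s)` (with
  adaptation `θ̂̇ = γsφ − k_c γ|s|θ̂`), filtered sliding-mode
  `u = −λs − ρz` (`τ ż = −z + sign(s)`), and the hybrid combining all
  three.  Plus a variance-threshold trigger for on-demand stimulation.
- **Reference generators** — a model-generated background trace and a
  12 Hz alpha-band surrogate, plus a CSV/EDF loader for real traces.

## Worked example

```python
import numpy as np
import thalcort as tc

params = tc.ModelParameters()                    # the absence-epilepsy point
traj = tc.simulate(params, np.zeros(4), 20.0)    # noise-free, dt = 1 ms
label = tc.classify_state(traj)
freq = tc.dominant_frequency(traj.y, traj.dt, transient_discard=10.0)
print(f"open-loop state: {label} at {freq:.2f} Hz")

ref = tc.generate_background_reference(params, 16.0, seed=1)
report = tc.compare_methods(
    params, np.zeros(4), ref, tc.ControllerConfig(),
    noise=tc.NoiseSpec(sd=1.0, seed=2), disturbance_seed=3,
    duration=16.0,
)
print(report.stats[["rms_e", "rms_u"]].round(4))
```

prints

```
open-loop state: 1-SWD at 3.00 Hz
               rms_e   rms_u
method
feedback      0.0101  0.0101
feedback+rbf  0.0085  0.1073
feedback+smc  0.0048  0.4830
hybrid        0.0045  0.4750
```

Read: left uncontrolled, the default coupling point (c_tr = 0.6, c_te = 3)
sits on a 3 Hz single-spike SWD — the electrographic signature of an
absence seizure.  Under closed-loop control tracking a noisy background
reference, with Gaussian noise and random pulse disturbances on RE, the
hybrid controller tracks best (smallest RMS error over the last 12 s,
roughly half the plain-feedback error here), and its robustness costs
control energy: its RMS control signal is ~47× the plain-feedback one.

A CLI mirrors the library (`thalcort simulate|scan1d|map2d|pulse|control|
trigger|report`), each subcommand taking a YAML config and writing tidy
CSV plus a `run.json` provenance record.

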