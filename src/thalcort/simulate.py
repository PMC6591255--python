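"""Fixed-step RK4 integration with pulses, noise and control inputs.

The integration protocol is deliberately plain: classical fourth-order
Runge-Kutta with a fixed step (default 1 ms), exogenous inputs held constant
across the four stages of each step (zero-order hold) and added directly to
the target population's state derivative.  Background noise is a Gaussian
value redrawn once per step; its standard deviation is in derivative units
per step, not scaled by sqrt(dt), so the effective noise power depends on the
step size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import eeg_observation, model_rhs
from .params import ModelParameters, POPULATIONS, population_index

__all__ = [
    "PulseTrainSpec",
    "NoiseSpec",
    "Trajectory",
    "integrate_step",
    "simulate",
    "simulate_ensemble",
    "single_pulse_experiment",
    "poisson_pulse_train",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """Rectangular pulse train on one or more populations.

    Each pulse holds ``amplitude`` on the target population(s) for ``width``
    seconds starting at each onset time.
    """

    onset_times: tuple[float, ...]
    amplitude: float
    width: float = 0.02
    target: tuple[str, ...] = ("RE",)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be > 0")
        onsets = tuple(float(t) for t in self.onset_times)
        if any(t < 0 for t in onsets):
            raise ValueError("onset times must be non-negative")
        if list(onsets) != sorted(onsets):
            raise ValueError("onset times must be sorted")
        object.__setattr__(self, "onset_times", onsets)
        tgt = (self.target,) if isinstance(self.target, str) else tuple(self.target)
        for name in tgt:
            population_index(name)
        object.__setattr__(self, "target", tgt)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Per-population input array of shape (len(t), 4)."""
        out = np.zeros((len(t), 4))
        active = np.zeros(len(t), dtype=bool)
        for onset in self.onset_times:
            active |= (t >= onset) & (t < onset + self.width)
        for name in self.target:
            out[active, population_index(name)] = self.amplitude
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian background noise, redrawn each step (zero-order hold)."""

    sd: float = 1.0
    mean: float = 0.0
    target: tuple[str, ...] = ("RE",)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        tgt = (self.target,) if isinstance(self.target, str) else tuple(self.target)
        for name in tgt:
            population_index(name)
        object.__setattr__(self, "target", tgt)


@dataclass
class Trajectory:
    """Simulated trajectory on a uniform time grid.

    ``u`` and ``d`` follow the zero-order-hold convention: index ``i`` is the
    input held on the step from ``t[i]`` to ``t[i+1]`` (the final entry is 0).
    """

    t: np.ndarray          # (n+1,)
    states: np.ndarray     # (n+1, 4)
    y: np.ndarray          # (n+1,)
    u: np.ndarray          # (n+1,) control applied to PY and IN
    d: np.ndarray          # (n+1,) disturbance applied (sum over targets)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("states", "y", "u", "d"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trajectory series {name!r} does not match the time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                **{name: self.states[:, i] for i, name in enumerate(POPULATIONS)},
                "y": self.y,
                "u": self.u,
                "d": self.d,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path: str | Path) -> None:
        """Compact binary export (numpy .npz)."""
        np.savez_compressed(path, t=self.t, states=self.states, y=self.y,
                            u=self.u, d=self.d)

    @classmethod
    def from_npz(cls, path: str | Path) -> "Trajectory":
        with np.load(path) as data:
            return cls(**{k: data[k] for k in ("t", "states", "y", "u", "d")})


def integrate_step(state, params: ModelParameters, dt: float, exogenous=None):
    """One classical RK4 step; ``exogenous`` held constant across stages."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    st = np.asarray(state, dtype=float)
    k1 = model_rhs(st, params, exogenous)
    k2 = model_rhs(st + 0.5 * dt * k1, params, exogenous)
    k3 = model_rhs(st + 0.5 * dt * k2, params, exogenous)
    k4 = model_rhs(st + dt * k3, params, exogenous)
    out = st + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(out)):
        bad = np.where(~np.isfinite(np.atleast_2d(out)))[-1]
        name = POPULATIONS[int(bad[0]) % 4]
        raise FloatingPointError(f"integration diverged in state component {name}")
    return out


def poisson_pulse_train(
    duration: float,
    rate: float = 0.25,
    amplitude: float = 2.0,
    width: float = 0.02,
    target: Sequence[str] = ("RE",),
    seed: int | None = None,
    random_sign: bool = True,
) -> list[PulseTrainSpec]:
    """Randomly distributed rectangular pulses (Poisson arrivals).

    Models unexpected projections from other brain areas: arrivals at the
    given rate (1/s), rectangular shape, amplitude with random sign when
    ``random_sign`` is set.  Returns one single-onset spec per pulse so signs
    can differ.
    """
    rng = np.random.default_rng(seed)
    t = 0.0
    specs: list[PulseTrainSpec] = []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        amp = amplitude * (rng.choice([-1.0, 1.0]) if random_sign else 1.0)
        specs.append(
            PulseTrainSpec(onset_times=(t,), amplitude=amp, width=width, target=tuple(target))
        )
    return specs


def simulate(
    params: ModelParameters,
    initial,
    duration: float,
    dt: float = 0.001,
    pulses: Iterable[PulseTrainSpec] = (),
    noise: NoiseSpec | None = None,
    control_input: Callable[[float, np.ndarray, float], float] | None = None,
    control_targets: Sequence[str] = ("PY", "IN"),
) -> Trajectory:
    """Integrate the model over ``[0, duration]`` on a fixed grid.

    ``control_input(t, state, y) -> u`` (optional) is evaluated once per step
    and routed to ``control_targets``.  With identical seeds and inputs the
    trajectory is reproducible bit for bit.
    """
    if duration <= dt:
        raise ValueError("duration must exceed dt")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    st = np.asarray(initial, dtype=float).copy()
    if st.shape != (4,):
        raise ValueError("initial state must have shape (4,)")

    d_wave = np.zeros((n + 1, 4))
    for spec in pulses:
        d_wave += spec.waveform(t)
    noise_targets: list[int] = []
    rng = None
    if noise is not None and noise.sd >= 0:
        rng = np.random.default_rng(noise.seed)
        noise_targets = [population_index(p) for p in noise.target]
    ctrl_idx = [population_index(p) for p in control_targets]

    states = np.empty((n + 1, 4))
    y = np.empty(n + 1)
    u = np.zeros(n + 1)
    d_rec = np.zeros(n + 1)
    states[0] = st
    y[0] = eeg_observation(st, params)
    for i in range(n):
        exo = d_wave[i].copy()
        if rng is not None:
            w = noise.mean + noise.sd * rng.standard_normal()
            for j in noise_targets:
                exo[j] += w
        d_rec[i] = exo.sum()   # total disturbance before the control term
        if control_input is not None:
            ui = float(control_input(t[i], st, y[i]))
            u[i] = ui
            for j in ctrl_idx:
                exo[j] += ui
        try:
            st = integrate_step(st, params, dt, exo)
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at t = {t[i]:.3f} s") from None
        states[i + 1] = st
        y[i + 1] = eeg_observation(st, params)
    return Trajectory(t=t, states=states, y=y, u=u, d=d_rec)


def simulate_ensemble(
    params: ModelParameters,
    initials,
    duration: float,
    dt: float = 0.001,
    record_last: float | None = None,
    overrides: dict[str, np.ndarray] | None = None,
    exogenous=None,
    chunk: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many noise-free trajectories at once (vectorized RK4).

    ``initials`` has shape (N, 4); ``overrides`` maps parameter names (e.g.
    ``c_tr``) to length-N arrays so every ensemble member may sit at its own
    point of the coupling plane.  Returns ``(final_states, y_window)`` where
    ``y_window`` holds the observed EEG over the trailing ``record_last``
    seconds (the whole run when None).  Processing is chunked to bound memory.
    """
    inits = np.atleast_2d(np.asarray(initials, dtype=float))
    n_tot = inits.shape[0]
    n = int(round(duration / dt))
    keep = n + 1 if record_last is None else min(n + 1, int(round(record_last / dt)))
    finals = np.empty_like(inits)
    ys = np.empty((n_tot, keep))
    overrides = overrides or {}
    for lo in range(0, n_tot, chunk):
        hi = min(lo + chunk, n_tot)
        sub = {k: np.asarray(v)[lo:hi] for k, v in overrides.items()}
        p = params.replace(**sub) if sub else params
        st = inits[lo:hi].copy()
        buf = np.empty((hi - lo, keep))
        k0 = n + 1 - keep
        if k0 == 0:
            buf[:, 0] = eeg_observation(st, p)
        for i in range(n):
            k1 = model_rhs(st, p, exogenous)
            k2 = model_rhs(st + 0.5 * dt * k1, p, exogenous)
            k3 = model_rhs(st + 0.5 * dt * k2, p, exogenous)
            k4 = model_rhs(st + dt * k3, p, exogenous)
            st += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if i + 1 >= k0:
                buf[:, i + 1 - k0] = eeg_observation(st, p)
        if not np.all(np.isfinite(st)):
            raise FloatingPointError("ensemble integration diverged")
        finals[lo:hi] = st
        ys[lo:hi] = buf
    return finals, ys


def single_pulse_experiment(
    params: ModelParameters,
    initial,
    pulses: Sequence[PulseTrainSpec],
    duration: float,
    dt: float = 0.001,
    classification_config=None,
    segment_discard: float = 6.0,
):
    """Run a pulse-stimulation experiment and label each inter-pulse segment.

    Segments run from one pulse offset to the next pulse onset (the first
    from t=0, the last to the end of the run); each is classified after
    discarding ``segment_discard`` seconds of post-pulse transient (less on
    segments too short for it, keeping a 2 s analysis window).  Returns
    ``(trajectory, labels)``.
    """
    import dataclasses

    from .analysis import ClassificationConfig, classify_series

    base = classification_config or ClassificationConfig()
    traj = simulate(params, initial, duration, dt=dt, pulses=pulses)
    onsets = sorted(t for spec in pulses for t in spec.onset_times)
    widths = {t: spec.width for spec in pulses for t in spec.onset_times}
    edges = [0.0] + [t for t in onsets] + [duration]
    labels = []
    for k in range(len(edges) - 1):
        a = edges[k] + (widths.get(edges[k], 0.0) if k > 0 else 0.0)
        b = edges[k + 1]
        i0, i1 = int(round(a / dt)), int(round(b / dt))
        discard = max(min(segment_discard, (b - a) - 2.0), 1e-9)
        cfg = dataclasses.replace(base, transient_discard=discard)
        labels.append(classify_series(traj.y[i0:i1], dt, cfg))
    return traj, labels
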