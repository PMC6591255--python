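"""Closed-loop seizure-abatement controllers.

Seizure abatement is cast as a tracking problem: drive the simulated EEG
``y = c1*PY + c2*IN`` to follow a desired normal trace ``y_d(t)``.  The
sliding variable is simply the tracking error, ``s = e = y - y_d``.  Four
controller laws are provided, all sharing the proportional reaching term
``-lam*s``:

======================  =====================================================
method                  control law
======================  =====================================================
``feedback``            u = -lam*s
``feedback+rbf``        u = -lam*s - theta_hat' phi(s)
``feedback+smc``        u = -lam*s - rho*z          (filtered switching)
``hybrid``              u = -lam*s - theta_hat' phi(s) - rho*z
======================  =====================================================

phi(s) is a Gaussian radial-basis vector approximating the unknown lumped
drift of the error dynamics, with adaptive weights

    d(theta_hat)/dt = -gamma*s*phi - k_c*gamma*|s|*theta_hat

(a gradient term plus sigma-modification leakage, keeping the weights
bounded).  The discontinuous switching term sign(s) — with the convention
sign(0) = +1 — is low-pass filtered, tau_f * dz/dt = -z + sign(s), to remove
chattering; the raw-sign variant is available for comparison.

The control signal is applied identically to PY and IN (u1 = u2 = u,
u3 = u4 = 0), entering each population's bracket like every other exogenous
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import eeg_observation
from .params import ModelParameters, population_index
from .reference import ReferenceSignal
from .simulate import NoiseSpec, PulseTrainSpec, Trajectory, integrate_step

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "TriggerConfig",
    "ClosedLoopResult",
    "sliding_surface",
    "sign_law",
    "rbf_basis",
    "update_nn_weights",
    "lpf_step",
    "control_output",
    "closed_loop_simulate",
    "variance_trigger_control",
    "lyapunov_diagnostics",
]

_METHODS = ("feedback", "feedback+rbf", "feedback+smc", "hybrid")


@dataclass(frozen=True)
class ControllerConfig:
    """Gains and structure of the tracking controller."""

    lam: float = 1.0            # reaching-law gain
    rho: float = 1.0            # switching gain
    k_c: float = 1.0            # leakage (sigma-modification) gain
    gamma: float = 10.0         # adaptation rate
    n_nodes: int = 11           # RBF node count
    width: float = 1.0          # Gaussian width of the RBF nodes
    centers: tuple[float, ...] | None = None   # default: uniform on [-1, 1]
    tau_filter: float = 0.01    # s, low-pass filter time constant
    method: str = "hybrid"
    switch_on_time: float = 4.0  # s, u = 0 before this
    targets: tuple[str, ...] = ("PY", "IN")
    raw_sign: bool = False      # unfiltered sign(s) instead of z (chattering)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.gamma <= 0 or self.k_c <= 0:
            raise ValueError("gamma and k_c must be > 0")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.tau_filter <= 0:
            raise ValueError("tau_filter must be > 0")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.centers is None:
            object.__setattr__(
                self, "centers",
                tuple(np.linspace(-1.0, 1.0, self.n_nodes)),
            )
        elif len(self.centers) != self.n_nodes:
            raise ValueError("len(centers) must equal n_nodes")
        for t in self.targets:
            population_index(t)


@dataclass
class ControllerState:
    """Mutable controller memory: RBF weights, filter state, sliding value."""

    theta_hat: np.ndarray
    z: float = 0.0
    s_value: float = 0.0

    @classmethod
    def initial(cls, cfg: ControllerConfig) -> "ControllerState":
        return cls(theta_hat=np.zeros(cfg.n_nodes))


@dataclass(frozen=True)
class TriggerConfig:
    """Variance-based on-demand activation of the controller."""

    var_threshold: float = 0.002
    window: float = 0.5       # s, moving variance window
    step: float = 0.05        # s, window slide step
    sustain: float = 0.1      # s the variance must stay above threshold
    action_duration: float = 1.0  # s of control once triggered

    def __post_init__(self) -> None:
        for name in ("var_threshold", "window", "step", "sustain", "action_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.window <= self.step:
            raise ValueError("window must exceed step")


@dataclass
class ClosedLoopResult:
    """Trajectory plus controller histories of a closed-loop run."""

    trajectory: Trajectory
    y_d: np.ndarray
    e: np.ndarray
    s: np.ndarray
    z: np.ndarray
    theta_hat: np.ndarray      # (n+1, n_nodes)
    config: ControllerConfig
    trigger_events: list[tuple[float, str]] = field(default_factory=list)
    trigger_state: np.ndarray | None = None
    var_series: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.trajectory.to_frame()
        df["y_d"] = self.y_d
        df["e"] = self.e
        if self.var_series is not None:
            df["var_window"] = self.var_series
        if self.trigger_state is not None:
            df["trigger_state"] = self.trigger_state.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary laws

def sliding_surface(y: float, y_d: float) -> float:
    """Sliding variable s = tracking error e = y - y_d."""
    return y - y_d


def sign_law(s: float) -> float:
    """Switching law: +1 for s >= 0, -1 for s < 0 (sign(0) = +1)."""
    return 1.0 if s >= 0 else -1.0


def rbf_basis(s: float, centers, width: float) -> np.ndarray:
    """Gaussian radial basis vector phi_j = exp(-(s - c_j)^2 / (2 width^2))."""
    if width <= 0:
        raise ValueError("width must be > 0")
    c = np.asarray(centers, dtype=float)
    return np.exp(-((s - c) ** 2) / (2.0 * width**2))


def update_nn_weights(
    theta_hat: np.ndarray,
    s: float,
    phi: np.ndarray,
    gamma: float,
    k_c: float,
    dt: float,
) -> np.ndarray:
    """One explicit-Euler step of the adaptive law.

    d(theta_hat)/dt = gamma*s*phi - k_c*gamma*|s|*theta_hat: the gradient
    term is the one that cancels the weight-error cross-term in the Lyapunov
    rate when the RBF output enters the control as ``-theta_hat' phi(s)``
    (with the opposite sign the loop has positive feedback); the leakage term
    keeps the weights bounded.  Euler at the plant step is adequate for gamma
    up to ~100 at dt = 1 ms.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = theta_hat + dt * (gamma * s * phi - k_c * gamma * abs(s) * theta_hat)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("adaptive weights diverged")
    return out


def lpf_step(z: float, s: float, tau_filter: float, dt: float) -> float:
    """Exact exponential update of the switching-term low-pass filter.

    tau_f * dz/dt = -z + sign(s), integrated exactly over one step with
    sign(s) held constant: z <- sign(s) + (z - sign(s)) exp(-dt / tau_f).
    """
    if tau_filter <= 0 or dt <= 0:
        raise ValueError("tau_filter and dt must be > 0")
    target = sign_law(s)
    return target + (z - target) * np.exp(-dt / tau_filter)


def control_output(cfg: ControllerConfig, st: ControllerState) -> float:
    """Controller output for the configured method (switch-on handled by the
    closed-loop runner)."""
    s = st.s_value
    u = -cfg.lam * s
    if cfg.method in ("feedback+rbf", "hybrid"):
        phi = rbf_basis(s, cfg.centers, cfg.width)
        u -= float(st.theta_hat @ phi)
    if cfg.method in ("feedback+smc", "hybrid"):
        sw = sign_law(s) if cfg.raw_sign else st.z
        u -= cfg.rho * sw
    return float(u)


# ---------------------------------------------------------------------------
# closed-loop simulation

def _pulse_array(pulses: Iterable[PulseTrainSpec], t: np.ndarray) -> np.ndarray:
    d = np.zeros((len(t), 4))
    for spec in pulses:
        d += spec.waveform(t)
    return d


def closed_loop_simulate(
    params: ModelParameters,
    initial,
    reference: ReferenceSignal,
    cfg: ControllerConfig,
    noise: NoiseSpec | None = None,
    disturbance: Sequence[PulseTrainSpec] = (),
    duration: float | None = None,
    dt: float = 0.001,
) -> ClosedLoopResult:
    """Run the plant under feedback from a reference trace.

    Discrete-time loop each step: measure y, form s = y - y_d, update the
    filter state and the RBF weights, compute u, then advance the plant one
    RK4 step with u held constant (applied to the configured targets) along
    with the disturbance and noise inputs.  Before ``cfg.switch_on_time`` the
    controller is inert (u = 0, no adaptation).
    """
    duration = float(duration if duration is not None else reference.duration)
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    y_d = reference.sample(t)

    st = np.asarray(initial, dtype=float).copy()
    ctrl = ControllerState.initial(cfg)
    d_wave = _pulse_array(disturbance, t)
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    noise_idx = [population_index(p) for p in noise.target] if noise is not None else []
    ctrl_idx = [population_index(p) for p in cfg.targets]

    states = np.empty((n + 1, 4))
    y = np.empty(n + 1)
    u = np.zeros(n + 1)
    d_rec = np.zeros(n + 1)
    e = np.empty(n + 1)
    s_hist = np.empty(n + 1)
    z_hist = np.zeros(n + 1)
    th_hist = np.zeros((n + 1, cfg.n_nodes))
    states[0] = st
    y[0] = eeg_observation(st, params)

    for i in range(n):
        e[i] = s_hist[i] = sliding_surface(y[i], y_d[i])
        ui = 0.0
        if t[i] >= cfg.switch_on_time:
            ctrl.s_value = s_hist[i]
            ctrl.z = lpf_step(ctrl.z, ctrl.s_value, cfg.tau_filter, dt)
            if cfg.method in ("feedback+rbf", "hybrid"):
                phi = rbf_basis(ctrl.s_value, cfg.centers, cfg.width)
                ctrl.theta_hat = update_nn_weights(
                    ctrl.theta_hat, ctrl.s_value, phi, cfg.gamma, cfg.k_c, dt
                )
            ui = control_output(cfg, ctrl)
        u[i] = ui
        z_hist[i + 1] = ctrl.z
        th_hist[i + 1] = ctrl.theta_hat

        exo = d_wave[i].copy()
        if rng is not None:
            w = noise.mean + noise.sd * rng.standard_normal()
            for j in noise_idx:
                exo[j] += w
        d_rec[i] = exo.sum()
        for j in ctrl_idx:
            exo[j] += ui
        try:
            st = integrate_step(st, params, dt, exo)
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at t = {t[i]:.3f} s") from None
        states[i + 1] = st
        y[i + 1] = eeg_observation(st, params)
    e[n] = s_hist[n] = sliding_surface(y[n], y_d[n])

    traj = Trajectory(t=t, states=states, y=y, u=u, d=d_rec)
    return ClosedLoopResult(
        trajectory=traj, y_d=y_d, e=e, s=s_hist, z=z_hist,
        theta_hat=th_hist, config=cfg,
    )


def variance_trigger_control(
    params: ModelParameters,
    initial,
    reference: ReferenceSignal,
    cfg: ControllerConfig,
    trigger: TriggerConfig,
    disturbance: Sequence[PulseTrainSpec] = (),
    noise: NoiseSpec | None = None,
    duration: float | None = None,
    dt: float = 0.001,
) -> ClosedLoopResult:
    """On-demand feedback control gated by a moving-window variance detector.

    The variance of y over the trailing ``trigger.window`` is evaluated every
    ``trigger.step``; once it exceeds ``var_threshold`` continuously for at
    least ``sustain``, seizure onset is declared, the (feedback-method)
    controller runs for ``action_duration`` and then disarms again.  Events
    are logged as (time, "on"/"off") pairs.
    """
    duration = float(duration if duration is not None else reference.duration)
    if trigger.window >= duration:
        raise ValueError("trigger window must be shorter than the run")
    fb_cfg = replace(cfg, method="feedback", switch_on_time=0.0)
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    y_d = reference.sample(t)

    st = np.asarray(initial, dtype=float).copy()
    d_wave = _pulse_array(disturbance, t)
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    noise_idx = [population_index(p) for p in noise.target] if noise is not None else []
    ctrl_idx = [population_index(p) for p in fb_cfg.targets]

    win = int(round(trigger.window / dt))
    step_n = max(1, int(round(trigger.step / dt)))
    sustain_n = int(round(trigger.sustain / dt))
    action_n = int(round(trigger.action_duration / dt))

    states = np.empty((n + 1, 4))
    y = np.empty(n + 1)
    u = np.zeros(n + 1)
    d_rec = np.zeros(n + 1)
    e = np.empty(n + 1)
    var_series = np.zeros(n + 1)
    active = np.zeros(n + 1, dtype=bool)
    events: list[tuple[float, str]] = []
    states[0] = st
    y[0] = eeg_observation(st, params)

    above_since: int | None = None
    control_until = -1
    last_var = 0.0
    for i in range(n):
        if i >= win and i % step_n == 0:
            last_var = float(np.var(y[i - win:i]))
        var_series[i] = last_var
        if last_var > trigger.var_threshold:
            if above_since is None:
                above_since = i
            if i - above_since >= sustain_n and i > control_until:
                control_until = i + action_n
                events.append((float(t[i]), "on"))
        else:
            above_since = None
        is_active = i <= control_until
        if active[max(i - 1, 0)] and not is_active:
            events.append((float(t[i]), "off"))
        active[i] = is_active

        e[i] = sliding_surface(y[i], y_d[i])
        ui = -fb_cfg.lam * e[i] if is_active else 0.0
        u[i] = ui

        exo = d_wave[i].copy()
        if rng is not None:
            w = noise.mean + noise.sd * rng.standard_normal()
            for j in noise_idx:
                exo[j] += w
        d_rec[i] = exo.sum()
        for j in ctrl_idx:
            exo[j] += ui
        st = integrate_step(st, params, dt, exo)
        states[i + 1] = st
        y[i + 1] = eeg_observation(st, params)
    e[n] = sliding_surface(y[n], y_d[n])
    var_series[n] = last_var

    traj = Trajectory(t=t, states=states, y=y, u=u, d=d_rec)
    return ClosedLoopResult(
        trajectory=traj, y_d=y_d, e=e, s=e.copy(),
        z=np.zeros(n + 1), theta_hat=np.zeros((n + 1, fb_cfg.n_nodes)),
        config=fb_cfg, trigger_events=events, trigger_state=active,
        var_series=var_series,
    )


def lyapunov_diagnostics(result: ClosedLoopResult, cfg: ControllerConfig | None = None):
    """Computable Lyapunov-style diagnostics of a closed-loop run.

    Returns ``(V_hat, V_s)`` where ``V_s = s^2 / 2`` and ``V_hat = s^2 / 2 +
    theta_hat' theta_hat / (2 gamma)`` — the estimable stand-in for the
    analysis functional (the ideal-weight error is unknowable at run time).
    Both are non-negative by construction; ultimate boundedness shows up as
    these series settling under a fixed bound after the adaptation transient.
    """
    cfg = cfg or result.config
    v_s = 0.5 * result.s**2
    v_hat = v_s + 0.5 / cfg.gamma * np.einsum("ij,ij->i", result.theta_hat, result.theta_hat)
    return v_hat, v_s
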