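"""Tracking-performance metrics and the four-method comparison report."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .control import ClosedLoopResult, ControllerConfig, closed_loop_simulate
from .params import ModelParameters
from .reference import ReferenceSignal
from .simulate import NoiseSpec, PulseTrainSpec, poisson_pulse_train

__all__ = [
    "summary_stats",
    "power_spectral_density",
    "PerformanceReport",
    "compare_methods",
    "METHOD_ORDER",
]

#: The four controller variants in their conventional numbering.
METHOD_ORDER = ("feedback", "feedback+rbf", "feedback+smc", "hybrid")


def summary_stats(x, dt: float, window: float = 12.0) -> tuple[float, float, float]:
    """(rms, mean, sd) of a series over its trailing ``window`` seconds."""
    x = np.asarray(x, dtype=float)
    n = int(round(window / dt))
    if n <= 0 or n > len(x):
        raise ValueError("window must be positive and no longer than the series")
    w = x[-n:]
    return float(np.sqrt(np.mean(w**2))), float(w.mean()), float(w.std())


def power_spectral_density(y, dt: float, segment: float = 4.0):
    """Averaged-periodogram (Welch) PSD of the mean-removed series.

    4 s segments with 50 % overlap by default; one-sided density normalised
    so the integral over frequency matches the series variance (to within the
    window's spectral leakage, a few per cent).
    """
    y = np.asarray(y, dtype=float)
    if len(y) * dt < 4.0:
        raise ValueError("need at least 4 s of signal for a PSD")
    nper = min(len(y), int(round(segment / dt)))
    freqs, psd = sps.welch(
        y - y.mean(), fs=1.0 / dt, nperseg=nper, noverlap=nper // 2,
        detrend="constant",
    )
    return freqs, psd


@dataclass
class PerformanceReport:
    """Per-method tracking statistics plus PSD tables, one evaluation window."""

    window: float
    stats: pd.DataFrame                  # index: method; rms/mean/sd of e and u
    psd: dict[str, tuple[np.ndarray, np.ndarray]]   # method -> (f, psd of y)
    psd_before: tuple[np.ndarray, np.ndarray] | None = None
    psd_reference: tuple[np.ndarray, np.ndarray] | None = None
    results: dict[str, ClosedLoopResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.stats.reset_index(names="method")


def compare_methods(
    params: ModelParameters,
    initial,
    reference: ReferenceSignal,
    base_config: ControllerConfig,
    noise: NoiseSpec | None = None,
    disturbance: Sequence[PulseTrainSpec] | None = None,
    disturbance_seed: int | None = None,
    duration: float | None = None,
    dt: float = 0.001,
    window: float = 12.0,
    methods: Sequence[str] = METHOD_ORDER,
) -> PerformanceReport:
    """Run the four controller variants under identical seeds and inputs.

    Pure measurement: simulates each method with the same disturbance
    realisation and noise seed, then tabulates RMS / mean / sd of the
    tracking error and control signal over the trailing ``window`` seconds,
    plus PSDs of the controlled output, the uncontrolled output and the
    reference.
    """
    duration = float(duration if duration is not None else reference.duration)
    if disturbance is None:
        disturbance = poisson_pulse_train(duration, seed=disturbance_seed)
    rows, psds, results = [], {}, {}
    for method in methods:
        cfg = replace(base_config, method=method)
        res = closed_loop_simulate(
            params, initial, reference, cfg,
            noise=noise, disturbance=disturbance, duration=duration, dt=dt,
        )
        rms_e, mean_e, sd_e = summary_stats(res.e, dt, window)
        rms_u, mean_u, sd_u = summary_stats(res.trajectory.u, dt, window)
        rows.append(
            {
                "method": method, "rms_e": rms_e, "mean_e": mean_e, "sd_e": sd_e,
                "rms_u": rms_u, "mean_u": mean_u, "sd_u": sd_u,
            }
        )
        n_psd = max(int(window / dt), int(4.0 / dt))   # PSD needs >= 4 s
        psds[method] = power_spectral_density(res.trajectory.y[-n_psd:], dt)
        results[method] = res

    # uncontrolled run (switch-on beyond the horizon) for the "before" PSD
    off_cfg = replace(base_config, switch_on_time=2 * duration)
    off = closed_loop_simulate(
        params, initial, reference, off_cfg,
        noise=noise, disturbance=disturbance, duration=duration, dt=dt,
    )
    n_psd = max(int(window / dt), int(4.0 / dt))
    psd_before = power_spectral_density(off.trajectory.y[-n_psd:], dt)
    n_ref = max(int(window / reference.dt), int(4.0 / reference.dt))
    psd_ref = power_spectral_density(reference.y_d[-n_ref:], reference.dt)

    stats = pd.DataFrame(rows).set_index("method")
    return PerformanceReport(
        window=window, stats=stats, psd=psds,
        psd_before=psd_before, psd_reference=psd_ref, results=results,
    )
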