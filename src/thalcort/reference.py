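"""Desired (reference) EEG traces for the tracking controller.

Two in-package generators cover the controller's test cases: a
model-generated *background* trace (the normal low-saturated activity of a
healthy cortical column, with physiological background noise on RE) and a
band-limited *alpha surrogate* (filtered Gaussian noise centred near 12 Hz)
standing in for a clinical scalp-EEG alpha channel.  A file loader accepts a
user-supplied single-channel trace (CSV, optionally EDF) and resamples it to
the plant grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .params import ModelParameters
from .simulate import NoiseSpec, simulate

__all__ = [
    "ReferenceSignal",
    "generate_background_reference",
    "generate_alpha_surrogate",
    "load_reference_from_file",
]


@dataclass
class ReferenceSignal:
    """Desired EEG y_d on a uniform grid."""

    t: np.ndarray
    y_d: np.ndarray
    provenance: str   # model_background | alpha_surrogate | file

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y_d):
            raise ValueError("t and y_d must have the same length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Values on an arbitrary grid (linear interpolation, edge-held)."""
        return np.interp(t, self.t, self.y_d)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "y": self.y_d}).to_csv(path, index=False)


def generate_background_reference(
    params: ModelParameters,
    duration: float,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    dt: float = 0.001,
) -> ReferenceSignal:
    """Background (LS) trace of the model itself, with noise on RE.

    Starts at the stable low-saturated equilibrium of the given parameters
    and integrates with Gaussian background noise (default sd 1 on RE).
    Raises if no stable background equilibrium exists at these parameters.
    """
    from .analysis import ClassificationConfig, find_equilibria

    split = ClassificationConfig().ls_hs_split
    eqs = [
        x for x, stable in find_equilibria(params)
        if stable and (params.c1 * x[0] + params.c2 * x[1]) < split
    ]
    if not eqs:
        raise RuntimeError("no stable background (LS) equilibrium at these parameters")
    if noise is None:
        noise = NoiseSpec(sd=1.0, mean=0.0, target=("RE",), seed=seed)
    elif seed is not None:
        noise = NoiseSpec(sd=noise.sd, mean=noise.mean, target=noise.target, seed=seed)
    traj = simulate(params, eqs[0], duration, dt=dt, noise=noise)
    return ReferenceSignal(t=traj.t, y_d=traj.y, provenance="model_background")


def generate_alpha_surrogate(
    duration: float,
    dt: float = 0.001,
    center_freq: float = 12.0,
    bandwidth: float = 3.0,
    amplitude: float = 0.3,
    seed: int | None = None,
    offset: float = 0.0,
) -> ReferenceSignal:
    """Synthetic alpha-band EEG: band-passed Gaussian noise near 12 Hz.

    ``amplitude`` is the target peak-to-peak range in model EEG units (about
    three times the background trace's excursion by default, comparable to
    the scaling of a clinical alpha channel against the model's y range).
    """
    if not 0 < bandwidth < center_freq:
        raise ValueError("bandwidth must be in (0, center_freq)")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    white = rng.standard_normal(n + 4000)   # pad to wash out filter edges
    nyq = 0.5 / dt
    lo = (center_freq - bandwidth / 2) / nyq
    hi = (center_freq + bandwidth / 2) / nyq
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)[2000:2000 + n]
    if amplitude == 0:
        y = np.zeros(n)
    else:
        y = x * (amplitude / np.ptp(x)) + offset
    return ReferenceSignal(t=np.arange(n) * dt, y_d=y, provenance="alpha_surrogate")


def load_reference_from_file(
    path: str | Path,
    channel: str | int | None = None,
    resample_to_dt: float = 0.001,
    rescale_ptp: float | None = None,
) -> ReferenceSignal:
    """Load a single-channel EEG trace from CSV (or EDF) as a reference.

    CSV files need a time column and one value column (``channel`` selects a
    column by name when given).  EDF reading requires :mod:`mne`.  The trace
    is linearly resampled to ``resample_to_dt`` and optionally rescaled to a
    stated peak-to-peak range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as err:
            raise ImportError("EDF input requires the optional dependency mne") from err
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        names = raw.ch_names
        pick = channel if isinstance(channel, str) else names[int(channel or 0)]
        if pick not in names:
            raise ValueError(f"channel {pick!r} not in {names}")
        data = raw.get_data(picks=[pick])[0]
        t = np.arange(len(data)) / raw.info["sfreq"]
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("CSV reference needs a time column and a value column")
        tcol = df.columns[0]
        if channel is None:
            vcol = df.columns[1]
        elif isinstance(channel, int):
            vcol = df.columns[channel]
        else:
            if channel not in df.columns:
                raise ValueError(f"channel {channel!r} not in CSV columns {list(df.columns)}")
            vcol = channel
        t = df[tcol].to_numpy(dtype=float)
        data = df[vcol].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("reference trace too short")
    grid = np.arange(0.0, t[-1] - t[0] + resample_to_dt / 2, resample_to_dt)
    y = np.interp(grid, t - t[0], data)
    if rescale_ptp is not None and np.ptp(y) > 0:
        y = (y - y.mean()) * (rescale_ptp / np.ptp(y)) + y.mean()
    return ReferenceSignal(t=grid, y_d=y, provenance="file")
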