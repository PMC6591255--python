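"""Regime classification, parameter sweeps and bifurcation machinery.

The model's noise-free attractors fall into five classes: low/high saturated
steady states (LS/HS), fast low-amplitude tonic oscillations (TO), slow
spike-and-wave discharges with m spikes per cycle (m-SWD), and slow
large-amplitude clonic oscillations (CO).  Classification works on the
observed EEG after discarding the transient:

* peak-to-peak amplitude below ``steady_amplitude_tol`` -> steady; LS or HS by
  comparing the level with ``ls_hs_split``;
* fundamental frequency (tallest autocorrelation peak) at or above
  ``to_freq_min`` -> TO;
* otherwise the trace is segmented into fundamental cycles and *narrow*
  prominent maxima (width below ``narrow_width_frac`` of the cycle) are
  counted: one or more spikes per cycle -> m-SWD, none -> CO.

The narrow/broad distinction is what separates a spike riding on a wave from
the wave's own broad crest; on this model spikes are 3-25 % of the cycle wide
while wave crests exceed 35 %.

Note the dominant FFT frequency of an SWD can be a harmonic of the cycle rate
(the spike train carries more power than the fundamental), which is why
classification relies on the autocorrelation fundamental instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .model import jacobian, model_rhs
from .params import ModelParameters
from .simulate import Trajectory, simulate_ensemble

__all__ = [
    "StateLabel",
    "ClassificationConfig",
    "BifurcationPoint",
    "RegionMap",
    "EquilibriumBranch",
    "ProbeResult",
    "dominant_frequency",
    "fundamental_frequency",
    "signal_extrema",
    "count_spikes_per_cycle",
    "classify_series",
    "classify_state",
    "one_param_scan",
    "two_param_map",
    "multistability_probe",
    "find_equilibrium",
    "find_equilibria",
    "continue_equilibria",
    "detect_hopf",
    "estimate_double_cycle",
]


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class StateLabel:
    """Discrete dynamical regime of one trajectory."""

    kind: str                       # TO | LS | HS | SWD | CO | UNRESOLVED
    m: int | None = None            # spikes per cycle, SWD only
    dominant_frequency: float = 0.0  # Hz, FFT peak (0 for steady states)

    def __post_init__(self) -> None:
        if self.kind not in ("TO", "LS", "HS", "SWD", "CO", "UNRESOLVED"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        if (self.m is not None) != (self.kind == "SWD"):
            raise ValueError("spike count m is defined exactly for SWD labels")

    def __str__(self) -> str:
        return f"{self.m}-SWD" if self.kind == "SWD" else self.kind


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the regime classifier (calibrated on the reference

    waveforms at c_tr=0.15; see the methods note for the calibration)."""

    steady_amplitude_tol: float = 1e-3   # peak-to-peak below this -> steady
    ls_hs_split: float = 0.35            # y level separating LS from HS
    to_freq_min: float = 10.0            # Hz floor for tonic oscillations
    spike_prominence: float = 0.03       # prominence, fraction of peak-to-peak
    narrow_width_frac: float = 0.30      # spike width ceiling, fraction of cycle
    transient_discard: float = 10.0      # s of initial trace ignored

    def __post_init__(self) -> None:
        for name in ("steady_amplitude_tol", "ls_hs_split", "to_freq_min",
                     "spike_prominence", "narrow_width_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str                 # "HB" | "dc" | "real"
    parameter_name: str
    parameter_value: float
    branch_id: str = ""
    frequency: float | None = None  # Hz of the crossing eigenpair (HB only)


@dataclass
class EquilibriumBranch:
    """Equilibria continued along one parameter axis."""

    axis: str
    parameter_values: np.ndarray     # (k,)
    states: np.ndarray               # (k, 4)
    eigenvalues: np.ndarray          # (k, 4) complex
    stable: np.ndarray               # (k,) bool
    terminated: str = "range"        # why continuation stopped


@dataclass
class ProbeResult:
    """Distinct attractors found by a multistability probe."""

    labels: list[StateLabel]
    representatives: list[np.ndarray]   # one initial state per attractor
    unresolved: int = 0

    @property
    def kinds(self) -> set[str]:
        return {lbl.kind for lbl in self.labels}

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RegionMap:
    """Cell-wise coexisting-state sets over the (c_tr, c_te) plane."""

    c_tr_values: np.ndarray
    c_te_values: np.ndarray
    cell_labels: list[list[tuple[StateLabel, ...]]]   # [i_tr][i_te]

    def kind_sets(self) -> np.ndarray:
        """Object array of frozensets of state kinds (m ignored)."""
        out = np.empty((len(self.c_tr_values), len(self.c_te_values)), dtype=object)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                kinds = frozenset(
                    lbl.kind for lbl in self.cell_labels[i][j] if lbl.kind != "UNRESOLVED"
                )
                out[i, j] = kinds or frozenset({"UNRESOLVED"})
        return out

    def region_ids(self) -> tuple[np.ndarray, int]:
        """Merge cells carrying identical coexistence sets into regions.

        Returns ``(id_grid, n_regions)`` where all cells with the same set of
        coexisting state kinds share one region id — the count of
        *qualitatively different* regions of the coupling plane.  Unlike a
        spatial connected-component count, this is stable under grid
        refinement (a region split into several patches by an interleaving
        band still counts once).
        """
        sets = self.kind_sets()
        uniq = sorted({s for s in sets.ravel()}, key=sorted)
        lookup = {s: k for k, s in enumerate(uniq)}
        ids = np.vectorize(lambda s: lookup[s])(sets)
        return ids, len(uniq)

    def patches(self) -> tuple[np.ndarray, int]:
        """Spatial connected components (4-connectivity) of the region grid."""
        sets = self.kind_sets()
        ids = np.full(sets.shape, -1, dtype=int)
        next_id = 0
        for uniq in sorted({s for s in sets.ravel()}, key=sorted):
            mask = np.vectorize(lambda s: s == uniq)(sets)
            lab, n = ndimage.label(mask)
            for k in range(1, n + 1):
                ids[lab == k] = next_id
                next_id += 1
        return ids, next_id

    @property
    def n_regions(self) -> int:
        return self.region_ids()[1]

    def to_frame(self) -> pd.DataFrame:
        ids, _ = self.region_ids()
        rows = []
        for i, ctr in enumerate(self.c_tr_values):
            for j, cte in enumerate(self.c_te_values):
                labels = self.cell_labels[i][j]
                rows.append(
                    {
                        "c_tr": ctr,
                        "c_te": cte,
                        "labels": "+".join(sorted(str(l) for l in labels)),
                        "dominant_frequency": max(
                            (l.dominant_frequency for l in labels), default=0.0
                        ),
                        "region_id": ids[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectral / waveform measures

def dominant_frequency(
    y,
    dt: float,
    transient_discard: float = 0.0,
    steady_amplitude_tol: float = 1e-3,
) -> float:
    """Frequency (Hz) of the largest FFT peak of the mean-removed trace.

    Returns 0 for (near-)steady traces.  Requires at least 4 s of signal
    after the transient so the resolution is 0.25 Hz or better.
    """
    y = np.asarray(y, dtype=float)
    n0 = int(round(transient_discard / dt))
    w = y[n0:]
    if len(w) * dt < 4.0:
        raise ValueError("need at least 4 s of signal after the transient")
    if np.ptp(w) < steady_amplitude_tol:
        return 0.0
    w = w - w.mean()
    spec = np.abs(np.fft.rfft(w))
    freqs = np.fft.rfftfreq(len(w), dt)
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)])


def fundamental_frequency(y, dt: float) -> float:
    """Cycle repetition rate from the autocorrelation (Hz).

    The fundamental is the lag of the first autocorrelation peak whose height
    is within 10 % of the tallest peak; taking the *tallest* family rather
    than the first peak avoids locking onto the spike interval of an m-SWD.
    Returns 0 when no periodicity is detectable.
    """
    y = np.asarray(y, dtype=float)
    ym = y - y.mean()
    if np.ptp(ym) == 0:
        return 0.0
    n = len(ym)
    ac = np.correlate(ym, ym, mode="full")[n - 1:]
    if ac[0] <= 0:
        return 0.0
    # peak positions from the (smooth) biased estimate, restricted to lags
    # the window supports; heights compared after unbiasing so a long-lag
    # fundamental is not penalised by the shrinking overlap
    half = ac[: n // 2]
    peaks, _ = signal.find_peaks(half)
    if len(peaks) == 0:
        return 0.0
    heights = half[peaks] * n / (n - peaks)
    lag = peaks[np.argmax(heights >= 0.9 * heights.max())]
    return 1.0 / (lag * dt)


def signal_extrema(y, transient_discard: float = 0.0, dt: float = 0.001,
                   steady_amplitude_tol: float = 1e-3) -> np.ndarray:
    """Values of all strict local maxima and minima after the transient.

    A steady trace returns its single level.
    """
    y = np.asarray(y, dtype=float)
    w = y[int(round(transient_discard / dt)):]
    if np.ptp(w) < steady_amplitude_tol:
        return np.array([w.mean()])
    mx, _ = signal.find_peaks(w)
    mn, _ = signal.find_peaks(-w)
    return np.sort(np.concatenate([w[mx], w[mn]]))


def count_spikes_per_cycle(
    y,
    dt: float,
    fundamental: float,
    prominence: float = 0.03,
    narrow_width_frac: float = 0.30,
) -> int:
    """Modal number of narrow prominent maxima per fundamental cycle.

    ``prominence`` is relative to the trace's peak-to-peak amplitude.  Maxima
    wider than ``narrow_width_frac`` of the cycle (the broad wave crest) are
    not counted as spikes.  Requires at least 3 complete cycles.
    """
    if fundamental <= 0:
        raise ValueError("fundamental frequency must be > 0")
    y = np.asarray(y, dtype=float)
    period = int(round(1.0 / (fundamental * dt)))
    n_cycles = len(y) // period
    if n_cycles < 3:
        raise ValueError("need at least 3 complete cycles to count spikes")
    ptp = np.ptp(y)
    peaks, props = signal.find_peaks(y, prominence=prominence * ptp, width=0)
    narrow = peaks[props["widths"] < narrow_width_frac * period]
    counts = np.histogram(narrow, bins=np.arange(0, (n_cycles + 1) * period, period))[0]
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


# ---------------------------------------------------------------------------
# classification

def classify_series(y, dt: float, cfg: ClassificationConfig | None = None) -> StateLabel:
    """Classify a noise-free EEG series into TO/LS/HS/m-SWD/CO.

    A decaying oscillation (second-half amplitude under half the first-half
    amplitude but not yet steady) is reported UNRESOLVED rather than guessed.
    """
    cfg = cfg or ClassificationConfig()
    y = np.asarray(y, dtype=float)
    w = y[int(round(cfg.transient_discard / dt)):]
    if len(w) * dt < 2.0:
        raise ValueError("need at least 2 s of signal after the transient")
    ptp = np.ptp(w)
    if ptp < cfg.steady_amplitude_tol:
        level = float(w.mean())
        return StateLabel(kind="LS" if level < cfg.ls_hs_split else "HS")
    # decaying transients (incl. critically slowed ringing near a Hopf):
    # for a sustained oscillation every quarter-window spans >= 1 cycle, so
    # its peak-to-peak equals the full amplitude; a shrinking envelope is a
    # transient, not an attractor
    q = len(w) // 4
    if np.ptp(w[-q:]) < 0.8 * np.ptp(w[:q]):
        return StateLabel(kind="UNRESOLVED")
    try:
        fd = dominant_frequency(w, dt, steady_amplitude_tol=cfg.steady_amplitude_tol)
    except ValueError:
        fd = fundamental_frequency(w, dt)
    f0 = fundamental_frequency(w, dt)
    if f0 >= cfg.to_freq_min:
        return StateLabel(kind="TO", dominant_frequency=fd)
    if f0 <= 0:
        return StateLabel(kind="UNRESOLVED")
    try:
        m = count_spikes_per_cycle(
            w, dt, f0, prominence=cfg.spike_prominence,
            narrow_width_frac=cfg.narrow_width_frac,
        )
    except ValueError:
        return StateLabel(kind="UNRESOLVED")
    if m >= 1:
        return StateLabel(kind="SWD", m=m, dominant_frequency=fd)
    return StateLabel(kind="CO", dominant_frequency=fd)


def classify_state(traj: Trajectory, cfg: ClassificationConfig | None = None) -> StateLabel:
    """Classify a simulated trajectory (noise-free probe)."""
    return classify_series(traj.y, traj.dt, cfg)


# ---------------------------------------------------------------------------
# equilibria

def find_equilibrium(params: ModelParameters, guess) -> np.ndarray:
    """Root of the vector field near ``guess`` with residual below 1e-10."""
    guess = np.asarray(guess, dtype=float)
    if not np.all(np.isfinite(guess)):
        raise ValueError("guess must be finite")
    sol = optimize.root(
        lambda x: model_rhs(x, params),
        guess,
        jac=lambda x: jacobian(x, params),
        method="hybr",
        tol=1e-13,
    )
    res = np.linalg.norm(model_rhs(sol.x, params))
    if not sol.success or res > 1e-10:
        raise RuntimeError(f"equilibrium search did not converge (residual {res:.2e})")
    return sol.x


def _equilibrium_from_py(py, params: ModelParameters):
    """Closed-form (IN, TC, RE) at equilibrium given PY, and the PY residual.

    At a fixed point the IN line is explicit (IN = h_i + c_ie f[PY]) and the
    TC/RE lines are linear in (TC, RE), so the 4-D root problem reduces to a
    scalar equation in PY.
    """
    from .model import linear_activation, sigmoid_activation

    p = params
    f_py = sigmoid_activation(py, p.epsilon)
    IN = p.h_i + p.c_ie * f_py
    A = p.h_r + p.c_re * f_py + (p.c_rt - p.c_rr) * p.b
    B = p.h_t + p.c_te * f_py - p.c_tr * p.b
    RE = (A + p.c_rt * p.a * B) / (1.0 + p.a * p.c_rr + p.a**2 * p.c_rt * p.c_tr)
    TC = B - p.c_tr * p.a * RE
    resid = (
        p.h_e - py + p.c_ee * f_py
        - p.c_ei * sigmoid_activation(IN, p.epsilon)
        + p.c_et * sigmoid_activation(TC, p.epsilon)
    )
    return IN, TC, RE, resid


def find_equilibria(
    params: ModelParameters,
    py_range: tuple[float, float] = (-6.0, 3.0),
    scan_points: int = 800,
) -> list[tuple[np.ndarray, bool]]:
    """All equilibria, via the exact reduction to a scalar equation in PY.

    The PY residual is scanned over ``py_range``; every sign change is
    bisected, the full state reassembled in closed form and polished by
    Newton root-finding.  Returns ``(state, stable)`` pairs with stability
    from the Jacobian spectrum.  Deterministic and (for this vector field,
    whose equilibria all have PY in the scan range) exhaustive.
    """
    pys = np.linspace(py_range[0], py_range[1], scan_points)
    _, _, _, res = _equilibrium_from_py(pys, params)
    out: list[tuple[np.ndarray, bool]] = []
    sign = np.sign(res)
    idx = np.where(sign[:-1] * sign[1:] <= 0)[0]
    for i in idx:
        if sign[i] == 0 and i > 0:
            continue
        lo, hi = pys[i], pys[i + 1]
        r_lo = res[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            r_mid = _equilibrium_from_py(mid, params)[3]
            if r_lo * r_mid <= 0:
                hi = mid
            else:
                lo, r_lo = mid, r_mid
        py = 0.5 * (lo + hi)
        IN, TC, RE, _ = _equilibrium_from_py(py, params)
        try:
            x = find_equilibrium(params, np.array([py, IN, TC, RE]))
        except RuntimeError:
            continue
        if any(np.allclose(x, x0, atol=1e-7) for x0, _ in out):
            continue
        ev = np.linalg.eigvals(jacobian(x, params))
        out.append((x, bool(np.all(ev.real < 0))))
    return out


def continue_equilibria(
    params: ModelParameters,
    axis: str,
    p_range: tuple[float, float],
    start: np.ndarray | None = None,
    step: float = 0.01,
    max_steps: int = 2000,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium along one parameter.

    Follows the branch through folds; records the Jacobian spectrum and a
    stability flag at every accepted point.  Stops when the parameter exits
    ``p_range`` or the corrector fails repeatedly.
    """
    p0, p1 = float(p_range[0]), float(p_range[1])
    if start is None:
        eqs = find_equilibria(params.replace(**{axis: p0}))
        if not eqs:
            raise RuntimeError("no starting equilibrium found")
        start = eqs[0][0]
    x = find_equilibrium(params.replace(**{axis: p0}), start)

    def F(v):
        return model_rhs(v[:4], params.replace(**{axis: v[4]}))

    def Fx(v):
        return jacobian(v[:4], params.replace(**{axis: v[4]}))

    def Fp(v, h=1e-7):
        up = model_rhs(v[:4], params.replace(**{axis: v[4] + h}))
        try:
            dn = model_rhs(v[:4], params.replace(**{axis: v[4] - h}))
        except ValueError:   # parameter bound (e.g. connectivity >= 0)
            return (up - model_rhs(v[:4], params.replace(**{axis: v[4]}))) / h
        return (up - dn) / (2 * h)

    vs = [np.append(x, p0)]
    # initial tangent: toward increasing parameter
    tang = np.zeros(5)
    tang[4] = 1.0
    dx = np.linalg.solve(Fx(vs[0]), -Fp(vs[0]))
    tang[:4] = dx
    tang /= np.linalg.norm(tang)
    if tang[4] < 0:
        tang = -tang

    pts, fails = [vs[0]], 0
    h = step
    while len(pts) < max_steps:
        v = pts[-1]
        pred = v + h * tang

        def G(w):
            return np.append(F(w), tang @ (w - pred))

        sol = optimize.root(G, pred, method="hybr", tol=1e-12)
        if not sol.success or np.linalg.norm(F(sol.x)) > 1e-9:
            fails += 1
            h *= 0.5
            if fails > 8:
                term = "corrector_failure"
                break
            continue
        fails = 0
        h = min(h * 1.4, step)
        new = sol.x
        new_tang = new - v
        new_tang /= np.linalg.norm(new_tang)
        tang = new_tang
        pts.append(new)
        if not (min(p0, p1) - 1e-9 <= new[4] <= max(p0, p1) + 1e-9):
            term = "range"
            break
    else:
        term = "max_steps"

    arr = np.array(pts)
    eigs = np.array([
        np.linalg.eigvals(jacobian(v[:4], params.replace(**{axis: v[4]}))) for v in pts
    ])
    return EquilibriumBranch(
        axis=axis,
        parameter_values=arr[:, 4],
        states=arr[:, :4],
        eigenvalues=eigs,
        stable=np.all(eigs.real < 0, axis=1),
        terminated=term,
    )


def _leading_complex_real(eigs: np.ndarray, im_tol: float = 1e-6) -> float:
    """Max real part over complex-conjugate eigenpairs; -inf if none."""
    cplx = eigs[np.abs(eigs.imag) > im_tol]
    return float(cplx.real.max()) if len(cplx) else -np.inf


def detect_hopf(
    branch: EquilibriumBranch,
    params: ModelParameters | None = None,
    eig_solver: Callable[[float, np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
    tol: float = 1e-4,
) -> list[BifurcationPoint]:
    """Locate eigenvalue crossings of the imaginary axis along a branch.

    A sign change of the leading complex-pair real part is refined by
    bisection to ``tol`` in the parameter and reported as a Hopf point (kind
    ``HB``) carrying the crossing frequency |Im lambda| / 2 pi.  Crossings of
    a *real* eigenvalue are reported separately with kind ``real``.

    ``eig_solver(p, x_guess) -> (x, eigenvalues)`` re-solves the equilibrium
    at intermediate parameter values; by default it is built from ``params``.
    """
    if len(branch.parameter_values) < 3:
        raise ValueError("branch must contain at least 3 points")
    if eig_solver is None:
        if params is None:
            raise ValueError("provide either params or eig_solver")

        def eig_solver(p, x_guess):
            pp = params.replace(**{branch.axis: p})
            x = find_equilibrium(pp, x_guess)
            return x, np.linalg.eigvals(jacobian(x, pp))

    out: list[BifurcationPoint] = []
    pv, st = branch.parameter_values, branch.states
    for i in range(len(pv) - 1):
        e0, e1 = branch.eigenvalues[i], branch.eigenvalues[i + 1]
        for kind in ("HB", "real"):
            if kind == "HB":
                mu0, mu1 = _leading_complex_real(e0), _leading_complex_real(e1)
            else:
                r0 = e0[np.abs(e0.imag) <= 1e-6].real
                r1 = e1[np.abs(e1.imag) <= 1e-6].real
                mu0 = float(r0.max()) if len(r0) else -np.inf
                mu1 = float(r1.max()) if len(r1) else -np.inf
            if not (np.isfinite(mu0) and np.isfinite(mu1)) or mu0 * mu1 >= 0:
                continue
            lo, hi = pv[i], pv[i + 1]
            x_lo = st[i].copy()
            mu_lo = mu0
            freq = None
            while abs(hi - lo) > tol:
                mid = 0.5 * (lo + hi)
                x_mid, e_mid = eig_solver(mid, x_lo)
                if kind == "HB":
                    mu_mid = _leading_complex_real(e_mid)
                    cplx = e_mid[np.abs(e_mid.imag) > 1e-6]
                    if len(cplx):
                        freq = float(np.abs(cplx[np.argmax(cplx.real)].imag) / (2 * np.pi))
                else:
                    rr = e_mid[np.abs(e_mid.imag) <= 1e-6].real
                    mu_mid = float(rr.max()) if len(rr) else mu_lo
                if mu_lo * mu_mid <= 0:
                    hi = mid
                else:
                    lo, x_lo, mu_lo = mid, x_mid, mu_mid
            out.append(
                BifurcationPoint(
                    kind=kind,
                    parameter_name=branch.axis,
                    parameter_value=0.5 * (lo + hi),
                    frequency=freq if kind == "HB" else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# attractor probing

_PROBE_BOX = (-4.0, 1.0)


def _attractor_key(label: StateLabel, y_window: np.ndarray, dt: float):
    """Coarse identity of an attractor for de-duplication."""
    if label.kind in ("LS", "HS"):
        return (label.kind, round(float(np.mean(y_window)), 2))
    f0 = fundamental_frequency(y_window, dt)
    ptp = np.ptp(y_window)
    return (label.kind, label.m, round(f0), round(ptp * 5) / 5)


def _classify_ensemble(ys: np.ndarray, dt: float, cfg: ClassificationConfig):
    """Classify each row of an ensemble's trailing y-window (transient
    already discarded by the caller)."""
    window_cfg = ClassificationConfig(
        steady_amplitude_tol=cfg.steady_amplitude_tol,
        ls_hs_split=cfg.ls_hs_split,
        to_freq_min=cfg.to_freq_min,
        spike_prominence=cfg.spike_prominence,
        narrow_width_frac=cfg.narrow_width_frac,
        transient_discard=1e-12,
    )
    return [classify_series(row, dt, window_cfg) for row in ys]


def multistability_probe(
    params: ModelParameters,
    n_initials: int = 50,
    seed: int = 0,
    duration: float = 22.0,
    window: float = 8.0,
    dt: float = 0.001,
    cfg: ClassificationConfig | None = None,
    box: tuple[float, float] = _PROBE_BOX,
    kick: bool = True,
) -> ProbeResult:
    """Census of coexisting attractors at one parameter point.

    Probes three sources of initial states: (1) ``n_initials`` seeded random
    states in ``box``; (2) every stable equilibrium (basins of the background
    state can be far smaller than the box, so random probing alone misses
    them); (3) when ``kick`` is set, single 20 ms pulses on RE (amplitudes
    +-5, +-10, +-15) applied at 12 phases of each oscillatory attractor found
    so far, emulating the pulse-stimulation protocol that switches between
    coexisting states.  Attractors are de-duplicated by label and, for steady
    states, by level.  Monotone discovery: the random probes for smaller
    ``n_initials`` are a prefix of those for larger ones under the same seed.
    """
    cfg = cfg or ClassificationConfig()
    if n_initials < 1:
        raise ValueError("n_initials must be >= 1")
    rng = np.random.default_rng(seed)
    inits = rng.uniform(box[0], box[1], size=(n_initials, 4))
    eq_inits = [x for x, stable in find_equilibria(params) if stable]
    all_inits = np.vstack([inits] + [x[None] for x in eq_inits]) if eq_inits else inits

    attractors: dict = {}
    unresolved = 0

    def absorb(initials: np.ndarray):
        nonlocal unresolved
        finals, ys = simulate_ensemble(
            params, initials, duration, dt=dt, record_last=window
        )
        labels = _classify_ensemble(ys, dt, cfg)
        for init, final, lbl, yw in zip(initials, finals, labels, ys):
            if lbl.kind == "UNRESOLVED":
                unresolved += 1
                continue
            key = _attractor_key(lbl, yw, dt)
            if key not in attractors:
                attractors[key] = (lbl, init.copy(), final.copy())
        return finals

    absorb(all_inits)

    if kick:
        osc_finals = [
            rec[2] for key, rec in attractors.items() if key[0] not in ("LS", "HS")
        ]
        kicked = []
        for final in osc_finals:
            # walk the cycle: take states every ~80 ms (12 phases ~ one slow cycle)
            st = final[None].copy()
            for _ in range(12):
                st, _ = simulate_ensemble(params, st, 0.08, dt=dt, record_last=0.002)
                for amp in (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0):
                    exo = np.zeros(4)
                    exo[3] = amp
                    bumped, _ = simulate_ensemble(
                        params, st, 0.02, dt=dt, record_last=0.002, exogenous=exo
                    )
                    kicked.append(bumped[0])
        if kicked:
            absorb(np.array(kicked))

    labels = [rec[0] for rec in attractors.values()]
    reps = [rec[1] for rec in attractors.values()]
    return ProbeResult(labels=labels, representatives=reps, unresolved=unresolved)


@dataclass
class ScanPoint:
    value: float
    labels: list[StateLabel]
    extrema: list[np.ndarray]            # per label
    dominant_frequencies: list[float]    # per label


def one_param_scan(
    params: ModelParameters,
    axis: str,
    values: Sequence[float],
    probe_initials: Sequence[np.ndarray] | None = None,
    duration: float = 22.0,
    window: float = 8.0,
    dt: float = 0.001,
    cfg: ClassificationConfig | None = None,
    equilibrium_seeds: bool = True,
) -> list[ScanPoint]:
    """Attractor census along one parameter axis.

    For every value the model is integrated from each probe initial (plus, by
    default, every stable equilibrium at that value), the outcomes are
    classified and de-duplicated, and the extrema and dominant frequency of
    each distinct attractor are recorded — the numerical analogue of an
    extrema-versus-parameter bifurcation diagram.
    """
    cfg = cfg or ClassificationConfig()
    values = list(values)
    if not values:
        return []
    if probe_initials is None:
        rng = np.random.default_rng(0)
        probe_initials = list(rng.uniform(*_PROBE_BOX, size=(5, 4)))
    probe_initials = [np.asarray(p, dtype=float) for p in probe_initials]

    # assemble one big ensemble: every (value, initial) pair
    blocks, owners = [], []
    for vi, val in enumerate(values):
        p_here = params.replace(**{axis: val})
        seeds = list(probe_initials)
        if equilibrium_seeds:
            seeds += [x for x, stable in find_equilibria(p_here) if stable]
        for s in seeds:
            blocks.append(s)
            owners.append(vi)
    initials = np.array(blocks)
    overrides = {axis: np.array([values[o] for o in owners])}
    _, ys = simulate_ensemble(
        params, initials, duration, dt=dt, record_last=window, overrides=overrides
    )
    labels = _classify_ensemble(ys, dt, cfg)

    out = []
    for vi, val in enumerate(values):
        rows = [k for k, o in enumerate(owners) if o == vi]
        seen: dict = {}
        for k in rows:
            lbl = labels[k]
            if lbl.kind == "UNRESOLVED":
                continue
            key = _attractor_key(lbl, ys[k], dt)
            if key not in seen:
                seen[key] = (
                    lbl,
                    signal_extrema(ys[k], steady_amplitude_tol=cfg.steady_amplitude_tol),
                    lbl.dominant_frequency,
                )
        out.append(
            ScanPoint(
                value=float(val),
                labels=[v[0] for v in seen.values()],
                extrema=[v[1] for v in seen.values()],
                dominant_frequencies=[v[2] for v in seen.values()],
            )
        )
    return out


def two_param_map(
    params: ModelParameters,
    c_tr_values: Sequence[float],
    c_te_values: Sequence[float],
    n_initials: int = 5,
    seed: int = 0,
    duration: float = 30.0,
    window: float = 8.0,
    dt: float = 0.001,
    cfg: ClassificationConfig | None = None,
) -> RegionMap:
    """Coexistence map over the cortico-thalamic coupling plane.

    Every cell is probed from ``n_initials`` seeded random states plus the
    cell's stable equilibria (from the exhaustive scalar-reduction scan).
    Cells are labelled with the set of state kinds found; identical adjacent
    sets merge into regions.
    """
    cfg = cfg or ClassificationConfig()
    c_tr_values = np.asarray(list(c_tr_values), dtype=float)
    c_te_values = np.asarray(list(c_te_values), dtype=float)
    if len(c_tr_values) < 1 or len(c_te_values) < 1:
        raise ValueError("parameter grids must be non-empty")
    rng = np.random.default_rng(seed)

    blocks, owners = [], []
    for i, ctr in enumerate(c_tr_values):
        for j, cte in enumerate(c_te_values):
            p_here = params.replace(c_tr=float(ctr), c_te=float(cte))
            stable_eqs = [x for x, stable in find_equilibria(p_here) if stable]
            cell_inits = list(rng.uniform(*_PROBE_BOX, size=(n_initials, 4)))
            cell_inits += stable_eqs
            for s in cell_inits:
                blocks.append(s)
                owners.append((i, j))

    initials = np.array(blocks)
    overrides = {
        "c_tr": np.array([c_tr_values[i] for i, _ in owners]),
        "c_te": np.array([c_te_values[j] for _, j in owners]),
    }
    _, ys = simulate_ensemble(
        params, initials, duration, dt=dt, record_last=window, overrides=overrides
    )
    labels = _classify_ensemble(ys, dt, cfg)

    cell_labels: list[list[tuple[StateLabel, ...]]] = [
        [() for _ in c_te_values] for _ in c_tr_values
    ]
    cell_seen: dict[tuple[int, int], dict] = {}
    for k, (i, j) in enumerate(owners):
        lbl = labels[k]
        d = cell_seen.setdefault((i, j), {})
        key = _attractor_key(lbl, ys[k], dt) if lbl.kind != "UNRESOLVED" else ("U",)
        if key not in d:
            d[key] = lbl
    for (i, j), d in cell_seen.items():
        found = tuple(l for l in d.values())
        cell_labels[i][j] = found
    return RegionMap(
        c_tr_values=c_tr_values, c_te_values=c_te_values, cell_labels=cell_labels
    )


# ---------------------------------------------------------------------------
# fold-of-cycles (double cycle) estimation

def estimate_double_cycle(
    params: ModelParameters,
    axis: str,
    p_range: tuple[float, float],
    n_steps: int = 40,
    settle: float = 8.0,
    window: float = 4.0,
    dt: float = 0.001,
    amp_threshold: float = 0.05,
    refine_tol: float = 1e-4,
    start_state: np.ndarray | None = None,
) -> list[BifurcationPoint]:
    """Edges where a stable limit cycle abruptly disappears (fold of cycles).

    Ramps the parameter slowly up and then down across ``p_range``, reusing
    the final state at each step (attractor following), and records the
    cycle's peak-to-peak amplitude.  An abrupt drop exceeding
    ``amp_threshold`` marks a cycle-disappearance edge; each edge is refined
    by bisection from the last cycling state and reported as a ``dc`` point
    (branch_id ``up`` or ``down``).  A cycle shrinking smoothly to zero (a
    supercritical Hopf) produces no dc point.  Unstable cycles are not
    tracked; only the hysteresis edges they produce are visible.
    """
    p_lo, p_hi = float(p_range[0]), float(p_range[1])
    values_up = np.linspace(p_lo, p_hi, n_steps)
    if start_state is None:
        start_state = np.zeros(4)

    def settle_amp(state, value, t_settle=settle):
        final, ys = simulate_ensemble(
            params, np.asarray(state, dtype=float)[None],
            t_settle + window, dt=dt, record_last=window,
            overrides={axis: np.array([value])},
        )
        return final[0], float(np.ptp(ys[0]))

    out: list[BifurcationPoint] = []
    for direction, values in (("up", values_up), ("down", values_up[::-1])):
        state = np.asarray(start_state, dtype=float)
        amps, states = [], []
        for v in values:
            state, a = settle_amp(state, v)
            amps.append(a)
            states.append(state.copy())
        amps = np.array(amps)
        cycling = amps > 1e-3
        for k in range(len(values) - 1):
            if cycling[k] and not cycling[k + 1] and amps[k] > amp_threshold:
                lo_v, hi_v = values[k], values[k + 1]
                lo_state = states[k]
                while abs(hi_v - lo_v) > refine_tol:
                    mid = 0.5 * (lo_v + hi_v)
                    st_mid, a_mid = settle_amp(lo_state, mid)
                    if a_mid > amp_threshold:
                        lo_v, lo_state = mid, st_mid
                    else:
                        hi_v = mid
                out.append(
                    BifurcationPoint(
                        kind="dc",
                        parameter_name=axis,
                        parameter_value=0.5 * (lo_v + hi_v),
                        branch_id=direction,
                    )
                )
    return out
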