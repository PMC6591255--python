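"""Vector field, activation functions, Jacobian and EEG observation map.

All functions broadcast over leading axes: a *state* is an array of shape
``(..., 4)`` holding (PY, IN, TC, RE), so ensembles of states integrate in one
vectorized call.  Connectivity parameters may likewise be scalars or arrays
broadcastable against ``state[..., 0]`` (used by the parameter-plane sweeps).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import ModelParameters

__all__ = [
    "sigmoid_activation",
    "linear_activation",
    "model_rhs",
    "eeg_observation",
    "jacobian",
]

# exponent clip: beyond this expit is exactly 0/1 in double precision anyway
_EXP_CLIP = 700.0


def sigmoid_activation(x, epsilon: float = 2.0e5):
    """Sigmoid transition function f[x] = 1 / (1 + epsilon^-x).

    Computed as ``expit(x * ln(epsilon))`` so that large ``|x|`` saturates to
    0/1 instead of overflowing.  Output is strictly inside (0, 1) for finite
    arguments and strictly increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid_activation requires finite input")
    if not np.all(np.asarray(epsilon) > 1):
        raise ValueError("epsilon must be > 1")
    z = np.clip(x * np.log(epsilon), -_EXP_CLIP, _EXP_CLIP)
    return expit(z)


def linear_activation(x, a: float = 2.8, b: float = 0.5):
    """Linear thalamic activation s[x] = a*x + b."""
    return a * np.asarray(x, dtype=float) + b


def model_rhs(state, params: ModelParameters, exogenous=None):
    """Time derivative of (PY, IN, TC, RE).

    ``exogenous`` is an optional additive per-population input of shape
    broadcastable to ``state``; it adds directly to the state derivative
    (``dx/dt = F(x) + exogenous``), so a control or disturbance channel has
    unit gain into its population.  This single convention carries
    stimulation pulses, background noise and control signals alike.
    """
    st = np.asarray(state, dtype=float)
    if st.shape[-1] != 4:
        raise ValueError("state must have shape (..., 4)")
    if not np.all(np.isfinite(st)):
        raise ValueError("model_rhs requires finite state")
    p = params
    PY, IN, TC, RE = st[..., 0], st[..., 1], st[..., 2], st[..., 3]
    f_py = sigmoid_activation(PY, p.epsilon)
    f_in = sigmoid_activation(IN, p.epsilon)
    f_tc = sigmoid_activation(TC, p.epsilon)
    s_tc = linear_activation(TC, p.a, p.b)
    s_re = linear_activation(RE, p.a, p.b)

    b_py = p.h_e - PY + p.c_ee * f_py - p.c_ei * f_in + p.c_et * f_tc
    b_in = p.h_i - IN + p.c_ie * f_py
    b_tc = p.h_t - TC + p.c_te * f_py - p.c_tr * s_re
    b_re = p.h_r - RE + p.c_re * f_py + p.c_rt * s_tc - p.c_rr * s_re

    out = np.empty(np.broadcast_shapes(st.shape, np.shape(b_py) + (4,)), dtype=float)
    out[..., 0] = p.tau_e * b_py
    out[..., 1] = p.tau_i * b_in
    out[..., 2] = p.tau_t * b_tc
    out[..., 3] = p.tau_r * b_re
    if exogenous is not None:
        out = out + np.asarray(exogenous, dtype=float)
    return out


def eeg_observation(state, params: ModelParameters):
    """Simulated EEG y = c1*PY + c2*IN."""
    st = np.asarray(state, dtype=float)
    return params.c1 * st[..., 0] + params.c2 * st[..., 1]


def _sigmoid_derivative(x, epsilon: float):
    f = sigmoid_activation(x, epsilon)
    return np.log(epsilon) * f * (1.0 - f)


def jacobian(state, params: ModelParameters):
    """Analytic Jacobian of :func:`model_rhs` at one state, shape (..., 4, 4).

    Uses f'[x] = ln(eps) f[x](1-f[x]) and s'[x] = a.
    """
    st = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(st)):
        raise ValueError("jacobian requires finite state")
    p = params
    PY, IN, TC = st[..., 0], st[..., 1], st[..., 2]
    df_py = _sigmoid_derivative(PY, p.epsilon)
    df_in = _sigmoid_derivative(IN, p.epsilon)
    df_tc = _sigmoid_derivative(TC, p.epsilon)

    J = np.zeros(st.shape[:-1] + (4, 4), dtype=float)
    J[..., 0, 0] = p.tau_e * (-1.0 + p.c_ee * df_py)
    J[..., 0, 1] = p.tau_e * (-p.c_ei * df_in)
    J[..., 0, 2] = p.tau_e * (p.c_et * df_tc)
    J[..., 1, 0] = p.tau_i * (p.c_ie * df_py)
    J[..., 1, 1] = -p.tau_i * np.ones_like(IN)
    J[..., 2, 0] = p.tau_t * (p.c_te * df_py)
    J[..., 2, 2] = -p.tau_t * np.ones_like(TC)
    J[..., 2, 3] = p.tau_t * (-p.c_tr * p.a)
    J[..., 3, 0] = p.tau_r * (p.c_re * df_py)
    J[..., 3, 2] = p.tau_r * (p.c_rt * p.a)
    J[..., 3, 3] = p.tau_r * (-1.0 - p.c_rr * p.a)
    return J
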