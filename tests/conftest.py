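import numpy as np
import pytest

import thalcort as tc


@pytest.fixture(scope="session")
def params() -> tc.ModelParameters:
    return tc.ModelParameters()


@pytest.fixture(scope="session")
def ls_equilibrium(params) -> np.ndarray:
    """Stable background (LS) equilibrium at the default coupling point."""
    eqs = [x for x, stable in tc.find_equilibria(params) if stable]
    assert len(eqs) == 1
    return eqs[0]


@pytest.fixture(scope="session")
def swd_trajectory(params) -> tc.Trajectory:
    """Noise-free spike-and-wave trajectory at the default coupling point.

    The all-zero initial state lies in the SWD basin at (c_tr, c_te) =
    (0.6, 3); 22 s leaves a clean post-transient window.
    """
    return tc.simulate(params, np.zeros(4), 22.0)


@pytest.fixture(scope="session")
def swd_window(swd_trajectory) -> np.ndarray:
    """Converged SWD waveform (final 8 s)."""
    return swd_trajectory.y[-8000:]
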