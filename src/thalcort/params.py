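"""Model parameters for the four-population thalamocortical neural-mass model.

The model couples an excitatory cortical pyramidal population (PY), a cortical
inhibitory interneuron population (IN), thalamocortical relay cells (TC) and
the thalamic reticular nucleus (RE).  Each population relaxes toward a constant
input offset ``h_*`` at rate ``tau_*`` (1/s) and receives synaptic input from
the others weighted by non-negative connectivity strengths ``c_xy`` (the
activity of population *y* as seen by population *x*).  Cortical activities
enter through a steep sigmoid ``f[x] = 1/(1 + eps^-x)``; thalamic activities
enter through a linear activation ``s[x] = a*x + b``.

The simulated EEG is the convex combination ``y = c1*PY + c2*IN`` of the two
cortical populations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = ["ModelParameters", "POPULATIONS", "population_index"]

#: Order of the state variables in every state array.
POPULATIONS = ("PY", "IN", "TC", "RE")

_RATE_FIELDS = ("tau_e", "tau_i", "tau_t", "tau_r")
_CONNECTIVITY_FIELDS = (
    "c_ee", "c_ei", "c_et", "c_ie", "c_te", "c_tr", "c_re", "c_rt", "c_rr",
)


def population_index(name: str) -> int:
    """Index of a population name ('PY', 'IN', 'TC', 'RE') in state arrays."""
    try:
        return POPULATIONS.index(name)
    except ValueError:
        raise ValueError(
            f"unknown population {name!r}; expected one of {POPULATIONS}"
        ) from None


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the thalamocortical model.

    Defaults are the reference values of the absence-epilepsy configuration;
    ``c_te`` (PY→TC excitation) and ``c_tr`` (RE→TC inhibition) are the two
    coupling strengths usually varied to map the seizure dynamics.
    """

    # population input offsets (dimensionless)
    h_e: float = -0.35
    h_i: float = -3.4
    h_t: float = -2.0
    h_r: float = -5.0
    # timescale rate constants (1/s)
    tau_e: float = 26.0
    tau_i: float = 32.5
    tau_t: float = 2.6
    tau_r: float = 2.6
    # connectivity strengths (dimensionless, >= 0)
    c_ee: float = 1.8
    c_ei: float = 1.5
    c_et: float = 1.0
    c_ie: float = 4.0
    c_te: float = 3.0
    c_tr: float = 0.6
    c_re: float = 3.0
    c_rt: float = 10.5
    c_rr: float = 0.2
    # activation functions
    epsilon: float = 2.0e5
    a: float = 2.8
    b: float = 0.5
    # EEG observation weights, y = c1*PY + c2*IN
    c1: float = 0.5
    c2: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _RATE_FIELDS:
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in _CONNECTIVITY_FIELDS:
            if not np.all(np.asarray(getattr(self, name)) >= 0):
                raise ValueError(f"{name} must be >= 0")
        if not np.all(np.asarray(self.epsilon) > 1):
            raise ValueError("epsilon must be > 1")
        if not np.all(np.isclose(np.asarray(self.c1) + np.asarray(self.c2), 1.0)):
            raise ValueError("observation weights must satisfy c1 + c2 = 1")
        if not (np.all(np.asarray(self.c2) > 0) and np.all(np.asarray(self.c1) >= np.asarray(self.c2))):
            raise ValueError("observation weights must satisfy c1 >= c2 > 0")

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))
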