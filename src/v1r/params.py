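"""Model parameters for the embryonic V1R conductance-based model.

The model is a single-compartment Hodgkin–Huxley-type description of an
embryonic Renshaw cell (V1R interneuron) containing a leak current, the
transient and persistent sodium currents (INat, INap), the delayed-rectifier
potassium current (IKdr) and, optionally, the A-type potassium current (IA)
and slow inactivation of INap.  Units are fixed to {mV, ms, nS, pF, pA} so
that pF·mV/ms = pA holds identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "GateSpec",
    "ModelParameters",
    "table1_basic",
    "table1_slow_inactivation",
    "table1_e14_5",
    "load_parameters",
    "PRESETS",
]

#: coefficients (a, b, c, d) of the voltage-dependent INat inactivation time
#: constant tau_h(V) = a - b*tanh((V + c)/d), in {ms, ms, mV, mV}
TAU_H_COEFS = (16.5, 13.5, 20.0, 15.0)

TAU_INSTANT = 0.0  # sentinel: gate follows its steady state instantaneously
TAU_H_RULE = -1.0  # sentinel: use the voltage-dependent tau_h rule


@dataclass(frozen=True)
class GateSpec:
    """Sigmoid (in)activation gate x with first-order kinetics.

    Steady state x_inf(V) = 1/(1 + exp(-(V - v_half)/k)); k > 0 denotes an
    activation gate (x_inf increasing with V), k < 0 an inactivation gate.
    ``tau`` is the voltage-independent time constant in ms, or one of the
    sentinels ``TAU_INSTANT`` / ``TAU_H_RULE``.  ``exponent`` is the power the
    gate enters the current term with.
    """

    v_half: float
    k: float
    tau: float
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("gate steepness k must be nonzero")
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")

    def steady_state(self, v: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Steady-state open fraction x_inf(V); in (0, 1) for finite V."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.v_half) / self.k))


def _default_gates(tau_s: float) -> dict:
    return {
        "m": GateSpec(-26.0, 9.5, 1.5, 3),     # INat activation
        "h": GateSpec(-45.0, -5.0, TAU_H_RULE),  # INat inactivation, tau_h(V)
        "mp": GateSpec(-36.0, 9.5, 1.5, 3),    # INap activation
        "s": GateSpec(-30.0, -5.0, tau_s),     # INap slow inactivation
        "n": GateSpec(-20.0, 15.0, 10.0, 3),   # IKdr activation
        "mA": GateSpec(-30.0, 12.0, TAU_INSTANT),  # IA activation, instantaneous
        "hA": GateSpec(-70.0, -7.0, 23.0),     # IA inactivation
    }


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the V1R model (units: mV, ms, nS, pF, pA)."""

    cin: float = 13.0         # input capacitance, pF
    gin: float = 1.0          # input (leak) conductance, nS
    vr: float = -60.0         # baseline potential, mV
    i: float = 20.0           # injected current, pA
    ena: float = 60.0         # sodium Nernst potential, mV
    ek: float = -96.0         # potassium Nernst potential, mV
    gnat: float = 20.0        # maximal INat conductance, nS
    gnap: float = 1.2         # maximal INap conductance, nS
    gkdr: float = 10.0        # maximal IKdr conductance, nS
    ga: float = 0.0           # maximal IA conductance, nS
    tau_s: float = 2000.0     # INap slow-inactivation time constant, ms
    include_ia: bool = False
    include_slow_inactivation: bool = False
    gates: dict = field(default=None)  # name -> GateSpec
    tau_h_coefs: tuple = TAU_H_COEFS

    def __post_init__(self) -> None:
        if self.gates is None:
            object.__setattr__(self, "gates", _default_gates(self.tau_s))
        for name in ("gnat", "gnap", "gkdr", "ga", "gin"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.cin <= 0 or self.gin <= 0:
            raise ValueError("Cin and Gin must be positive")
        if not (self.ek < self.vr < self.ena):
            raise ValueError("require EK < Vr < ENa")

    # -- convenience -------------------------------------------------------
    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        if "tau_s" in kwargs and "gates" not in kwargs:
            gates = dict(self.gates)
            gates["s"] = replace(gates["s"], tau=kwargs["tau_s"])
            kwargs["gates"] = gates
        return replace(self, **kwargs)

    @property
    def membrane_time_constant(self) -> float:
        """Passive time constant Cin/Gin in ms (13 ms for the default cell)."""
        return self.cin / self.gin

    def tau_h(self, v: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Voltage-dependent INat inactivation time constant, ms.

        Decreases monotonically from 30 ms (hyperpolarized) to 3 ms
        (depolarized).
        """
        a, b, c, d = self.tau_h_coefs
        return a - b * np.tanh((np.asarray(v, dtype=float) + c) / d)

    # -- packing for the numeric kernels ----------------------------------
    def pack(self) -> np.ndarray:
        """Flatten into the float64 layout consumed by the numba kernels."""
        g = self.gates
        return np.array(
            [
                self.cin, self.gin, self.vr, self.ena, self.ek,
                self.gnat, self.gnap, self.gkdr,
                self.ga if self.include_ia else 0.0,
                self.i,
                g["m"].v_half, g["m"].k, g["m"].tau,
                g["h"].v_half, g["h"].k,
                *self.tau_h_coefs,
                g["mp"].v_half, g["mp"].k, g["mp"].tau,
                g["s"].v_half, g["s"].k, g["s"].tau,
                g["n"].v_half, g["n"].k, g["n"].tau,
                g["mA"].v_half, g["mA"].k,
                g["hA"].v_half, g["hA"].k, g["hA"].tau,
                1.0 if self.include_ia else 0.0,
                1.0 if self.include_slow_inactivation else 0.0,
            ],
            dtype=np.float64,
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cin": self.cin, "gin": self.gin, "vr": self.vr, "i": self.i,
            "ena": self.ena, "ek": self.ek, "gnat": self.gnat,
            "gnap": self.gnap, "gkdr": self.gkdr, "ga": self.ga,
            "tau_s": self.tau_s, "include_ia": self.include_ia,
            "include_slow_inactivation": self.include_slow_inactivation,
            "tau_h_coefs": list(self.tau_h_coefs),
            "gates": {
                name: {"v_half": g.v_half, "k": g.k, "tau": g.tau,
                       "exponent": g.exponent}
                for name, g in self.gates.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        gates = d.pop("gates", None)
        if gates is not None:
            d["gates"] = {name: GateSpec(**spec) for name, spec in gates.items()}
        tau_h = d.pop("tau_h_coefs", None)
        if tau_h is not None:
            d["tau_h_coefs"] = tuple(tau_h)
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


# -- presets ---------------------------------------------------------------

def table1_basic(**overrides) -> ModelParameters:
    """Basic E12.5 model: no IA, no slow inactivation (Cin = 13 pF)."""
    return ModelParameters().with_(**overrides) if overrides else ModelParameters()


def table1_slow_inactivation(**overrides) -> ModelParameters:
    """Model with slow inactivation of INap (tau_s = 2 s); IA never included."""
    p = ModelParameters(include_slow_inactivation=True, i=10.0, gnap=2.5, gkdr=5.0)
    return p.with_(**overrides) if overrides else p


def table1_e14_5(**overrides) -> ModelParameters:
    """E14.5 variant of the basic model: larger capacitance (18 pF)."""
    p = ModelParameters(cin=18.0)
    return p.with_(**overrides) if overrides else p


PRESETS = {
    "table1_basic": table1_basic,
    "table1_slow_inactivation": table1_slow_inactivation,
    "table1_E14_5": table1_e14_5,
    "table1_e14_5": table1_e14_5,
}


def load_parameters(source: Union[str, Path, dict]) -> ModelParameters:
    """Load parameters from a preset name, YAML/JSON file, or dict."""
    if isinstance(source, dict):
        return ModelParameters.from_dict(source)
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]()
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelParameters.from_dict(data)
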