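"""Model parameters for the cortex-basal ganglia-thalamus (BGCT) loop.

The loop couples seven neuronal populations, indexed 1..7:

    1 cortex, 2 striatum (D1), 3 striatum (D2), 4 GPi, 5 GPe,
    6 thalamus, 7 STN.

Each population carries a membrane capacitance ``C_i``, a resistance
``R_i`` and an external input ``I_i``.  Populations interact through
connection weights ``T_ij`` (from population j to i) via a saturating
Hill response; ``Dinput`` is the tonic dopamine level acting on the two
striatal populations with opposite sign.  ``T42`` (striatum-D1 -> GPi)
and ``T53`` (striatum-D2 -> GPe) are the direct- and indirect-pathway
weights that the analysis modules treat as the main control parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParameters", "WEIGHT_NAMES", "N_POP"]

N_POP = 7

#: Connection weights of the loop, in packed order.  Every weight that the
#: drift field uses appears here; there are no hidden couplings.
WEIGHT_NAMES = (
    "T16", "T21", "T26", "T31", "T36", "T42", "T45",
    "T47", "T53", "T57", "T64", "T71", "T75",
)

# Typical operating point of the loop (capacitances, resistances, inputs,
# fixed weights).  The direct/indirect weights T42 and T53 are the control
# parameters of the analysis and have no canonical value; they default to
# 1.0 (monostable regime) and are overridden per scan.
_DEFAULTS = {
    "C": 3.60,
    "R": 1.67,
    "I": (0.1, 0.05, 1.2, 4.4, 2.8, 2.0, 1.2),
    "T16": 2.0, "T21": 1.4, "T26": 1.4, "T31": 1.4, "T36": 1.4,
    "T42": 1.0, "T45": 3.0, "T47": 2.0, "T53": 1.0, "T57": 1.0,
    "T64": 3.2, "T71": 1.8, "T75": 1.8,
    "s": 2.0, "n": 2, "Dinput": 0.6,
}

# Sign pattern of each weighted Hill term: (target population i, source
# population j, sign).  Excitatory couplings enter with +, inhibitory
# (striatal GABA, GPe->STN/GPi, GPi->thalamus) with -.
COUPLINGS = (
    ("T16", 1, 6, +1.0),
    ("T21", 2, 1, +1.0),
    ("T26", 2, 6, +1.0),
    ("T31", 3, 1, +1.0),
    ("T36", 3, 6, +1.0),
    ("T42", 4, 2, -1.0),
    ("T45", 4, 5, -1.0),
    ("T47", 4, 7, +1.0),
    ("T53", 5, 3, -1.0),
    ("T57", 5, 7, +1.0),
    ("T64", 6, 4, -1.0),
    ("T71", 7, 1, +1.0),
    ("T75", 7, 5, -1.0),
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of the seven-population firing-rate loop.

    ``C``, ``R`` and ``I`` are length-7 arrays (population order above);
    connection weights are scalars named after their ``T_ij`` role.
    ``s`` and ``n`` are the Hill coefficient and index of the response
    nonlinearity ``x^n / (s^n + x^n)``.
    """

    C: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(N_POP, _DEFAULTS["C"]))
    R: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(N_POP, _DEFAULTS["R"]))
    I: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array(_DEFAULTS["I"]))
    T16: float = _DEFAULTS["T16"]
    T21: float = _DEFAULTS["T21"]
    T26: float = _DEFAULTS["T26"]
    T31: float = _DEFAULTS["T31"]
    T36: float = _DEFAULTS["T36"]
    T42: float = _DEFAULTS["T42"]
    T45: float = _DEFAULTS["T45"]
    T47: float = _DEFAULTS["T47"]
    T53: float = _DEFAULTS["T53"]
    T57: float = _DEFAULTS["T57"]
    T64: float = _DEFAULTS["T64"]
    T71: float = _DEFAULTS["T71"]
    T75: float = _DEFAULTS["T75"]
    s: float = _DEFAULTS["s"]
    n: int = _DEFAULTS["n"]
    Dinput: float = _DEFAULTS["Dinput"]

    def __post_init__(self) -> None:
        for name in ("C", "R", "I"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_POP,):
                raise ValueError(f"{name} must have length {N_POP}")
            object.__setattr__(self, name, arr)
        if not (np.all(self.C > 0) and np.all(self.R > 0)):
            raise ValueError("all capacitances C and resistances R must be > 0")
        if self.s <= 0:
            raise ValueError("Hill coefficient s must be > 0")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("Hill index n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))

    # -- derived quantities -------------------------------------------------

    @property
    def weights(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in WEIGHT_NAMES}

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden.

        Scalar per-population entries may be addressed as ``C1..C7``,
        ``R1..R7`` and ``I1..I7`` in addition to the array fields.
        """
        kwargs: dict = {}
        arrays = {k: np.array(getattr(self, k)) for k in ("C", "R", "I")}
        for key, value in overrides.items():
            if key in ("C", "R", "I"):
                arrays[key] = np.asarray(value, dtype=float)
            elif (len(key) in (2, 3) and key[0] in "CRI" and key[1:].isdigit()
                  and 1 <= int(key[1:]) <= N_POP):
                arrays[key[0]][int(key[1:]) - 1] = float(value)
            elif key in WEIGHT_NAMES or key in ("s", "Dinput"):
                kwargs[key] = float(value)
            elif key == "n":
                kwargs[key] = int(value)
            else:
                raise KeyError(f"unknown parameter {key!r}")
        kwargs.update(arrays)
        return dataclasses.replace(self, **kwargs)

    # -- flat key-value serialization --------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with keys C1..C7, R1..R7, I1..I7, T??, s, n, Dinput."""
        out: dict[str, float] = {}
        for name in ("C", "R", "I"):
            for i in range(N_POP):
                out[f"{name}{i + 1}"] = float(getattr(self, name)[i])
        out.update(self.weights)
        out["s"] = float(self.s)
        out["n"] = int(self.n)
        out["Dinput"] = float(self.Dinput)
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        return cls().replace(**mapping)

    def save(self, path: str | Path) -> None:
        """Write the parameter set as a flat YAML key-value file."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        """Load a flat YAML (or JSON — a YAML subset) parameter file."""
        text = Path(path).read_text()
        mapping = yaml.safe_load(text)
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(mapping)

    # -- packing for the compiled kernels ----------------------------------

    def pack(self) -> np.ndarray:
        """Flatten to the float64 layout used by the numerical kernels."""
        out = np.empty(24 + len(WEIGHT_NAMES))
        out[0:7] = self.C
        out[7:14] = self.R
        out[14:21] = self.I
        out[21] = self.s
        out[22] = float(self.n)
        out[23] = self.Dinput
        for k, name in enumerate(WEIGHT_NAMES):
            out[24 + k] = getattr(self, name)
        return out

    def equilibrium_box(self, margin: float = 1e-6) -> np.ndarray:
        """A-priori bounds containing every equilibrium of the field.

        At a fixed point ``x_i = R_i (I_i + sum of signed weighted Hill
        terms)`` and each Hill factor lies in ``[0, 1)``, so the signed
        sums bound each coordinate.  Returns shape (2, 7): rows are the
        lower and upper bounds.
        """
        lo = np.array(self.I, dtype=float)
        hi = np.array(self.I, dtype=float)
        lo[1] += self.Dinput
        hi[1] += self.Dinput
        lo[2] -= self.Dinput
        hi[2] -= self.Dinput
        for name, i, _j, sign in COUPLINGS:
            w = getattr(self, name)
            if sign > 0:
                hi[i - 1] += w
            else:
                lo[i - 1] -= w
        box = np.vstack([self.R * lo - margin, self.R * hi + margin])
        return box

    def __repr__(self) -> str:  # compact: only non-default scalars
        diffs = []
        base = ModelParameters()
        for name in (*WEIGHT_NAMES, "s", "n", "Dinput"):
            if getattr(self, name) != getattr(base, name):
                diffs.append(f"{name}={getattr(self, name):g}")
        inner = ", ".join(diffs) if diffs else "defaults"
        return f"ModelParameters({inner})"
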