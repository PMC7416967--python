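"""Dynamical state of the cell model.

Fifteen state variables: two free calcium concentrations (cytosol, ER), the
IP3/PIP2 pair, three myosin cross-bridge fractions (the fourth, M, follows by
conservation), three retained IP3R gate probabilities (X11 eliminated), three
retained RyR gate probabilities (R00 eliminated), and two bookkeeping
accumulators for cumulative calcium clearance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields

import numpy as np

__all__ = ["CellState", "STATE_ORDER", "STATE_UNITS"]


@dataclass(frozen=True)
class CellState:
    Ca_cyt: float       # uM, free cytosolic calcium
    Ca_er: float        # uM, free ER calcium
    IP3: float          # uM
    PIP2: float         # uM
    Mp: float           # fraction, phosphorylated free cross-bridges
    AMp: float          # fraction, attached phosphorylated cross-bridges
    AM: float           # fraction, attached dephosphorylated (latch)
    X00: float          # IP3R: rest
    X01: float          # IP3R: Ca on inactivation site
    X10: float          # IP3R: Ca on activation site (conducting)
    R10: float          # RyR: Ca on activation sites (conducting)
    R11: float          # RyR: both site classes occupied
    R01: float          # RyR: Ca on inactivation sites
    Ca_sink: float = 0.0    # uM, cumulative efflux to the ECS (cytosol volume)
    Ca_source: float = 0.0  # uM, cumulative mitochondrial release

    @property
    def M(self) -> float:
        """Free unphosphorylated myosin fraction (conservation)."""
        return 1.0 - self.Mp - self.AMp - self.AM

    @property
    def X11(self) -> float:
        """IP3R doubly Ca-bound state (conservation)."""
        return 1.0 - self.X00 - self.X01 - self.X10

    @property
    def R00(self) -> float:
        """RyR free-receptor state (conservation)."""
        return 1.0 - self.R10 - self.R11 - self.R01

    def validate(self, tol: float = 1e-9) -> None:
        """Raise ``ValueError`` on a physically invalid state."""
        for name in ("Ca_cyt", "Ca_er", "IP3", "PIP2"):
            if getattr(self, name) < -tol:
                raise ValueError(f"{name} must be non-negative")
        frac_names = ("Mp", "AMp", "AM", "X00", "X01", "X10",
                      "R10", "R11", "R01")
        for name in frac_names:
            v = getattr(self, name)
            if v < -tol or v > 1.0 + tol:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("M", "X11", "R00"):
            v = getattr(self, name)
            if v < -tol or v > 1.0 + tol:
                raise ValueError(f"eliminated state {name}={v} outside [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CellState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_ORDER),):
            raise ValueError(f"expected state vector of length {len(STATE_ORDER)}")
        return cls(**dict(zip(STATE_ORDER, y)))

    def replace(self, **changes) -> "CellState":
        return dataclasses.replace(self, **changes)


STATE_ORDER: tuple = tuple(f.name for f in fields(CellState))

STATE_UNITS: dict = {
    "Ca_cyt": "uM", "Ca_er": "uM", "IP3": "uM", "PIP2": "uM",
    "Mp": "fraction", "AMp": "fraction", "AM": "fraction",
    "X00": "probability", "X01": "probability", "X10": "probability",
    "R10": "probability", "R11": "probability", "R01": "probability",
    "Ca_sink": "uM", "Ca_source": "uM",
}
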