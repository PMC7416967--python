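"""Public model surface: buffering factors, individual fluxes, gate and
myosin kinetics, and the assembled right-hand side.

These wrappers validate inputs and delegate every rate law to the compiled
kernels in :mod:`vsmcal.kernels`, so the scalar API and the integrator share
one implementation.  Fluxes are uM/s of cytosolic free-calcium change,
positive into the cytosol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels as K
from .params import ParameterSet
from .state import CellState

__all__ = [
    "FluxBreakdown",
    "buffering_factor_cyt", "total_cyt_calcium",
    "buffering_factor_er", "total_er_calcium",
    "myosin_rhs", "tension_fraction", "myosin_calcium_flux",
    "ip3_pip2_rhs",
    "flux_mcu", "flux_nclx", "nernst_mit", "flux_mit_leak",
    "flux_serca", "serca_zero_flux_ratio",
    "ip3r_rhs", "flux_ipr", "ipr_open_probability",
    "ryr_rhs", "flux_ryr",
    "flux_ncx", "flux_vocc", "flux_pm_leak_pmca", "nernst_ecs",
    "flux_breakdown", "full_rhs", "atp_rate",
]


@dataclass(frozen=True)
class FluxBreakdown:
    """Per-mechanism calcium fluxes (uM/s) at one state.

    Aggregates satisfy, by construction,
    ``J_mit_to_cyt = J_mcu + J_nclx + J_mit_leak``,
    ``J_er_to_cyt = J_serca + J_ipr + J_ryr`` and
    ``J_ecs_to_cyt = J_ecs_leak + J_pmca + J_ncx + J_vocc``.
    """

    J_mcu: float
    J_nclx: float
    J_mit_leak: float
    J_serca: float
    J_ipr: float
    J_ryr: float
    J_ncx: float
    J_vocc: float
    J_pmca: float
    J_ecs_leak: float
    J_cyt_cyt: float

    @property
    def J_mit_to_cyt(self) -> float:
        return self.J_mcu + self.J_nclx + self.J_mit_leak

    @property
    def J_er_to_cyt(self) -> float:
        return self.J_serca + self.J_ipr + self.J_ryr

    @property
    def J_ecs_to_cyt(self) -> float:
        return self.J_ecs_leak + self.J_pmca + self.J_ncx + self.J_vocc


def _check_nonneg(value: float, name: str) -> None:
    if value < 0.0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def _check_pos(value: float, name: str) -> None:
    if value <= 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


# --- buffering -------------------------------------------------------------

def buffering_factor_cyt(Ca_cyt: float, params: ParameterSet) -> float:
    """Rapid-buffer factor b_cyt = 1 + sum_i K_i [B_i]/(K_i + c)^2, >= 1."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return float(K.b_cyt_kernel(Ca_cyt, params.to_vector()))


def total_cyt_calcium(Ca_cyt: float, params: ParameterSet) -> float:
    """Total (free + bound) cytosolic calcium, uM.

    Saturable form c + sum_i [B_i] c/(K_i + c) — the antiderivative of the
    buffering factor, so d(total)/dc == buffering_factor_cyt.
    """
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return float(K.total_cyt_kernel(Ca_cyt, params.to_vector()))


def buffering_factor_er(Ca_er: float, params: ParameterSet) -> float:
    """ER rapid-buffer factor over the calreticulin C and P site classes."""
    _check_nonneg(Ca_er, "Ca_er")
    return float(K.b_er_kernel(Ca_er, params.to_vector()))


def total_er_calcium(Ca_er: float, params: ParameterSet) -> float:
    """Total (free + bound) ER calcium, uM."""
    _check_nonneg(Ca_er, "Ca_er")
    return float(K.total_er_kernel(Ca_er, params.to_vector()))


# --- myosin ----------------------------------------------------------------

def myosin_rhs(state: CellState, Ca_cyt: float, params: ParameterSet):
    """Time derivatives (dMp, dAMp, dAM); the four-state sum is conserved."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return K.myosin_rhs_kernel(state.Mp, state.AMp, state.AM, Ca_cyt,
                               params.to_vector())


def tension_fraction(state: CellState) -> float:
    """Contractile tension proxy Fr = AMp + AM (proportionality constant 1)."""
    return state.AMp + state.AM


def myosin_calcium_flux(myosin_derivatives, params: ParameterSet) -> float:
    """J_cyt->cyt = -stoich * [Myo] * d(Mp + AMp)/dt.

    Phosphorylated heads sequester cytosolic calcium, so net phosphorylation
    lowers free calcium.
    """
    dMp, dAMp = myosin_derivatives[0], myosin_derivatives[1]
    return -params.myosin_ca_stoich * params.Myo_tot * (dMp + dAMp)


# --- IP3 / PIP2 ------------------------------------------------------------

def ip3_pip2_rhs(IP3: float, PIP2: float, Ca_cyt: float,
                 params: ParameterSet):
    """(dIP3/dt, dPIP2/dt) with Ca-dependent PLC rate r_h."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    _check_nonneg(IP3, "IP3")
    _check_nonneg(PIP2, "PIP2")
    return K.ip3_pip2_rhs_kernel(IP3, PIP2, Ca_cyt, params.to_vector())


# --- mitochondrial fluxes --------------------------------------------------

def flux_mcu(Ca_cyt: float, params: ParameterSet) -> float:
    """Uniporter uptake out of the cytosol; always <= 0."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return float(K.flux_mcu_kernel(Ca_cyt, params.to_vector()))


def flux_nclx(Ca_cyt: float, Ca_mit: float, params: ParameterSet) -> float:
    """Mitochondrial Na/Ca exchanger, matrix -> cytosol; >= 0."""
    _check_pos(Ca_cyt, "Ca_cyt")
    _check_nonneg(Ca_mit, "Ca_mit")
    return float(K.flux_nclx_kernel(Ca_cyt, Ca_mit, params.to_vector()))


def nernst_mit(Ca_mit: float, Ca_cyt: float, params: ParameterSet) -> float:
    """Mitochondrial calcium Nernst potential (mV), (RT/2F) ln(mit/cyt)."""
    _check_pos(Ca_mit, "Ca_mit")
    _check_pos(Ca_cyt, "Ca_cyt")
    return float(K.nernst_mit_kernel(Ca_mit, Ca_cyt, params.to_vector()))


def flux_mit_leak(Ca_mit: float, Ca_cyt: float,
                  params: ParameterSet) -> float:
    """Ohmic leak nu_mit_leak * (E_Ca,mit - dPsi_m)."""
    _check_pos(Ca_mit, "Ca_mit")
    _check_pos(Ca_cyt, "Ca_cyt")
    return float(K.flux_mit_leak_kernel(Ca_cyt, Ca_mit, params.to_vector()))


# --- ER fluxes -------------------------------------------------------------

def flux_serca(Ca_cyt: float, Ca_er: float, params: ParameterSet) -> float:
    """SERCA pump flux; <= 0 (cytosol -> ER) above the thermodynamic ratio."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    _check_nonneg(Ca_er, "Ca_er")
    return float(K.flux_serca_kernel(Ca_cyt, Ca_er, params.to_vector()))


def serca_zero_flux_ratio(params: ParameterSet) -> float:
    """Ca_cyt/Ca_er ratio at which the SERCA cycle stalls."""
    return (params.K1_serca * params.K3_serca
            * np.sqrt(params.km2_serca * params.km4_serca
                      / (params.k2_serca * params.k4_serca)))


# --- IP3R ------------------------------------------------------------------

def ip3r_rhs(X00: float, X01: float, X10: float, Ca_cyt: float,
             IP3: float, params: ParameterSet):
    """Derivatives of the retained IP3R states (X11 by conservation)."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    if IP3 <= 0.0:
        raise ValueError("IP3 must be strictly positive (k1, k3 diverge)")
    return K.ip3r_rhs_kernel(X00, X01, X10, Ca_cyt, IP3, params.to_vector())


def ipr_open_probability(X10: float) -> float:
    """P(open) = X10^4 + 4 X10^3 (1 - X10): >= 3 of 4 active subunits."""
    return float(K.ipr_open_prob_kernel(X10))


def flux_ipr(X10: float, Ca_cyt: float, Ca_er: float,
             params: ParameterSet) -> float:
    if not 0.0 <= X10 <= 1.0:
        raise ValueError("X10 must lie in [0, 1]")
    return float(K.flux_ipr_kernel(X10, Ca_cyt, Ca_er, params.to_vector()))


# --- RyR -------------------------------------------------------------------

def ryr_rhs(R10: float, R11: float, R01: float, Ca_cyt: float,
            params: ParameterSet):
    """Derivatives of the retained RyR states (R00 by conservation)."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return K.ryr_rhs_kernel(R10, R11, R01, Ca_cyt, params.to_vector())


def flux_ryr(R10: float, Ca_cyt: float, Ca_er: float,
             params: ParameterSet) -> float:
    if not 0.0 <= R10 <= 1.0:
        raise ValueError("R10 must lie in [0, 1]")
    return float(K.flux_ryr_kernel(R10, Ca_cyt, Ca_er, params.to_vector()))


# --- plasma membrane -------------------------------------------------------

def flux_ncx(Ca_cyt: float, params: ParameterSet) -> float:
    """Na/Ca exchanger; net extrusion (<= 0) at and above resting calcium."""
    _check_nonneg(Ca_cyt, "Ca_cyt")
    return float(K.flux_ncx_kernel(Ca_cyt, params.to_vector()))


def flux_vocc(Ca_cyt: float, params: ParameterSet) -> float:
    """Voltage-operated calcium channel influx."""
    _check_pos(Ca_cyt, "Ca_cyt")
    return float(K.flux_vocc_kernel(Ca_cyt, params.to_vector()))


def nernst_ecs(Ca_cyt: float, params: ParameterSet) -> float:
    """Plasma-membrane calcium Nernst potential (mV)."""
    _check_pos(Ca_cyt, "Ca_cyt")
    return float(K.nernst_ecs_kernel(Ca_cyt, params.to_vector()))


def flux_pm_leak_pmca(Ca_cyt: float, params: ParameterSet):
    """(J_ecs_leak, J_pmca)."""
    _check_pos(Ca_cyt, "Ca_cyt")
    p = params.to_vector()
    return (float(K.flux_ecs_leak_kernel(Ca_cyt, p)),
            float(K.flux_pmca_kernel(Ca_cyt, p)))


# --- assembled -------------------------------------------------------------

def flux_breakdown(state: CellState, params: ParameterSet) -> FluxBreakdown:
    """Every component flux at one state (unrescaled)."""
    vals = K.flux_kernel(state.to_vector(), params.to_vector())
    return FluxBreakdown(*(float(v) for v in vals))


def full_rhs(t: float, state: CellState, params: ParameterSet) -> np.ndarray:
    """Complete state derivative at time ``t`` (autonomous system).

    Compartment aggregates carry their alpha rescaling; Ca_mit is a fixed
    scenario parameter (quasi-steady dissolution of calcium-phosphate
    clusters holds matrix free calcium at saturation).
    """
    state.validate(tol=1e-6)
    return np.asarray(K.rhs_kernel(t, state.to_vector(), params.to_vector()))


def atp_rate(J_mit_to_cyt: float, params: ParameterSet) -> float:
    """ATP production rate (uM/s, cytosol-referenced) tied to dissolution.

    Each dissolved calcium consumes ``protons_per_Ca`` matrix protons and
    three protons fund one ATP at the F0F1 synthase, so the rate carries the
    sign of the mitochondrial flux: outward flux reinforces the proton
    gradient, inward flux opposes it.
    """
    return params.protons_per_Ca * J_mit_to_cyt / params.protons_per_ATP
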