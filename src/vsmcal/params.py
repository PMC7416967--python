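"""Model parameters for the vascular smooth muscle calcium model.

All concentrations are micromolar (uM), rates per second, potentials in mV,
volumes in pL.  Fluxes everywhere in the package are referenced to the
cytosolic volume (uM/s of cytosolic concentration change).

Three constants are *calibrated* rather than tabulated: the mitochondrial
Ohmic leak conductance ``nu_mit_leak`` (zero net mitochondrial flux at the
resting state), the NCX prefactor ``Q_ncx`` (zero net plasma-membrane flux at
rest; the literature prefactor is dimensionally unusable) and the SERCA
multiplier ``serca_scale`` (zero net ER flux at rest).  See
:mod:`vsmcal.calibration`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["ParameterSet", "default_parameters", "PARAM_ORDER", "GAS_CONSTANT"]

#: molar gas constant, J/(mol K)
GAS_CONSTANT = 8.31446261815324


@dataclass(frozen=True)
class ParameterSet:
    """Immutable container of every model constant.

    Field groups follow the model compartments.  Use
    :func:`dataclasses.replace` (re-exported as :meth:`replace`) to derive
    variants, and :meth:`to_vector` for the packed float array consumed by the
    numerical kernels.
    """

    # --- cytosolic buffers (rapid buffer approximation) ---
    K_CaM: float = 0.260        # uM, calmodulin site dissociation constant
    CaM_tot: float = 30.0       # uM, calmodulin site concentration
    K_B: float = 0.530          # uM, "other" buffer dissociation constant
    B_tot: float = 30.0         # uM, "other" buffer concentration

    # --- myosin four-state (Hai-Murphy latch) model ---
    Myo_tot: float = 10.0       # uM, total myosin heads
    gamma_cross: float = 17.0   # (uM)^-3 s^-1, Ca^3-dependent MLCK rate
    K2: float = 0.5             # s^-1, Mp -> M dephosphorylation
    K3: float = 0.4             # s^-1, Mp -> AMp cross-bridge attachment
    K4: float = 0.1             # s^-1, AMp -> Mp detachment
    K5: float = 0.5             # s^-1, AMp -> AM dephosphorylation
    K7: float = 0.1             # s^-1, AM -> M latch detachment

    # --- IP3 / PIP2 turnover ---
    eta_IP3: float = 11.725     # (uM s)^-1, PLC signal gain
    kdeg_IP3: float = 1.25      # s^-1, IP3 degradation
    k_c: float = 0.4            # uM, Ca binding to PLC
    PIP2_rr: float = 0.1        # s^-1, PIP2 replenishment
    PIP2_tot: float = 118.61    # uM, total PIP2 pool
    G_conc: float = 3.314e-5    # uM, fixed active G-protein concentration

    # --- mitochondria ---
    nu_mcu: float = 4.4e-6      # uM/s, MCU rate constant
    nu_nclx: float = 0.13       # uM/s, NCLX rate constant
    K_mcu1: float = 6.0         # uM, MCU translocation dissociation constant
    K_mcu2: float = 0.38        # uM, MCU activation dissociation constant
    L_mcu: float = 50.0         # -, allosteric equilibrium constant
    p1: float = 0.1             # mV^-1, MCU voltage dependence
    p2: float = 0.0161          # mV^-1, NCLX voltage dependence
    dPsi_m: float = 140.0       # mV, fixed mitochondrial membrane potential
    nu_mit_leak: float = 8.8376e-3   # uM s^-1 mV^-1, Ohmic leak (calibrated)

    # --- ER buffers ---
    K_CalC: float = 2.0e3       # uM, calreticulin site C
    CalC_tot: float = 7.2e3     # uM
    K_CalP: float = 10.0        # uM, calreticulin site P
    CalP_tot: float = 7.2e2     # uM

    # --- SERCA (two-state cycle, rates already scaled by xi = 10) ---
    K1_serca: float = 0.7           # uM, cytosolic binding constant
    K3_serca: float = 1.111111e-5   # ER-side binding constant
    k2_serca: float = 6.0           # s^-1 (0.6 * xi)
    km2_serca: float = 9.7          # s^-1 (0.97 * xi)
    k4_serca: float = 4.0           # s^-1 (0.4 * xi)
    km4_serca: float = 0.012        # s^-1 (1.2e-3 * xi)
    SERCA_tot: float = 182.0        # uM, pump protein
    serca_scale: float = 1.0        # -, calibrated multiplier

    # --- IP3R (four-state reduction, De Young-Keizer style constants) ---
    nu_ipr: float = 1000.0      # s^-1, channel rate constant
    a1: float = 167.6           # (uM s)^-1, IP3 binding (inactivation empty)
    a2: float = 3.81            # (uM s)^-1, Ca inactivation (IP3 bound)
    a3: float = 413.4           # (uM s)^-1, IP3 binding (inactivation occupied)
    a4: float = 0.3101          # (uM s)^-1, Ca inactivation (IP3 unbound)
    a5: float = 53.9            # (uM s)^-1, Ca activation
    b1: float = 228.0           # s^-1
    b2: float = 0.409           # s^-1
    b3: float = 188.5           # s^-1
    b4: float = 0.096           # s^-1
    b5: float = 4.52            # s^-1

    # --- RyR (four-state, two independent Ca sites) ---
    nu_ryr: float = 0.2         # s^-1, channel rate constant
    Kr1: float = 2.5            # (uM)^-2 s^-1, activation binding
    Kr2: float = 1.5            # (uM)^-1 s^-1, inactivation binding
    Kmr1: float = 7.6           # s^-1, activation unbinding
    Kmr2: float = 84.0          # s^-1, inactivation unbinding

    # --- plasma membrane ---
    phi_ecs: float = -54.0      # mV, fixed membrane potential
    Na_cyt: float = 8.0e3       # uM
    Na_ecs: float = 1.4e5       # uM
    eta_ncx: float = 0.35       # -, NCX energy barrier position
    d_ncx: float = 1.0e8        # uM^-4  ( = (0.01 uM)^-4 )
    k_ncx1: float = 0.125       # uM, NCX allosteric Ca activation
    k_ncx2: float = 0.5         # uA, literature prefactor (unused; see Q_ncx)
    Q_ncx: float = 1.0          # uM/s-scale prefactor (calibrated)
    Q_pmca: float = 0.04        # uM/s, PMCA maximal rate
    k_pmca: float = 0.15        # uM, PMCA dissociation constant
    Q_vocc: float = 0.10        # uM (mV s)^-1, VOCC conductance
    g_leak_ecs: float = 3.0e-5  # uM (mV s)^-1, non-specific leak conductance
    F: float = 96487.0          # C/mol, Faraday constant

    # --- geometry ---
    V_cyt: float = 0.7          # pL
    r_ercyt: float = 10.0       # -, V_cyt / V_er
    r_mitcyt: float = 13.6      # -, V_cyt / V_mit

    # --- environment / scenario ---
    Ca_ecs: float = 1300.0      # uM, fixed extracellular calcium
    Ca_mit: float = 0.1         # uM, mitochondrial free (saturation) calcium
    temperature_K: float = 310.0

    # --- ATP stoichiometry ---
    protons_per_Ca: float = 2.0     # protons consumed per dissolved Ca
    protons_per_ATP: float = 3.0    # protons per ATP at the F0F1 synthase
    # Calcium sequestered per phosphorylated myosin head, feeding the
    # myosin -> cytosol reaction flux.  Default 0: myosin is a contraction
    # readout whose calcium consumption is negligible next to the explicit
    # buffers (see docs/methods.md); set to 1 (or 3) to enable the coupling.
    myosin_ca_stoich: float = 0.0

    # --- flux rescalings (the alpha sweep axes) ---
    alpha_er: float = 1.0
    alpha_mit: float = 1.0
    alpha_pm: float = 1.0

    # --- numerical guard ---
    ca_floor: float = 1e-6      # uM, floor on Ca_cyt inside flux kernels

    def __post_init__(self) -> None:
        positive = [
            f.name
            for f in fields(self)
            if f.name not in ("phi_ecs", "k_ncx2", "myosin_ca_stoich")
        ]
        if self.myosin_ca_stoich < 0.0:
            raise ValueError("myosin_ca_stoich must be non-negative")
        for name in positive:
            if not getattr(self, name) > 0.0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in ("alpha_er", "alpha_mit", "alpha_pm"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def RT_over_F(self) -> float:
        """RT/F in mV at ``temperature_K``."""
        return 1e3 * GAS_CONSTANT * self.temperature_K / self.F

    @property
    def RT_over_2F(self) -> float:
        """RT/2F in mV — the Nernst slope for a divalent ion (~13.357 mV at 310 K)."""
        return 0.5 * self.RT_over_F

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_vector(self) -> np.ndarray:
        """Pack into the float vector consumed by the numba kernels."""
        vec = np.empty(len(PARAM_ORDER), dtype=np.float64)
        for i, name in enumerate(PARAM_ORDER[:-1]):
            vec[i] = getattr(self, name)
        vec[-1] = self.RT_over_2F
        return vec

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["RT_over_2F"] = self.RT_over_2F
        return d


#: packing order for the kernel parameter vector; RT_over_2F (derived) is last
PARAM_ORDER: tuple = tuple(
    f.name for f in fields(ParameterSet)
) + ("RT_over_2F",)


def default_parameters(**overrides) -> ParameterSet:
    """The reference (uncalibrated) parameter set.

    ``nu_mit_leak``, ``Q_ncx`` and ``serca_scale`` carry placeholder values
    until :func:`vsmcal.calibration.calibrate` enforces the resting fixed
    point.
    """
    return ParameterSet(**overrides)
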