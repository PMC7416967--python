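"""Steady-state parameterization.

The resting cell (Ca_cyt = 0.1 uM, Ca_er = 500 uM, Ca_mit = 0.1 uM,
Ca_ecs = 1300 uM) is enforced as an exact fixed point by solving for three
free constants:

* ``nu_mit_leak`` — zero net mitochondrial flux at rest (the Nernst
  potential vanishes when matrix and cytosolic calcium are equal, so the
  leak must cancel MCU uptake plus NCLX extrusion);
* ``Q_ncx`` — zero net plasma-membrane flux at rest given the tabulated
  VOCC, PMCA and leak conductances;
* ``serca_scale`` — zero net ER flux at rest given the IP3R and RyR release
  at their gate fixed points.

Because each compartment aggregate vanishes at the calibrated rest state,
any rescaling (alpha_er, alpha_mit, alpha_pm) leaves the fixed point intact.

Gate fixed points here are computed from the *full* four-state transition
matrices (a 4x4 linear solve with a normalization row) — an independent
construction from the reduced affine right-hand sides in
:mod:`vsmcal.kernels`, which the test suite cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels as K
from .params import ParameterSet, default_parameters
from .state import CellState

__all__ = [
    "CalibrationResult", "solve_ip3_steady", "solve_gate_steady",
    "solve_myosin_steady", "calibrate_mit_leak", "calibrate_pm_and_er",
    "build_baseline_state", "calibrate", "calibrated_parameters",
]

#: enforced resting free calcium concentrations (uM)
CA_CYT_REST = 0.1
CA_ER_REST = 500.0
CA_MIT_REST = 0.1

RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationResult:
    nu_mit_leak: float      # uM s^-1 mV^-1
    Q_ncx: float            # uM/s-scale NCX prefactor
    serca_scale: float      # dimensionless
    IP3_ss: float           # uM
    PIP2_ss: float          # uM
    baseline_state: CellState
    residual_norm: float    # max |dy/dt| at baseline, natural units / s

    def to_dict(self) -> dict:
        return {
            "nu_mit_leak": self.nu_mit_leak,
            "Q_ncx": self.Q_ncx,
            "serca_scale": self.serca_scale,
            "IP3_ss": self.IP3_ss,
            "PIP2_ss": self.PIP2_ss,
            "residual_norm": self.residual_norm,
        }


def solve_ip3_steady(params: ParameterSet,
                     Ca_cyt: float = CA_CYT_REST) -> tuple[float, float]:
    """Closed-form fixed point of the IP3/PIP2 pair at fixed calcium.

    With r_h = eta * c/(k_c + c) * [G], the 2x2 linear system gives
    IP3_ss = r_h rr PIP2_tot / (kdeg (r_h + rr) + r_h rr).
    """
    rh = params.eta_IP3 * Ca_cyt / (params.k_c + Ca_cyt) * params.G_conc
    rr = params.PIP2_rr
    kdeg = params.kdeg_IP3
    if rh == 0.0:
        return 0.0, params.PIP2_tot
    ip3 = rh * rr * params.PIP2_tot / (kdeg * (rh + rr) + rh * rr)
    pip2 = kdeg * ip3 / rh
    return float(ip3), float(pip2)


def _stationary_4state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state rate matrix (columns = from)."""
    A = Q.copy()
    A[-1, :] = 1.0                      # replace one balance row by sum = 1
    b = np.zeros(4)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    if np.any(pi < -1e-12):
        raise ValueError("gate stationary solve produced negative occupancy")
    return pi


def solve_gate_steady(Ca_cyt: float, IP3: float,
                      params: ParameterSet) -> dict:
    """IP3R and RyR fixed points from full 4x4 transition-rate matrices.

    Returns a dict with X00, X01, X10, X11, R00, R10, R11, R01.
    """
    if Ca_cyt <= 0.0 or IP3 <= 0.0:
        raise ValueError("Ca_cyt and IP3 must be strictly positive")
    p = params.to_vector()
    (act_on, act_off, inact_on, inact_off,
     a2c, b2, act_on_i, b5) = K.ip3r_rates_kernel(Ca_cyt, IP3, p)
    # state order (X00, X01, X10, X11); Q[i, j] = rate j -> i, Q[j, j] = -sum
    Qx = np.zeros((4, 4))
    Qx[2, 0] = act_on
    Qx[0, 2] = act_off
    Qx[1, 0] = inact_on
    Qx[0, 1] = inact_off
    Qx[3, 2] = a2c
    Qx[2, 3] = b2
    Qx[3, 1] = act_on_i
    Qx[1, 3] = b5
    np.fill_diagonal(Qx, 0.0)
    Qx[np.diag_indices(4)] = -Qx.sum(axis=0)
    X = _stationary_4state(Qx)

    c = Ca_cyt
    a_on = params.Kr1 * c * c
    i_on = params.Kr2 * c
    # state order (R00, R10, R01, R11); two independent site classes
    Qr = np.zeros((4, 4))
    Qr[1, 0] = a_on
    Qr[0, 1] = params.Kmr1
    Qr[2, 0] = i_on
    Qr[0, 2] = params.Kmr2
    Qr[3, 1] = i_on
    Qr[1, 3] = params.Kmr2
    Qr[3, 2] = a_on
    Qr[2, 3] = params.Kmr1
    Qr[np.diag_indices(4)] = -Qr.sum(axis=0)
    R = _stationary_4state(Qr)

    return {
        "X00": X[0], "X01": X[1], "X10": X[2], "X11": X[3],
        "R00": R[0], "R10": R[1], "R01": R[2], "R11": R[3],
    }


def solve_myosin_steady(Ca_cyt: float, params: ParameterSet) -> dict:
    """Myosin four-state fixed point at fixed calcium (4x4 linear solve)."""
    k1 = params.gamma_cross * Ca_cyt ** 3
    # state order (M, Mp, AMp, AM)
    Q = np.zeros((4, 4))
    Q[1, 0] = k1                       # M -> Mp
    Q[0, 1] = params.K2                # Mp -> M
    Q[2, 1] = params.K3                # Mp -> AMp
    Q[1, 2] = params.K4                # AMp -> Mp
    Q[3, 2] = params.K5                # AMp -> AM
    Q[2, 3] = k1                       # AM -> AMp (K6 = K1)
    Q[0, 3] = params.K7                # AM -> M
    Q[np.diag_indices(4)] = -Q.sum(axis=0)
    pi = _stationary_4state(Q)
    return {"M": pi[0], "Mp": pi[1], "AMp": pi[2], "AM": pi[3]}


def calibrate_mit_leak(params: ParameterSet) -> float:
    """Leak conductance nulling the mitochondrial flux at rest.

    At Ca_mit = Ca_cyt the Nernst potential is zero, so
    nu_mit_leak = (J_mcu + J_nclx) / dPsi_m.
    """
    p = params.to_vector()
    j = (K.flux_mcu_kernel(CA_CYT_REST, p)
         + K.flux_nclx_kernel(CA_CYT_REST, CA_MIT_REST, p))
    nu = float(j / params.dPsi_m)
    if nu <= 0.0:
        raise ValueError(
            "calibrated nu_mit_leak must be positive; "
            "NCLX extrusion must exceed MCU uptake at rest")
    return nu


def calibrate_pm_and_er(params: ParameterSet,
                        gates: dict | None = None) -> tuple[float, float]:
    """(Q_ncx, serca_scale) nulling the PM and ER aggregates at rest."""
    p = params.to_vector()
    other_pm = (K.flux_vocc_kernel(CA_CYT_REST, p)
                + K.flux_pmca_kernel(CA_CYT_REST, p)
                + K.flux_ecs_leak_kernel(CA_CYT_REST, p))
    shape = K.ncx_shape_kernel(CA_CYT_REST, p)
    q_ncx = float(-other_pm / shape)
    if q_ncx < 0.0:
        raise ValueError(
            "plasma-membrane balance requires NCX influx at rest; "
            "check VOCC/PMCA/leak parameters")

    if gates is None:
        ip3_ss, _ = solve_ip3_steady(params)
        gates = solve_gate_steady(CA_CYT_REST, ip3_ss, params)
    release = (K.flux_ipr_kernel(gates["X10"], CA_CYT_REST, CA_ER_REST, p)
               + K.flux_ryr_kernel(gates["R10"], CA_CYT_REST, CA_ER_REST, p))
    raw = params.replace(serca_scale=1.0)
    serca_raw = K.flux_serca_kernel(CA_CYT_REST, CA_ER_REST, raw.to_vector())
    scale = float(-release / serca_raw)
    if scale <= 0.0:
        raise ValueError("SERCA must pump cytosol -> ER at rest")
    return q_ncx, scale


def build_baseline_state(params: ParameterSet) -> CellState:
    """Assemble the resting state from the analytic fixed points.

    ``params`` must already be calibrated; raises if the right-hand side at
    the assembled state exceeds the residual tolerance.
    """
    ip3_ss, pip2_ss = solve_ip3_steady(params)
    gates = solve_gate_steady(CA_CYT_REST, ip3_ss, params)
    myo = solve_myosin_steady(CA_CYT_REST, params)
    state = CellState(
        Ca_cyt=CA_CYT_REST, Ca_er=CA_ER_REST, IP3=ip3_ss, PIP2=pip2_ss,
        Mp=myo["Mp"], AMp=myo["AMp"], AM=myo["AM"],
        X00=gates["X00"], X01=gates["X01"], X10=gates["X10"],
        R10=gates["R10"], R11=gates["R11"], R01=gates["R01"],
        Ca_sink=0.0, Ca_source=0.0,
    )
    resid = _residual_norm(state, params)
    if resid > RESIDUAL_TOL:
        raise ValueError(
            f"baseline residual {resid:.3e} exceeds {RESIDUAL_TOL:.0e}; "
            "parameters are not calibrated")
    return state


def _residual_norm(state: CellState, params: ParameterSet) -> float:
    dy = K.rhs_kernel(0.0, state.to_vector(), params.to_vector())
    return float(np.max(np.abs(dy)))


def calibrate(params: ParameterSet | None = None
              ) -> tuple[ParameterSet, CalibrationResult]:
    """Solve the three free constants and assemble the resting state.

    Idempotent: recalibrating an already-calibrated set reproduces the same
    constants (none of the solves depends on its own target constant).
    """
    if params is None:
        params = default_parameters()
    must_rest = params.replace(Ca_mit=CA_MIT_REST)
    nu = calibrate_mit_leak(must_rest)
    ip3_ss, pip2_ss = solve_ip3_steady(must_rest)
    gates = solve_gate_steady(CA_CYT_REST, ip3_ss, must_rest)
    q_ncx, scale = calibrate_pm_and_er(must_rest, gates)
    calibrated = params.replace(nu_mit_leak=nu, Q_ncx=q_ncx,
                                serca_scale=scale)
    baseline = build_baseline_state(calibrated.replace(Ca_mit=CA_MIT_REST))
    resid = _residual_norm(baseline,
                           calibrated.replace(Ca_mit=CA_MIT_REST))
    result = CalibrationResult(
        nu_mit_leak=nu, Q_ncx=q_ncx, serca_scale=scale,
        IP3_ss=ip3_ss, PIP2_ss=pip2_ss,
        baseline_state=baseline, residual_norm=resid,
    )
    return calibrated, result


def calibrated_parameters(**overrides) -> tuple[ParameterSet, CellState]:
    """Convenience: calibrated defaults (plus overrides) and the rest state.

    Overrides are applied *before* calibration, so e.g. a different Ca_mit or
    alpha triple still starts from the enforced resting fixed point.
    """
    params, result = calibrate(default_parameters().replace(**overrides))
    return params, result.baseline_state
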