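"""Numba-compiled flux kernels and the full ODE right-hand side.

Single source of truth for every rate law: the public wrappers in
:mod:`vsmcal.model` and the integrator in :mod:`vsmcal.simulate` both call
these kernels.  Kernels take the packed parameter vector produced by
``ParameterSet.to_vector()`` and scalar/array state values.

Sign convention: every flux ``J`` is a rate of change of *cytosolic* free
calcium (uM/s, positive = raises cytosolic calcium), before division by the
buffering factor.

A floor of ``ca_floor`` (default 1e-6 uM) is applied to cytosolic calcium
inside the kernels to guard the NCLX ratio and the Nernst logarithms; the
floor is far below any concentration visited by nominal trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PARAM_ORDER

# ---------------------------------------------------------------------------
# index constants (plain ints -> compile-time constants for numba)
# ---------------------------------------------------------------------------
for _i, _name in enumerate(PARAM_ORDER):
    globals()["I_" + _name.upper()] = _i
del _i, _name

N_STATE = 15
# state vector layout (see vsmcal.state.STATE_ORDER)
S_CA_CYT, S_CA_ER, S_IP3, S_PIP2 = 0, 1, 2, 3
S_MP, S_AMP, S_AM = 4, 5, 6
S_X00, S_X01, S_X10 = 7, 8, 9
S_R10, S_R11, S_R01 = 10, 11, 12
S_SINK, S_SOURCE = 13, 14

# flux table layout returned by flux_kernel
N_FLUX = 11
F_MCU, F_NCLX, F_MIT_LEAK = 0, 1, 2
F_SERCA, F_IPR, F_RYR = 3, 4, 5
F_NCX, F_VOCC, F_PMCA, F_ECS_LEAK = 6, 7, 8, 9
F_CYT_CYT = 10

FLUX_NAMES = (
    "J_mcu", "J_nclx", "J_mit_leak",
    "J_serca", "J_ipr", "J_ryr",
    "J_ncx", "J_vocc", "J_pmca", "J_ecs_leak",
    "J_cyt_cyt",
)


# ---------------------------------------------------------------------------
# buffering
# ---------------------------------------------------------------------------
@njit(cache=True)
def b_cyt_kernel(c, p):
    """Cytosolic rapid-buffer factor, >= 1."""
    t1 = p[I_K_CAM] * p[I_CAM_TOT] / (p[I_K_CAM] + c) ** 2
    t2 = p[I_K_B] * p[I_B_TOT] / (p[I_K_B] + c) ** 2
    return 1.0 + t1 + t2


@njit(cache=True)
def total_cyt_kernel(c, p):
    """Free + buffer-bound cytosolic calcium (saturable form)."""
    return c * (1.0 + p[I_CAM_TOT] / (p[I_K_CAM] + c)
                + p[I_B_TOT] / (p[I_K_B] + c))


@njit(cache=True)
def b_er_kernel(cer, p):
    """ER rapid-buffer factor, >= 1."""
    t1 = p[I_K_CALC] * p[I_CALC_TOT] / (p[I_K_CALC] + cer) ** 2
    t2 = p[I_K_CALP] * p[I_CALP_TOT] / (p[I_K_CALP] + cer) ** 2
    return 1.0 + t1 + t2


@njit(cache=True)
def total_er_kernel(cer, p):
    """Free + buffer-bound ER calcium (saturable form)."""
    return cer * (1.0 + p[I_CALC_TOT] / (p[I_K_CALC] + cer)
                  + p[I_CALP_TOT] / (p[I_K_CALP] + cer))


# ---------------------------------------------------------------------------
# myosin (Hai-Murphy four-state latch model)
# ---------------------------------------------------------------------------
@njit(cache=True)
def myosin_rhs_kernel(Mp, AMp, AM, c, p):
    """d/dt of (Mp, AMp, AM); M follows by conservation."""
    k1 = p[I_GAMMA_CROSS] * c ** 3      # M -> Mp (MLCK, Ca^3)
    k6 = k1                             # AM -> AMp
    M = 1.0 - Mp - AMp - AM
    dMp = p[I_K4] * AMp + k1 * M - (p[I_K2] + p[I_K3]) * Mp
    dAMp = p[I_K3] * Mp + k6 * AM - (p[I_K4] + p[I_K5]) * AMp
    dAM = p[I_K5] * AMp - (p[I_K7] + k6) * AM
    return dMp, dAMp, dAM


# ---------------------------------------------------------------------------
# IP3 / PIP2
# ---------------------------------------------------------------------------
@njit(cache=True)
def ip3_pip2_rhs_kernel(ip3, pip2, c, p):
    rh = p[I_ETA_IP3] * c / (p[I_K_C] + c) * p[I_G_CONC]
    dip3 = rh * pip2 - p[I_KDEG_IP3] * ip3
    dpip2 = -(rh + p[I_PIP2_RR]) * pip2 + p[I_PIP2_RR] * (p[I_PIP2_TOT] - ip3)
    return dip3, dpip2


# ---------------------------------------------------------------------------
# mitochondrial fluxes
# ---------------------------------------------------------------------------
@njit(cache=True)
def flux_mcu_kernel(c, p):
    """Uniporter uptake, unidirectional cytosol -> matrix (<= 0)."""
    x = c / p[I_K_MCU1]
    num = x * (1.0 + x) ** 3
    den = (1.0 + x) ** 4 + p[I_L_MCU] * (1.0 + c / p[I_K_MCU2]) ** 2.3
    return -p[I_NU_MCU] * num / den * np.exp(p[I_P1] * p[I_DPSI_M])


@njit(cache=True)
def flux_nclx_kernel(c, camit, p):
    """NCLX extrusion, matrix -> cytosol (>= 0)."""
    ceff = max(c, p[I_CA_FLOOR])
    return p[I_NU_NCLX] * (camit / ceff) * np.exp(p[I_P2] * p[I_DPSI_M])


@njit(cache=True)
def nernst_mit_kernel(camit, c, p):
    """Mitochondrial calcium Nernst potential, mV."""
    ceff = max(c, p[I_CA_FLOOR])
    return p[I_RT_OVER_2F] * np.log(camit / ceff)


@njit(cache=True)
def flux_mit_leak_kernel(c, camit, p):
    """Ohmic non-specific mitochondrial leak."""
    return p[I_NU_MIT_LEAK] * (nernst_mit_kernel(camit, c, p) - p[I_DPSI_M])


# ---------------------------------------------------------------------------
# ER fluxes
# ---------------------------------------------------------------------------
@njit(cache=True)
def flux_serca_kernel(c, cer, p):
    """SERCA pump: two-state King-Altman cycle, net <= 0 above the
    thermodynamic concentration ratio (pumping cytosol -> ER)."""
    k2 = p[I_K2_SERCA]
    km2 = p[I_KM2_SERCA]
    k4 = p[I_K4_SERCA]
    km4 = p[I_KM4_SERCA]
    K1 = p[I_K1_SERCA]
    K3 = p[I_K3_SERCA]
    num = k2 * k4 * c * c - K1 * K1 * K3 * K3 * km2 * km4 * cer * cer
    den = (cer * cer * c * c * K3 * K3 * (k2 + km2)
           + c * c * (k4 + k2)
           + cer * cer * K1 * K1 * K3 * K3 * (km2 + km4)
           + K1 * K1 * (k4 + km4))
    return -p[I_SERCA_SCALE] * 2.0 * p[I_SERCA_TOT] * num / den


@njit(cache=True)
def ip3r_rates_kernel(c, ip3, p):
    """Effective transition rates of the reduced IP3R four-state scheme.

    IP3 binding is at rapid equilibrium (k1 = b1/(a1*IP3) on
    inactivation-empty states, k3 = b3/(a3*IP3) on inactivation-occupied
    ones); Ca activation proceeds from the IP3-bound fraction only.
    Returns (act_on, act_off, inact_on, inact_off, a2c, b2, act_on_i, b5):
    rest<->active, rest<->inactivated, active<->both, inactivated<->both.
    """
    ip3e = max(ip3, 1e-12)
    k1 = p[I_B1] / (p[I_A1] * ip3e)
    k3 = p[I_B3] / (p[I_A3] * ip3e)
    act_on = p[I_A5] * c / (1.0 + k1)                       # X00 -> X10
    act_off = p[I_B5]                                       # X10 -> X00
    inact_on = c * (p[I_A2] + p[I_A4] * k1) / (1.0 + k1)    # X00 -> X01
    inact_off = (p[I_B2] + p[I_B4] * k3) / (1.0 + k3)       # X01 -> X00
    a2c = p[I_A2] * c                                       # X10 -> X11
    b2 = p[I_B2]                                            # X11 -> X10
    act_on_i = p[I_A5] * c / (1.0 + k3)                     # X01 -> X11
    b5 = p[I_B5]                                            # X11 -> X01
    return act_on, act_off, inact_on, inact_off, a2c, b2, act_on_i, b5


@njit(cache=True)
def ip3r_rhs_kernel(X00, X01, X10, c, ip3, p):
    """d/dt of the three retained IP3R states (X11 by conservation)."""
    act_on, act_off, inact_on, inact_off, a2c, b2, act_on_i, b5 = \
        ip3r_rates_kernel(c, ip3, p)
    X11 = 1.0 - X00 - X01 - X10
    dX00 = act_off * X10 + inact_off * X01 - (act_on + inact_on) * X00
    dX01 = inact_on * X00 + b5 * X11 - (inact_off + act_on_i) * X01
    dX10 = act_on * X00 + b2 * X11 - (act_off + a2c) * X10
    return dX00, dX01, dX10


@njit(cache=True)
def ipr_open_prob_kernel(X10):
    """Channel open probability: >= 3 of 4 subunits in the active state."""
    return X10 ** 4 + 4.0 * X10 ** 3 * (1.0 - X10)


@njit(cache=True)
def flux_ipr_kernel(X10, c, cer, p):
    return p[I_NU_IPR] * ipr_open_prob_kernel(X10) * (cer - c)


@njit(cache=True)
def ryr_rhs_kernel(R10, R11, R01, c, p):
    """d/dt of the three retained RyR states (R00 by conservation).

    Two independent site classes: activation binds Ca^2 at Kr1*c^2 / unbinds
    at Kmr1; inactivation binds at Kr2*c / unbinds at Kmr2.
    """
    a = p[I_KR1] * c * c    # activation on
    b = p[I_KMR1]           # activation off
    g = p[I_KR2] * c        # inactivation on
    d = p[I_KMR2]           # inactivation off
    R00 = 1.0 - R10 - R11 - R01
    dR10 = a * R00 + d * R11 - (b + g) * R10
    dR11 = g * R10 + a * R01 - (b + d) * R11
    dR01 = g * R00 + b * R11 - (d + a) * R01
    return dR10, dR11, dR01


@njit(cache=True)
def flux_ryr_kernel(R10, c, cer, p):
    return p[I_NU_RYR] * R10 * R10 * (cer - c)


# ---------------------------------------------------------------------------
# plasma membrane fluxes
# ---------------------------------------------------------------------------
@njit(cache=True)
def ncx_shape_kernel(c, p):
    """NCX concentration/voltage dependence with unit prefactor.

    Negative at and above resting calcium (net extrusion); the calibrated
    prefactor Q_ncx multiplies this shape.
    """
    ceff = max(c, p[I_CA_FLOOR])
    rtf = 2.0 * p[I_RT_OVER_2F]     # RT/F, mV
    phi = p[I_PHI_ECS]
    phiF = np.exp(p[I_ETA_NCX] * phi / rtf)
    phiR = np.exp((p[I_ETA_NCX] - 1.0) * phi / rtf)
    na_c3 = p[I_NA_CYT] ** 3
    na_e3 = p[I_NA_ECS] ** 3
    num = na_c3 * p[I_CA_ECS] * phiF - na_e3 * ceff * phiR
    den = 1.0 + p[I_D_NCX] * (ceff * na_e3 + p[I_CA_ECS] * na_c3)
    act = 1.0 / (1.0 + (p[I_K_NCX1] / ceff) ** 2)
    return num / den * act


@njit(cache=True)
def flux_ncx_kernel(c, p):
    return p[I_Q_NCX] * ncx_shape_kernel(c, p)


@njit(cache=True)
def nernst_ecs_kernel(c, p):
    ceff = max(c, p[I_CA_FLOOR])
    return p[I_RT_OVER_2F] * np.log(p[I_CA_ECS] / ceff)


@njit(cache=True)
def flux_vocc_kernel(c, p):
    phi = p[I_PHI_ECS]
    dbar = 1.0 / (1.0 + np.exp(-phi / 8.3))
    fbar = 1.0 / (1.0 + np.exp((phi + 42.0) / 9.1))
    return p[I_Q_VOCC] * dbar * fbar * (nernst_ecs_kernel(c, p) - phi)


@njit(cache=True)
def flux_ecs_leak_kernel(c, p):
    return -p[I_G_LEAK_ECS] * (p[I_PHI_ECS] - nernst_ecs_kernel(c, p))


@njit(cache=True)
def flux_pmca_kernel(c, p):
    return -p[I_Q_PMCA] * c / (c + p[I_K_PMCA])


# ---------------------------------------------------------------------------
# assembled flux table and full right-hand side
# ---------------------------------------------------------------------------
@njit(cache=True)
def flux_kernel(y, p):
    """All component fluxes (uM/s, cytosol-referenced, unrescaled)."""
    c = y[S_CA_CYT]
    cer = y[S_CA_ER]
    camit = p[I_CA_MIT]
    out = np.empty(N_FLUX)
    out[F_MCU] = flux_mcu_kernel(c, p)
    out[F_NCLX] = flux_nclx_kernel(c, camit, p)
    out[F_MIT_LEAK] = flux_mit_leak_kernel(c, camit, p)
    out[F_SERCA] = flux_serca_kernel(c, cer, p)
    out[F_IPR] = flux_ipr_kernel(y[S_X10], c, cer, p)
    out[F_RYR] = flux_ryr_kernel(y[S_R10], c, cer, p)
    out[F_NCX] = flux_ncx_kernel(c, p)
    out[F_VOCC] = flux_vocc_kernel(c, p)
    out[F_PMCA] = flux_pmca_kernel(c, p)
    out[F_ECS_LEAK] = flux_ecs_leak_kernel(c, p)
    dMp, dAMp, dAM = myosin_rhs_kernel(y[S_MP], y[S_AMP], y[S_AM], c, p)
    out[F_CYT_CYT] = -p[I_MYOSIN_CA_STOICH] * p[I_MYO_TOT] * (dMp + dAMp)
    return out


@njit(cache=True)
def rhs_kernel(t, y, p):
    """Time derivative of the 15-dimensional state vector.

    Compartment aggregates are rescaled by (alpha_er, alpha_mit, alpha_pm)
    wherever they appear, so mass bookkeeping stays exact under rescaling.
    """
    c = y[S_CA_CYT]
    cer = y[S_CA_ER]
    fl = flux_kernel(y, p)
    J_mit = p[I_ALPHA_MIT] * (fl[F_MCU] + fl[F_NCLX] + fl[F_MIT_LEAK])
    J_er = p[I_ALPHA_ER] * (fl[F_SERCA] + fl[F_IPR] + fl[F_RYR])
    J_ecs = p[I_ALPHA_PM] * (fl[F_NCX] + fl[F_VOCC] + fl[F_PMCA]
                             + fl[F_ECS_LEAK])
    dy = np.empty(N_STATE)
    dy[S_CA_CYT] = (J_er + J_mit + J_ecs + fl[F_CYT_CYT]) / b_cyt_kernel(c, p)
    dy[S_CA_ER] = -p[I_R_ERCYT] * J_er / b_er_kernel(cer, p)
    dip3, dpip2 = ip3_pip2_rhs_kernel(y[S_IP3], y[S_PIP2], c, p)
    dy[S_IP3] = dip3
    dy[S_PIP2] = dpip2
    dMp, dAMp, dAM = myosin_rhs_kernel(y[S_MP], y[S_AMP], y[S_AM], c, p)
    dy[S_MP] = dMp
    dy[S_AMP] = dAMp
    dy[S_AM] = dAM
    dX00, dX01, dX10 = ip3r_rhs_kernel(y[S_X00], y[S_X01], y[S_X10],
                                       c, y[S_IP3], p)
    dy[S_X00] = dX00
    dy[S_X01] = dX01
    dy[S_X10] = dX10
    dR10, dR11, dR01 = ryr_rhs_kernel(y[S_R10], y[S_R11], y[S_R01], c, p)
    dy[S_R10] = dR10
    dy[S_R11] = dR11
    dy[S_R01] = dR01
    dy[S_SINK] = -J_ecs
    dy[S_SOURCE] = J_mit
    return dy


@njit(cache=True)
def flux_table_kernel(Y, p):
    """Flux table for an (n, 15) array of states -> (n, 11)."""
    n = Y.shape[0]
    out = np.empty((n, N_FLUX))
    for i in range(n):
        out[i, :] = flux_kernel(Y[i, :], p)
    return out
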