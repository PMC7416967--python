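"""Unit tests for the flux laws, buffering factors and gating kinetics.

Frozen expected values were computed independently (hand evaluation of the
rate laws, or small linear solves) before being asserted here.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsmcal import (CellState, default_parameters, flux_breakdown,
                    solve_gate_steady, solve_ip3_steady, solve_myosin_steady)
from vsmcal import model as M

P0 = default_parameters()


def _random_state(rng):
    fr = rng.dirichlet(np.ones(4))
    x = rng.dirichlet(np.ones(4))
    r = rng.dirichlet(np.ones(4))
    return CellState(
        Ca_cyt=float(rng.uniform(0.01, 2.0)),
        Ca_er=float(rng.uniform(10.0, 1000.0)),
        IP3=float(rng.uniform(1e-4, 0.1)),
        PIP2=float(rng.uniform(1.0, 118.0)),
        Mp=fr[0], AMp=fr[1], AM=fr[2],
        X00=x[0], X01=x[1], X10=x[2],
        R10=r[0], R11=r[1], R01=r[2],
    )


class TestBuffering:
    @pytest.mark.parametrize("c, expected", [
        (0.1, 101.2457),                        # hand evaluation
        (0.0, 1 + 30 / 0.26 + 30 / 0.53),       # = 172.988
    ])
    def test_cytosolic_factor_values(self, c, expected):
        assert M.buffering_factor_cyt(c, P0) == pytest.approx(expected, rel=1e-4)

    def test_saturation_limits(self):
        assert M.buffering_factor_cyt(1e6, P0) == pytest.approx(1.0, abs=1e-3)
        assert M.buffering_factor_er(1e7, P0) == pytest.approx(1.0, abs=1e-3)

    def test_factors_at_least_one_and_decreasing(self):
        grid = np.logspace(-4, 4, 200)
        bc = [M.buffering_factor_cyt(c, P0) for c in grid]
        be = [M.buffering_factor_er(c, P0) for c in grid]
        assert min(bc) >= 1.0 and min(be) >= 1.0
        assert np.all(np.diff(bc) < 0) and np.all(np.diff(be) < 0)

    @pytest.mark.parametrize("c, expected", [
        (0.0, 0.0),
        (0.1, 0.1 * (1 + 30 / 0.36 + 30 / 0.63)),   # = 13.1952
    ])
    def test_total_calcium_values(self, c, expected):
        assert M.total_cyt_calcium(c, P0) == pytest.approx(expected, rel=1e-9)

    def test_total_derivative_is_buffering_factor(self):
        c, h = 0.1, 1e-6
        num = (M.total_cyt_calcium(c + h, P0)
               - M.total_cyt_calcium(c - h, P0)) / (2 * h)
        assert num == pytest.approx(M.buffering_factor_cyt(c, P0), rel=1e-6)

    @pytest.mark.parametrize("c, expected", [
        (500.0, 3.33168),
        (0.0, 1 + 7200 / 2000 + 720 / 10),          # = 76.6
    ])
    def test_er_factor_values(self, c, expected):
        assert M.buffering_factor_er(c, P0) == pytest.approx(expected, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            M.buffering_factor_cyt(-0.1, P0)
        with pytest.raises(ValueError):
            M.buffering_factor_er(-1.0, P0)


class TestMyosin:
    def test_fixed_point_matches_independent_solve(self):
        # frozen from a 4x4 stationary solve with K1 = K6 = 0.017 /s
        fp = solve_myosin_steady(0.1, P0)
        assert fp["Mp"] == pytest.approx(0.018699, rel=1e-4)
        assert fp["AMp"] == pytest.approx(0.014183, rel=1e-4)
        assert fp["AM"] == pytest.approx(0.060612, rel=1e-4)
        state = CellState(0.1, 500, 0.01, 118, fp["Mp"], fp["AMp"], fp["AM"],
                          0.7, 0.2, 0.005, 0.003, 1e-5, 0.002)
        d = M.myosin_rhs(state, 0.1, P0)
        assert max(abs(v) for v in d) < 1e-12

    def test_relaxed_state_is_absorbing_at_zero_calcium(self):
        state = CellState(0.0, 500, 0.01, 118, 0.0, 0.0, 0.0,
                          0.7, 0.2, 0.005, 0.003, 1e-5, 0.002)
        assert M.myosin_rhs(state, 0.0, P0) == (0.0, 0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_four_state_sum_conserved(self, seed):
        s = _random_state(np.random.default_rng(seed))
        dMp, dAMp, dAM = M.myosin_rhs(s, s.Ca_cyt, P0)
        # independent dM/dt from the eliminated state's own balance
        k1 = P0.gamma_cross * s.Ca_cyt ** 3
        dM = P0.K2 * s.Mp + P0.K7 * s.AM - k1 * s.M
        assert abs(dM + dMp + dAMp + dAM) < 1e-12

    def test_tension_fraction(self):
        fp = solve_myosin_steady(0.1, P0)
        s = CellState(0.1, 500, 0.01, 118, fp["Mp"], fp["AMp"], fp["AM"],
                      0.7, 0.2, 0.005, 0.003, 1e-5, 0.002)
        assert M.tension_fraction(s) == pytest.approx(0.074795, rel=1e-3)
        assert M.tension_fraction(s.replace(AMp=0.0, AM=0.0)) == 0.0
        assert M.tension_fraction(s.replace(Mp=0.0, AMp=0.4, AM=0.6)) == 1.0

    def test_calcium_flux_stoichiometry(self):
        coupled = P0.replace(myosin_ca_stoich=1.0)
        # net phosphorylation of 0.01/s with [Myo] = 10 uM removes 0.1 uM/s
        assert M.myosin_calcium_flux((0.01, 0.0, 0.0), coupled) == \
            pytest.approx(-0.1)
        assert M.myosin_calcium_flux((0.0, 0.02, 0.0), coupled) < 0
        # default configuration: myosin is a readout, no calcium feedback
        assert M.myosin_calcium_flux((0.01, 0.0, 0.0), P0) == 0.0


class TestIP3:
    def test_rate_and_fixed_point(self):
        ip3, pip2 = solve_ip3_steady(P0)
        assert ip3 == pytest.approx(7.3679e-3, rel=1e-4)
        d = M.ip3_pip2_rhs(ip3, pip2, 0.1, P0)
        assert max(abs(v) for v in d) < 1e-12

    def test_zero_calcium_pure_degradation(self):
        dip3, _ = M.ip3_pip2_rhs(0.5, 100.0, 0.0, P0)
        assert dip3 == pytest.approx(-P0.kdeg_IP3 * 0.5)

    def test_no_plc_gain_means_no_ip3(self):
        p = P0.replace(eta_IP3=1e-30)
        ip3, pip2 = solve_ip3_steady(p)
        assert ip3 == pytest.approx(0.0, abs=1e-25)
        assert pip2 == pytest.approx(P0.PIP2_tot, rel=1e-9)


class TestMitochondrialFluxes:
    def test_mcu_values_and_sign(self):
        assert M.flux_mcu(0.0, P0) == 0.0
        assert M.flux_mcu(0.1, P0) == pytest.approx(-1.0697e-3, rel=1e-3)
        grid = np.linspace(0.01, 5.0, 100)
        j = np.array([M.flux_mcu(c, P0) for c in grid])
        assert np.all(j <= 0)
        assert abs(M.flux_mcu(1.0, P0)) > abs(M.flux_mcu(0.1, P0))

    def test_nclx_values(self):
        assert M.flux_nclx(0.1, 0.1, P0) == pytest.approx(
            0.13 * np.exp(0.0161 * 140), rel=1e-9)    # = 1.23835
        assert M.flux_nclx(0.1, 0.0, P0) == 0.0
        assert M.flux_nclx(0.2, 0.5, P0) == pytest.approx(
            2 * M.flux_nclx(0.2, 0.25, P0), rel=1e-12)
        with pytest.raises(ValueError):
            M.flux_nclx(0.0, 0.1, P0)

    def test_nernst(self):
        assert M.nernst_mit(0.1, 0.1, P0) == 0.0
        assert M.nernst_mit(0.25, 0.1, P0) == pytest.approx(12.2386, rel=1e-3)
        assert M.nernst_mit(0.3, 0.07, P0) == pytest.approx(
            -M.nernst_mit(0.07, 0.3, P0), rel=1e-12)
        with pytest.raises(ValueError):
            M.nernst_mit(0.0, 0.1, P0)

    def test_leak_zero_iff_nernst_equals_potential(self, params):
        e_target = params.dPsi_m
        camit = 0.1 * np.exp(e_target / params.RT_over_2F)
        assert M.flux_mit_leak(camit, 0.1, params) == pytest.approx(0.0, abs=1e-12)
        assert M.flux_mit_leak(0.1, 0.1, params) == pytest.approx(
            -params.nu_mit_leak * 140.0, rel=1e-12)


class TestERFluxes:
    def test_serca_zero_flux_ratio(self):
        ratio = M.serca_zero_flux_ratio(P0)
        assert ratio == pytest.approx(5.4166e-7, rel=1e-4)
        cer = 500.0
        assert M.flux_serca(ratio * cer, cer, P0) == pytest.approx(0.0, abs=1e-10)

    def test_serca_signs(self):
        assert M.flux_serca(0.1, 500.0, P0) < 0      # pumping cytosol -> ER
        assert M.flux_serca(0.0, 500.0, P0) >= 0     # reverse mode only

    def test_serca_balances_release_after_calibration(self, params, baseline):
        j = flux_breakdown(baseline, params)
        assert j.J_serca == pytest.approx(-(j.J_ipr + j.J_ryr), abs=1e-12)
        assert j.J_serca == pytest.approx(-0.2242, rel=5e-3)

    def test_ipr_flux_values(self):
        assert M.ipr_open_probability(1.0) == 1.0
        assert M.flux_ipr(0.004820, 0.1, 500.0, P0) == pytest.approx(
            0.2231, rel=1e-3)
        assert M.flux_ipr(0.3, 0.1, 0.1, P0) == 0.0

    def test_ryr_flux_values(self):
        assert M.flux_ryr(0.003272, 0.1, 500.0, P0) == pytest.approx(
            1.0704e-3, rel=1e-3)
        assert M.flux_ryr(0.0, 0.1, 500.0, P0) == 0.0
        assert M.flux_ryr(0.3, 0.1, 0.1, P0) == 0.0


class TestGating:
    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_probability_conservation(self, seed):
        """d/dt of the eliminated state, written from its own inflow/outflow
        balance, cancels the sum of the retained derivatives."""
        s = _random_state(np.random.default_rng(seed))
        c = s.Ca_cyt
        dx = M.ip3r_rhs(s.X00, s.X01, s.X10, c, s.IP3, P0)
        k3 = P0.b3 / (P0.a3 * s.IP3)
        dX11 = (P0.a2 * c * s.X10 + P0.a5 * c / (1 + k3) * s.X01
                - (P0.b2 + P0.b5) * s.X11)
        assert abs(sum(dx) + dX11) < 1e-12
        dr = M.ryr_rhs(s.R10, s.R11, s.R01, c, P0)
        dR00 = (P0.Kmr1 * s.R10 + P0.Kmr2 * s.R01
                - (P0.Kr1 * c ** 2 + P0.Kr2 * c) * s.R00)
        assert abs(sum(dr) + dR00) < 1e-12

    def test_rhs_zero_at_linear_solve_fixed_point(self):
        ip3, _ = solve_ip3_steady(P0)
        g = solve_gate_steady(0.1, ip3, P0)
        dx = M.ip3r_rhs(g["X00"], g["X01"], g["X10"], 0.1, ip3, P0)
        dr = M.ryr_rhs(g["R10"], g["R11"], g["R01"], 0.1, P0)
        assert max(abs(v) for v in dx) < 1e-10
        assert max(abs(v) for v in dr) < 1e-10

    def test_ip3r_fixed_point_attracting(self):
        ip3, _ = solve_ip3_steady(P0)
        h = 1e-7
        A = np.zeros((3, 3))
        g = solve_gate_steady(0.1, ip3, P0)
        x0 = np.array([g["X00"], g["X01"], g["X10"]])
        for j in range(3):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            A[:, j] = (np.array(M.ip3r_rhs(*xp, 0.1, ip3, P0))
                       - np.array(M.ip3r_rhs(*xm, 0.1, ip3, P0))) / (2 * h)
        assert np.max(np.linalg.eigvals(A).real) < 0

    def test_ryr_detailed_balance(self):
        g = solve_gate_steady(0.1, 0.007368, P0)
        c = 0.1
        assert g["R10"] / g["R00"] == pytest.approx(
            P0.Kr1 * c ** 2 / P0.Kmr1, rel=1e-10)
        assert g["R01"] / g["R00"] == pytest.approx(
            P0.Kr2 * c / P0.Kmr2, rel=1e-10)
        assert g["R11"] / g["R10"] == pytest.approx(
            P0.Kr2 * c / P0.Kmr2, rel=1e-10)

    def test_ip3r_requires_positive_ip3(self):
        with pytest.raises(ValueError):
            M.ip3r_rhs(0.7, 0.2, 0.05, 0.1, 0.0, P0)


class TestPlasmaMembrane:
    def test_vocc_baseline_value(self):
        assert M.flux_vocc(0.1, P0) == pytest.approx(0.021253, rel=1e-3)

    def test_vocc_zero_at_nernst_potential(self):
        e = M.nernst_ecs(0.1, P0)
        assert M.flux_vocc(0.1, P0.replace(phi_ecs=e)) == pytest.approx(
            0.0, abs=1e-12)

    def test_leak_and_pmca_values(self):
        leak, pmca = M.flux_pm_leak_pmca(0.1, P0)
        assert leak == pytest.approx(5.4157e-3, rel=1e-3)
        assert pmca == pytest.approx(-0.016, rel=1e-9)
        _, pmca0 = M.flux_pm_leak_pmca(1e-12, P0)
        assert pmca0 == pytest.approx(0.0, abs=1e-10)

    def test_ncx_extrusion_and_vanishing_activation(self, params):
        j = M.flux_ncx(0.1, params)
        assert j == pytest.approx(-0.010678, rel=1e-3)
        assert abs(M.flux_ncx(1e-4, params)) < abs(j) * 1e-3
        grid = np.linspace(0.1, 0.3, 30)
        vals = np.array([M.flux_ncx(c, params) for c in grid])
        assert np.all(np.diff(-vals) > 0)   # |J| increasing near baseline


class TestAssembled:
    def test_flux_aggregates_are_component_sums(self, params, rng):
        for _ in range(20):
            s = _random_state(rng)
            j = flux_breakdown(s, params)
            assert j.J_mit_to_cyt == pytest.approx(
                j.J_mcu + j.J_nclx + j.J_mit_leak, rel=1e-12, abs=1e-15)
            assert j.J_er_to_cyt == pytest.approx(
                j.J_serca + j.J_ipr + j.J_ryr, rel=1e-12, abs=1e-15)
            assert j.J_ecs_to_cyt == pytest.approx(
                j.J_ecs_leak + j.J_pmca + j.J_ncx + j.J_vocc,
                rel=1e-12, abs=1e-15)

    def test_full_rhs_vanishes_at_calibrated_baseline(self, params, baseline):
        dy = M.full_rhs(0.0, baseline, params)
        assert np.max(np.abs(dy)) < 1e-9

    def test_zero_mit_rescaling_silences_source(self, params, baseline):
        p = params.replace(alpha_mit=1e-12, Ca_mit=0.25)
        dy = M.full_rhs(0.0, baseline, p)
        i_source = len(dy) - 1
        assert abs(dy[i_source]) < 1e-9

    def test_atp_rate(self, params):
        assert M.atp_rate(0.0, params) == 0.0
        p2 = params.replace(protons_per_Ca=2.0, protons_per_ATP=3.0)
        assert M.atp_rate(3.0, p2) == pytest.approx(2.0)
        assert np.sign(M.atp_rate(-1.5, params)) == -1.0
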