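"""Calibration of the free constants and the resting fixed point."""

import numpy as np
import pytest

from vsmcal import (CellState, calibrate, default_parameters,
                    full_rhs, simulate)
from vsmcal.calibration import (build_baseline_state, calibrate_mit_leak,
                                calibrate_pm_and_er)


class TestLeakCalibration:
    def test_value_and_nulling(self, params):
        # (J_nclx + J_mcu)/dPsi_m = (1.23835 - 0.00107)/140
        assert params.nu_mit_leak == pytest.approx(8.8377e-3, rel=1e-4)
        from vsmcal.model import flux_mcu, flux_mit_leak, flux_nclx
        total = (flux_mcu(0.1, params) + flux_nclx(0.1, 0.1, params)
                 + flux_mit_leak(0.1, 0.1, params))
        assert abs(total) < 1e-12

    def test_mcu_dominating_nclx_is_rejected(self):
        bad = default_parameters(nu_nclx=1e-12, nu_mcu=1.0)
        with pytest.raises(ValueError):
            calibrate_mit_leak(bad)


class TestPlasmaMembraneAndER:
    def test_ncx_carries_the_pm_imbalance(self, params, baseline):
        from vsmcal import flux_breakdown
        j = flux_breakdown(baseline, params)
        assert j.J_ncx == pytest.approx(-0.010678, rel=1e-3)
        assert abs(j.J_ecs_to_cyt) < 1e-12
        assert abs(j.J_er_to_cyt) < 1e-12
        assert abs(j.J_mit_to_cyt) < 1e-12

    def test_calibrated_prefactor_matches_printed_constant(self, params):
        """The dimensional reading k_ncx2/(2 F V_cyt) of the literature
        prefactor reproduces the calibrated Q_ncx to a fraction of a percent
        (uA / (C/mol * pL) -> uM/s)."""
        printed = params.k_ncx2 * 1e-6 / (2 * params.F * params.V_cyt * 1e-12)
        printed_uM_per_s = printed * 1e6
        assert params.Q_ncx == pytest.approx(printed_uM_per_s, rel=5e-3)

    def test_ncx_must_extrude(self):
        # VOCC influx removed -> PM balance needs NCX influx -> rejected
        bad = default_parameters(Q_vocc=1e-12)
        with pytest.raises(ValueError):
            calibrate_pm_and_er(bad)


class TestBaseline:
    def test_residual_below_tolerance(self, calres):
        assert calres.residual_norm < 1e-9

    def test_accumulators_start_at_zero(self, baseline):
        assert baseline.Ca_sink == 0.0 and baseline.Ca_source == 0.0

    def test_enforced_concentrations(self, baseline):
        assert baseline.Ca_cyt == 0.1 and baseline.Ca_er == 500.0

    def test_myosin_components(self, baseline):
        assert baseline.Mp == pytest.approx(0.018699, rel=1e-4)
        assert baseline.AMp == pytest.approx(0.014183, rel=1e-4)
        assert baseline.AM == pytest.approx(0.060612, rel=1e-4)

    def test_uncalibrated_parameters_fail_assembly(self):
        with pytest.raises(ValueError):
            build_baseline_state(default_parameters())


class TestInvariances:
    def test_idempotence(self, params, calres):
        p2, r2 = calibrate(params)
        assert r2.nu_mit_leak == pytest.approx(calres.nu_mit_leak, rel=1e-12)
        assert r2.Q_ncx == pytest.approx(calres.Q_ncx, rel=1e-12)
        assert r2.serca_scale == pytest.approx(calres.serca_scale, rel=1e-12)

    @pytest.mark.parametrize("alphas", [
        (0.1, 1.0, 1.0), (1.0, 10.0, 1.0), (3.0, 0.2, 7.0)])
    def test_rescaling_preserves_fixed_point(self, params, baseline, alphas):
        ae, am, ap = alphas
        p = params.replace(alpha_er=ae, alpha_mit=am, alpha_pm=ap)
        dy = full_rhs(0.0, baseline, p)
        assert np.max(np.abs(dy)) < 1e-9

    def test_baseline_locally_stable(self, params, baseline):
        perturbed = baseline.replace(Ca_cyt=baseline.Ca_cyt * 1.01)
        traj = simulate(perturbed, params, 300.0, output_dt=1.0)
        final = traj.Ca_cyt[-1]
        assert abs(final - baseline.Ca_cyt) < 1e-3 * baseline.Ca_cyt


class TestGateSteadyStates:
    def test_probabilities_normalized(self, params):
        from vsmcal import solve_gate_steady, solve_ip3_steady
        ip3, _ = solve_ip3_steady(params)
        g = solve_gate_steady(0.1, ip3, params)
        assert g["X00"] + g["X01"] + g["X10"] + g["X11"] == pytest.approx(1.0)
        assert g["R00"] + g["R10"] + g["R01"] + g["R11"] == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in g.values())

    def test_rejects_nonpositive_inputs(self, params):
        from vsmcal import solve_gate_steady
        with pytest.raises(ValueError):
            solve_gate_steady(0.1, 0.0, params)
        with pytest.raises(ValueError):
            solve_gate_steady(-1.0, 0.01, params)
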