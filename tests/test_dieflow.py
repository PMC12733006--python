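"""Die-flow solver: analytic oracles, conservation, mesh study, RMSE."""

from dataclasses import replace

import numpy as np
import pytest

import spc_rheoflow as sr
from spc_rheoflow import dieflow, synthetic


@pytest.fixture(scope="module")
def newtonian_case():
    return sr.make_newtonian_die_case(1000.0, 6.36e-6)


@pytest.fixture(scope="module")
def newtonian_field(newtonian_case):
    return dieflow.solve(newtonian_case, ny=32, nz=100)


class TestNewtonianOracle:
    def test_pressure_drop_matches_duct_series_within_1pct(
            self, newtonian_case, newtonian_field):
        assert newtonian_field.delta_p == pytest.approx(
            newtonian_case.reference_dp, rel=0.01)

    def test_pressure_drop_linear_in_viscosity(self, newtonian_field):
        case2 = sr.make_newtonian_die_case(2000.0, 6.36e-6)
        f2 = dieflow.solve(case2, ny=32, nz=100)
        assert f2.delta_p == pytest.approx(2 * newtonian_field.delta_p,
                                           rel=1e-6)

    def test_isothermal_walls_leave_temperature_unchanged(
            self, newtonian_field):
        # walls at inlet temperature, dissipation off: outlet T = inlet T
        np.testing.assert_allclose(newtonian_field.bulk_T, 20.0,
                                   rtol=0, atol=1e-9)

    def test_pressure_monotone_decreasing(self, newtonian_field):
        assert np.all(np.diff(newtonian_field.pressure) < 0)


class TestPowerLawOracle:
    def test_slab_profile_matches_closed_form(self):
        # width >> height: plane-channel power-law profile
        n = 0.4
        mat = sr.MaterialProperties(rho=1000.0, cp_poly=[4000.0],
                                    k_poly=[0.5])
        model = sr.PowerLawTemperatureModel(K0=1000.0, Ea_k=0.0, n0=n,
                                            alpha_n=0.0, T_ref=293.15)
        case = dieflow.DieCase(width=1.0, height=0.01, length=0.5,
                               zone_wall_T=(20.0, 20.0, 20.0), inlet_T=20.0,
                               inlet_Q=1e-4, material=mat, model=model,
                               include_dissipation=False)
        f = dieflow.solve(case, ny=64, nz=10)
        h = case.height / 2
        u_mean = case.inlet_Q / (case.width * case.height)
        exact = u_mean * (2 * n + 1) / (n + 1) * (1 - (f.y / h) ** ((n + 1) / n))
        assert np.max(np.abs(f.U[0] - exact)) / exact[0] < 0.01


class TestConservation:
    def test_mass_conserved_along_die(self, spc0_material, spc0_ptt):
        case = dieflow.DieCase(material=spc0_material, model=spc0_ptt,
                               inlet_Q=1e-6)
        f = dieflow.solve(case, ny=24, nz=100)
        rates = [f.flow_rate(i) for i in range(0, 101, 10)]
        np.testing.assert_allclose(rates, case.inlet_Q, rtol=1e-3)

    def test_global_energy_balance(self):
        # Newtonian with cooling walls and dissipation: enthalpy deficit
        # equals wall loss plus dissipation within 1%
        case = sr.make_newtonian_die_case(1000.0, 1e-6)
        case = replace(case, zone_wall_T=(100.0, 50.0, 10.0), inlet_T=100.0,
                       include_dissipation=True)
        f = dieflow.solve(case, ny=48, nz=400)

        def enthalpy_flux(i):
            T, u = f.T[i], f.U[i]
            cpbar = np.array([np.mean(case.material.cp(np.linspace(0.0, t, 20)))
                              for t in T])
            return 2 * case.width * np.trapezoid(
                case.material.rho * cpbar * u * T, f.y)

        lhs = enthalpy_flux(len(f.z) - 1) - enthalpy_flux(0)
        rhs = f.wall_heat_W + f.dissipation_W
        assert lhs == pytest.approx(rhs, rel=0.01)

    def test_wall_shear_sign_fixed_by_flow_direction(self, newtonian_field):
        # du/dy < 0 on the upper half-gap for forward flow
        assert np.all(np.diff(newtonian_field.U[0]) < 0)


class TestModelConsistency:
    def test_model_a_matches_model_b_for_powerlaw_like_ptt(
            self, spc0_material):
        # premise: PTT mimicking a power-law flow curve over the
        # pressure-dominant shear-rate window [gd_wall/5, gd_wall]
        ptt = sr.PTTParams(eta0_ref=5112.0, lambda_ref=1.0, epsilon=0.05)
        caseB = dieflow.DieCase(material=spc0_material, model=ptt,
                                inlet_Q=1e-6,
                                zone_wall_T=(100.0, 100.0, 100.0),
                                inlet_T=100.0)
        fB = dieflow.solve(caseB, ny=32, nz=50)
        tau_w = fB.dpdz[0] * synthetic.duct_shape_factor(0.02, 0.01) * 0.005
        gd_w = float(sr.constitutive.ptt_shear_rate_from_stress(ptt, tau_w))
        gds = np.logspace(np.log10(gd_w / 5), np.log10(gd_w), 30)
        taus = np.array([sr.ptt_steady_shear(ptt, g)[0] for g in gds])
        nfit, logK = np.polyfit(np.log(gds), np.log(taus), 1)
        modelA = sr.PowerLawTemperatureModel(K0=float(np.exp(logK)), Ea_k=0.0,
                                             n0=float(nfit), alpha_n=0.0,
                                             T_ref=373.15)
        fA = dieflow.solve(replace(caseB, model=modelA), ny=32, nz=50)
        assert fA.delta_p == pytest.approx(fB.delta_p, rel=0.02)


class TestMeshIndependence:
    def test_refinement_changes_pressure_below_2pct(self, newtonian_case):
        study = dieflow.mesh_independence(newtonian_case, [16, 32], nz=60)
        assert study["changes"][0] < 0.02
        assert study["converged"]

    def test_change_decreases_monotonically_with_refinement(
            self, newtonian_case):
        study = dieflow.mesh_independence(newtonian_case, [8, 16, 32, 64],
                                          nz=60)
        assert study["changes"] == sorted(study["changes"], reverse=True)

    def test_identical_resolutions_rejected(self, newtonian_case):
        with pytest.raises(ValueError):
            dieflow.mesh_independence(newtonian_case, [16, 16])

    def test_coarse_grid_flagged_against_criterion(self, spc0_material):
        # a deliberately coarse grid on a strongly shear-thinning melt
        # violates the 2% criterion; a fine pair satisfies it
        model = sr.PowerLawTemperatureModel(K0=4071.0, Ea_k=0.0, n0=0.138,
                                            alpha_n=0.0, T_ref=373.15)
        case = dieflow.DieCase(material=spc0_material, model=model,
                               inlet_Q=6.36e-6)
        coarse = dieflow.mesh_independence(case, [8, 64], nz=40)
        fine = dieflow.mesh_independence(case, [32, 64], nz=40)
        assert fine["changes"][0] < 0.02
        assert coarse["changes"][0] > fine["changes"][0]


class TestTemperatureSummary:
    def test_isothermal_case_zone_means_equal_inlet(self, newtonian_field):
        s = dieflow.temperature_summary(newtonian_field)
        for key in ("zone1", "zone2", "zone3", "outlet"):
            assert s[key] == pytest.approx(20.0, abs=1e-9)

    def test_zone_means_stable_under_refinement(self, spc0_material,
                                                spc0_ptt):
        case = dieflow.DieCase(material=spc0_material, model=spc0_ptt,
                               inlet_Q=2.4e-6)
        s1 = dieflow.temperature_summary(dieflow.solve(case, ny=24, nz=200))
        s2 = dieflow.temperature_summary(dieflow.solve(case, ny=48, nz=400))
        for key in ("zone1", "zone2", "zone3", "outlet"):
            assert s2[key] == pytest.approx(s1[key], rel=0.005)


class TestRmse:
    def test_identical_series_give_zero(self):
        assert dieflow.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset_gives_offset_magnitude(self):
        assert dieflow.rmse([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2.0)

    def test_arithmetic_example(self):
        assert dieflow.rmse([1.0, 3.0], [2.0, 5.0]) == pytest.approx(
            np.sqrt(5.0 / 2.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dieflow.rmse([1.0], [1.0, 2.0])

    def test_validation_report_collects_kinds(self):
        rep = dieflow.validation_report(
            {"pressure": [1.0, 2.0], "temperature": [90.0]},
            {"pressure": [1.5, 2.5], "temperature": [91.0]})
        assert rep.rmse_pressure == pytest.approx(0.5)
        assert rep.rmse_temperature == pytest.approx(1.0)
        assert rep.rmse_velocity is None
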