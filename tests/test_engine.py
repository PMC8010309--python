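"""Kinetic laws and whole-body simulation properties."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import voripbpk as v
from voripbpk.engine import SimulationError, tdi_rate
from voripbpk.population import BLOOD_COMPARTMENTS, ORGANS, IndividualPhysiology

from conftest import FAST, auc


def closed_form_ess(p: v.TDIParameters, inhibitor: float) -> float:
    return p.kdeg * p.e0 / (p.kdeg + p.kinact * inhibitor / (p.ki + inhibitor))


class TestTdiRate:
    def test_unperturbed_steady_state(self):
        p = v.TDIParameters(e0=4.32)
        assert tdi_rate(4.32, 0.0, p) == pytest.approx(0.0)

    def test_steady_state_at_ki(self):
        p = v.TDIParameters(e0=1.0)
        ess = closed_form_ess(p, p.ki)   # kdeg/(kdeg + kinact/2)
        assert ess == pytest.approx(3.2e-4 / (3.2e-4 + 0.02))
        assert tdi_rate(ess, p.ki, p) == pytest.approx(0.0, abs=1e-12)

    def test_saturated_steady_state(self):
        p = v.TDIParameters(e0=1.0)
        ess = closed_form_ess(p, 1e9 * p.ki)
        assert ess == pytest.approx(3.2e-4 / (3.2e-4 + 0.04), rel=1e-6)
        assert ess == pytest.approx(0.0079, abs=2e-4)

    def test_ode_relaxes_to_closed_form(self):
        p = v.TDIParameters(e0=4.32)
        for inhibitor in (0.0, p.ki, 100 * p.ki):
            sol = solve_ivp(lambda t, y: [tdi_rate(y[0], inhibitor, p)],
                            (0.0, 5e5), [p.e0], rtol=1e-10, atol=1e-14)
            assert sol.y[0, -1] == pytest.approx(
                closed_form_ess(p, inhibitor), rel=1e-3)


class TestMichaelisMenten:
    KIN = v.EnzymeKinetics("CYP2C19", km=3.5, kcat=1.19)

    def test_zero_substrate_zero_rate(self):
        assert v.michaelis_menten_rate(0.0, 0.76, self.KIN, 1.8) == 0.0

    def test_half_saturation_at_km(self):
        vmax = 1.19 * 0.76 * 1.8
        rate = v.michaelis_menten_rate(3.5, 0.76, self.KIN, 1.8)
        assert rate == pytest.approx(vmax / 2)

    def test_first_order_limit(self):
        cu = 1e-6
        rate = v.michaelis_menten_rate(cu, 0.76, self.KIN, 1.8)
        assert rate == pytest.approx(1.19 * 0.76 / 3.5 * 1.8 * cu, rel=1e-4)


class TestWeibullDissolution:
    def test_half_dissolved_at_dt50(self):
        assert v.weibull_dissolution_fraction(30, 30, 1.29) == pytest.approx(0.5)

    def test_starts_at_zero(self):
        assert v.weibull_dissolution_fraction(0, 30, 1.29) == 0.0

    def test_shape_one_is_exponential(self):
        t = np.array([5.0, 20.0, 60.0])
        f = v.weibull_dissolution_fraction(t, 30, 1.0)
        np.testing.assert_allclose(f, 1 - np.exp(-np.log(2) * t / 30))

    def test_monotone_and_saturating(self):
        t = np.linspace(0, 600, 200)
        f = v.weibull_dissolution_fraction(t, 30, 1.29)
        assert np.all(np.diff(f) >= 0)
        assert f[-1] > 0.999


def one_compartment_individual(v_ven=10.0, gfr_ml_min=79.365, q_each=100.0):
    """Degenerate physiology: all drug mass effectively in one stirred pool."""
    eps = 1e-5
    volumes = {o: eps for o in ORGANS}
    volumes["venous_blood"] = v_ven
    volumes["arterial_blood"] = eps
    flows = {o: q_each for o in ORGANS if o != "lung"}
    co = sum(flows.values())
    flows["lung"] = co
    return IndividualPhysiology(
        age=30, sex="male", phenotype="PM", body_weight=73, height=176,
        organ_volumes=volumes, blood_flows=flows, cardiac_output=co,
        gfr=gfr_ml_min, hematocrit=0.44,
        enzyme_liver_conc={"CYP2C19": 0, "CYP3A4": 0, "CYP2C9": 0},
        si_surface_cm2=6600, si_lumen_l=0.5)


class TestAnalyticOracle:
    def test_degenerate_model_matches_exponential(self):
        """A single well-stirred pool with linear renal clearance must follow
        C(t) = C0 exp(-k t) with k = CL_eff / V."""
        ind = one_compartment_individual()
        kp = {o: 1.0 for o in ORGANS}
        model = v.build_model(ind, kinetics={}, tdi=None, kp_map=kp,
                              options=v.ModelOptions(rtol=1e-10, atol=1e-12))
        res = model.simulate(v.DosingRegimen.single_iv(100, 0), t_end=24,
                             output_dt=0.5)
        dose_umol = res.dose_total_umol
        cl = ind.gfr * 60 / 1000 * 0.42           # filtration clearance, L/h
        co = ind.cardiac_output
        cl_eff = cl * co / (co + cl)              # arterial sampling correction
        vol = ind.organ_volumes["venous_blood"]
        t = res.t[res.t > 0.2]
        c = res.conc_umol_l[res.t > 0.2]
        expected = dose_umol / vol * np.exp(-cl_eff / vol * t)
        np.testing.assert_allclose(c, expected, rtol=1e-3)

    def test_solver_tolerance_convergence(self):
        ind = one_compartment_individual()
        kp = {o: 1.0 for o in ORGANS}
        model = v.build_model(ind, kinetics={}, tdi=None, kp_map=kp)
        reg = v.DosingRegimen.single_iv(100, 60)
        a1 = auc(model.simulate(reg, 24, output_dt=0.5, rtol=1e-6, atol=1e-9))
        a2 = auc(model.simulate(reg, 24, output_dt=0.5, rtol=5e-7, atol=1e-9))
        assert a1 == pytest.approx(a2, rel=1e-3)


class TestWholeBodySimulation:
    def test_conservation_with_clearances_off(self, adult_nm):
        model = v.build_model(adult_nm, kinetics={}, tdi=None,
                              drug=v.DrugParameters(gfr_fraction=0),
                              options=FAST)
        res = model.simulate(v.DosingRegimen.single_iv(100, 0), 24,
                             output_dt=0.5)
        total = res.amounts.sum(axis=1)[1:]       # post-bolus points
        np.testing.assert_allclose(total, res.dose_total_umol, rtol=1e-5)

    def test_zero_dose_zero_concentration(self, adult_nm):
        model = v.build_model(adult_nm, options=FAST)
        res = model.simulate(v.DosingRegimen("iv_infusion", ()), 12,
                             output_dt=0.5)
        assert np.all(res.conc_mg_l == 0)

    def test_mass_balance_iv(self, nm_single_iv_result):
        assert nm_single_iv_result.mass_balance_error() < 0.005

    def test_mass_balance_oral(self, adult_nm):
        model = v.build_model(adult_nm, options=FAST)
        reg = v.DosingRegimen("oral_tablet", (v.DoseEvent(0, 400),))
        res = model.simulate(reg, 48, output_dt=0.5)
        assert res.mass_balance_error() < 0.005

    def test_infusion_cmax_near_end_of_infusion(self, nm_single_iv_result):
        res = nm_single_iv_result
        t_cmax = res.t[np.argmax(res.conc_mg_l)]
        assert 0 < t_cmax <= 1.0 + 0.25

    def test_microdose_linearity(self, adult_nm):
        model = v.build_model(adult_nm, options=FAST)
        a1 = auc(model.simulate(v.DosingRegimen.single_iv(1, 0), 48, output_dt=0.25))
        a2 = auc(model.simulate(v.DosingRegimen.single_iv(2, 0), 48, output_dt=0.25))
        assert a2 / a1 == pytest.approx(2.0, rel=0.01)

    def test_saturation_superlinearity_at_therapeutic_doses(self, adult_nm):
        model = v.build_model(adult_nm, options=FAST)
        a4 = auc(model.simulate(v.DosingRegimen.single_iv(400, 120), 96, output_dt=0.25))
        a8 = auc(model.simulate(v.DosingRegimen.single_iv(800, 120), 96, output_dt=0.25))
        assert a8 / a4 > 2.0

    def test_pm_metabolism_bypasses_cyp2c19(self, adult_pm):
        model = v.build_model(adult_pm, options=FAST)
        res = model.simulate(v.DosingRegimen.single_iv(200, 60), 48, output_dt=0.5)
        assert res.cumulative["met_cyp2c19"][-1] == 0.0
        assert res.cumulative["met_cyp3a4_liver"][-1] > 0
        assert res.cumulative["met_cyp2c9"][-1] > 0

    def test_renal_clearance_is_filtration_of_unbound_drug(self, nm_single_iv_result):
        """Cumulative renal excretion equals GFR x fu x integral of arterial conc."""
        res = nm_single_iv_result
        ind = res.individual
        c_art = res.amounts[:, -2] / ind.organ_volumes["arterial_blood"]
        expected = np.trapezoid(c_art, res.t) * ind.gfr * 60 / 1000 * 0.42
        assert res.cumulative["renal"][-1] == pytest.approx(expected, rel=0.01)

    def test_genotype_auc_ordering(self, no_var):
        aucs = {}
        for ph in ("RM", "NM", "IM", "PM"):
            ind = v.generate_individual(30, "male", ph, no_var, seed=1)
            model = v.build_model(ind, options=FAST)
            aucs[ph] = auc(model.simulate(v.DosingRegimen.single_iv(200, 60),
                                          48, output_dt=0.25))
        assert aucs["PM"] > aucs["IM"] > aucs["NM"] > aucs["RM"]

    def test_auto_inhibition_raises_steady_state_exposure(self, adult_nm):
        reg = v.DosingRegimen.schedule(200, 12, 14, "iv_infusion", 60)
        on = v.build_model(adult_nm, options=FAST).simulate(reg, 168, output_dt=0.25)
        off = v.build_model(adult_nm, tdi=None, options=FAST).simulate(
            reg, 168, output_dt=0.25)
        assert auc(off, 156, 168) <= auc(on, 156, 168)
        # active enzyme never exceeds baseline under inactivation + turnover
        assert np.all(on.enzyme_liver_cyp3a4 <= on.individual.enzyme_liver_conc[
            "CYP3A4"] * (1 + 1e-9))

    def test_missing_kp_rejected(self, adult_nm):
        with pytest.raises(ValueError, match="partition"):
            v.build_model(adult_nm, kp_map={"liver": 1.0})

    def test_t_end_must_cover_regimen(self, adult_nm):
        model = v.build_model(adult_nm, options=FAST)
        with pytest.raises(ValueError):
            model.simulate(v.DosingRegimen.schedule(200, 12, 4, "iv_infusion", 60), 24)


class TestSimulatePopulation:
    def test_single_subject_equals_direct_simulation(self, adult_nm):
        reg = v.DosingRegimen.single_iv(200, 60)
        pop_res = v.simulate_population([adult_nm], reg, 24, options=FAST,
                                        output_dt=0.5)
        direct = v.build_model(adult_nm, options=FAST).simulate(
            reg, 24, output_dt=0.5)
        np.testing.assert_array_equal(pop_res[0].conc_mg_l, direct.conc_mg_l)

    def test_population_reproducible_and_mean_within_band(self):
        spec = v.PopulationSpec(n=30, age_range=(20, 40), male_fraction=1.0,
                                phenotype_mix={"NM": 1.0}, seed=3)
        reg = v.DosingRegimen.single_iv(200, 60)
        r1 = v.simulate_population(v.generate_population(spec), reg, 24,
                                   options=FAST, output_dt=0.5)
        r2 = v.simulate_population(v.generate_population(spec), reg, 24,
                                   options=FAST, output_dt=0.5)
        m1 = np.vstack([r.conc_mg_l for r in r1])
        np.testing.assert_array_equal(m1, np.vstack([r.conc_mg_l for r in r2]))
        mean = m1.mean(axis=0)
        p5, p95 = np.percentile(m1, 5, axis=0), np.percentile(m1, 95, axis=0)
        sel = mean > 0.05
        assert np.all(mean[sel] >= p5[sel]) and np.all(mean[sel] <= p95[sel])
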