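"""Non-compartmental analysis against closed-form oracles, and the
verification statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voripbpk as v
from voripbpk.nca import (fold_error, fold_range_fraction, lambda_z,
                          mean_fold_error, pk_summary,
                          prediction_interval_coverage)


class TestAucTrapezoid:
    def test_log_down_on_falling_segment(self):
        # rising 0->2 gives 1; falling 2->1 gives 1/ln 2
        val = v.auc_trapezoid([0, 1, 2], [0, 2, 1])
        assert val == pytest.approx(1 + 1 / np.log(2), rel=1e-12)

    def test_constant_concentration(self):
        t = np.linspace(0, 24, 25)
        assert v.auc_trapezoid(t, np.ones_like(t)) == pytest.approx(24.0)

    def test_exponential_matches_analytic(self):
        t = np.linspace(0, 50, 501)
        c = 10 * np.exp(-0.1 * t)
        analytic = 10 / 0.1 * (1 - np.exp(-5))
        assert v.auc_trapezoid(t, c) == pytest.approx(analytic, rel=1e-3)

    def test_exact_on_rising_linear_data(self):
        t = np.array([0.0, 2.0, 5.0])
        c = 3.0 * t
        assert v.auc_trapezoid(t, c) == pytest.approx(0.5 * 3 * 25)

    def test_window_outside_grid_raises(self):
        with pytest.raises(ValueError):
            v.auc_trapezoid([0, 1, 2], [1, 1, 1], 0, 5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.05, 2))
    def test_subinterval_additivity(self, c0, k):
        t = np.linspace(0, 12, 49)
        c = c0 * np.exp(-k * t)
        whole = v.auc_trapezoid(t, c, 0, 12)
        # split at a grid point: the log-down rule is additive there
        split = v.auc_trapezoid(t, c, 0, 5.25) + v.auc_trapezoid(t, c, 5.25, 12)
        assert whole == pytest.approx(split, rel=1e-9)


class TestAucInf:
    def test_pure_exponential_is_exact(self):
        t = np.linspace(0, 40, 401)
        c = 10 * np.exp(-0.1 * t)
        assert v.auc_inf(t, c) == pytest.approx(100.0, rel=1e-3)

    def test_stable_under_truncation(self):
        t = np.linspace(0, 40, 401)
        c = 10 * np.exp(-0.1 * t)
        full = v.auc_inf(t, c)
        short = v.auc_inf(t[:250], c[:250])
        assert short == pytest.approx(full, rel=0.02)

    def test_lambda_z_recovered_on_biexponential_tail(self):
        spec = v.SyntheticPKCurveSpec("biexponential", dose=200, cl=15, v=40,
                                      k12=1.0, k21=0.5,
                                      times=np.linspace(0, 72, 289))
        t, c, _ = v.generate_pk_curve(spec)
        from voripbpk.synthetic import _biexponential_constants
        _, _, _, beta = _biexponential_constants(spec)
        assert lambda_z(t, c, window=(48, 72)) == pytest.approx(beta, rel=0.01)

    def test_nonpositive_terminal_rejected(self):
        with pytest.raises(ValueError):
            lambda_z([0, 1, 2, 3], [4, 2, 1, 0])

    def test_rising_terminal_rejected(self):
        with pytest.raises(ValueError):
            lambda_z([0, 1, 2, 3], [1, 1, 2, 3])


class TestPkSummary:
    def test_superposition_identity_for_linear_drug(self):
        """At steady state of a linear system, AUC_tau equals single-dose
        AUC_inf (verified with saturable metabolism and inactivation off:
        renal filtration only)."""
        from test_engine import one_compartment_individual
        from voripbpk.population import ORGANS
        ind = one_compartment_individual()
        kp = {o: 1.0 for o in ORGANS}
        model = v.build_model(ind, kinetics={}, tdi=None, kp_map=kp,
                              options=v.ModelOptions(rtol=1e-8, atol=1e-11))
        single = model.simulate(v.DosingRegimen.single_iv(100, 60), 48,
                                output_dt=0.25)
        multi = model.simulate(
            v.DosingRegimen.schedule(100, 12, 10, "iv_infusion", 60), 120,
            output_dt=0.25)
        auc_inf_single = v.auc_inf(single.t, single.conc_mg_l, window=(12, 36))
        auc_tau_ss = v.auc_trapezoid(multi.t, multi.conc_mg_l, 108, 120)
        assert auc_tau_ss == pytest.approx(auc_inf_single, rel=0.01)

    def test_windows_and_cmax(self):
        class R:
            t = np.linspace(0, 24, 97)
            conc_mg_l = 5 * np.exp(-0.2 * t)
            dose_total_mg = 100.0
            body_weight = 50.0
        pk = pk_summary(R(), tau_window=(0, 12), window_24h=(0, 24))
        assert pk.cmax == pytest.approx(5.0)
        assert pk.auc_tau == pytest.approx(5 / 0.2 * (1 - np.exp(-0.2 * 12)), rel=1e-3)
        assert pk.auc_24h == pytest.approx(pk.auc_obs)
        assert pk.cl_per_kg == pytest.approx(100 / pk.auc_inf / 50)

    def test_missing_window_raises(self):
        class R:
            t = np.linspace(0, 12, 25)
            conc_mg_l = np.exp(-0.3 * t)
        with pytest.raises(ValueError):
            pk_summary(R(), t_last=24, extrapolate=False)


class TestFoldStatistics:
    def test_table_ratio_example(self):
        ratio, fold = fold_error(48.9, 44.4)
        assert round(ratio, 2) == 1.10
        assert fold == ratio

    def test_identity_and_symmetry(self):
        assert fold_error(3.3, 3.3) == (1.0, 1.0)
        assert fold_error(1, 2)[1] == fold_error(2, 1)[1] == 2.0

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            fold_error(1.0, 0.0)

    def test_all_unit_ratios_give_100_percent(self):
        assert fold_range_fraction(np.ones(7), 0.8, 1.25) == 100

    def test_wide_range_dominates_stringent_range(self):
        rng = np.random.default_rng(0)
        ratios = rng.lognormal(0, 0.3, 200)
        assert (fold_range_fraction(ratios, 0.5, 2.0)
                >= fold_range_fraction(ratios, 0.8, 1.25))

    def test_inclusive_bounds_count_boundary(self):
        assert fold_range_fraction([0.8, 1.25], 0.8, 1.25) == 100
        assert fold_range_fraction([0.8, 1.25], 0.8, 1.25, inclusive=False) == 0

    def test_empty_input_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            fold_range_fraction([], 0.8, 1.25)
        with pytest.raises(ValueError):
            mean_fold_error([])

    def test_rounding_half_up(self):
        # 8 of 11 inside = 72.7% -> 73
        ratios = [1.0] * 8 + [2.0] * 3
        assert fold_range_fraction(ratios, 0.8, 1.25) == 73


class _Curve:
    def __init__(self, t, c):
        self.t, self.conc_mg_l = t, c


class TestPredictionIntervalCoverage:
    def _sims(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 24, 25)
        base = 10 * np.exp(-0.15 * t)
        return t, [_Curve(t, base * rng.lognormal(0, 0.25)) for _ in range(n)]

    def test_median_fully_covered(self):
        t, sims = self._sims()
        median = np.median(np.vstack([s.conc_mg_l for s in sims]), axis=0)
        assert prediction_interval_coverage(sims, t, median) == 1.0

    def test_outliers_not_covered(self):
        t, sims = self._sims()
        far = 100 * np.max(np.vstack([s.conc_mg_l for s in sims]), axis=0)
        assert prediction_interval_coverage(sims, t, far) == 0.0

    def test_self_drawn_points_covered_about_90_percent(self):
        t, sims = self._sims(n=200, seed=1)
        rng = np.random.default_rng(2)
        base = 10 * np.exp(-0.15 * t)
        obs_t, obs_c = [], []
        for _ in range(40):
            draw = base * rng.lognormal(0, 0.25)
            for j in range(0, 25, 6):
                obs_t.append(t[j]), obs_c.append(draw[j])
        cov = prediction_interval_coverage(sims, obs_t, obs_c)
        # binomial error around 0.9 for ~200 points
        assert 0.8 <= cov <= 0.98

    def test_too_few_subjects_rejected(self):
        t, sims = self._sims(n=5)
        with pytest.raises(ValueError):
            prediction_interval_coverage(sims[:5], t, np.ones_like(t))
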