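"""Closed-form kinetics, covariate scaling, and random-effect mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tacropk as tp
from tacropk.model import covariate_multipliers

from conftest import ode_concentration

FINAL = tp.FINAL_STRUCTURAL


class TestConcentration:
    def test_zero_dose_is_zero(self):
        reg = tp.day3_regimen(0.0)
        assert tp.concentration(FINAL, reg, 72.0) == 0.0

    def test_nothing_absorbed_at_dose_time(self):
        reg = tp.DosingRegimen(3.0, 12.0, 1)
        assert tp.concentration(FINAL, reg, 0.0) == 0.0

    def test_day3_trough_matches_per_dose_superposition(self):
        # brute-force per-dose sum, written independently of the implementation
        reg = tp.day3_regimen(1.0)
        ke = FINAL.cl_f / FINAL.v_f
        expected = 0.0
        for t_dose in [0, 12, 24, 36, 48, 60]:
            dt = 72.0 - t_dose
            expected += (
                1.0
                * FINAL.ka
                / (FINAL.v_f * (FINAL.ka - ke))
                * (np.exp(-ke * dt) - np.exp(-FINAL.ka * dt))
                * 1000.0
            )
        got = tp.concentration(FINAL, reg, 72.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.206, abs=5e-4)

    def test_steady_state_trough_geometric_series(self):
        # closed form D*ka/(V(ka-ke)) * [e^-ke*tau/(1-e^-ke*tau) - e^-ka*tau/(1-e^-ka*tau)]
        ke = FINAL.cl_f / FINAL.v_f
        tau = 12.0
        acc = lambda k: np.exp(-k * tau) / (1 - np.exp(-k * tau))
        expected = 0.5 * FINAL.ka / (FINAL.v_f * (FINAL.ka - ke)) * (acc(ke) - acc(FINAL.ka)) * 1000.0
        reg = tp.DosingRegimen(0.5, tau, 200)
        got = tp.concentration(FINAL, reg, 200 * tau)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(0.883, abs=1e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.01, 100.0),
        t=st.floats(0.5, 120.0),
        dose=st.floats(0.1, 10.0),
    )
    def test_dose_linearity(self, scale, t, dose):
        r1 = tp.DosingRegimen(dose, 12.0, 6)
        r2 = tp.DosingRegimen(dose * scale, 12.0, 6)
        c1 = tp.concentration(FINAL, r1, t)
        c2 = tp.concentration(FINAL, r2, t)
        assert c2 == pytest.approx(scale * c1, rel=1e-10, abs=1e-300)

    def test_never_negative_and_zero_before_first_dose(self):
        reg = tp.DosingRegimen(3.0, 12.0, 4, t_first=24.0)
        t = np.linspace(0, 120, 50)
        c = tp.concentration(FINAL, reg, t)
        assert np.all(c >= 0)
        assert np.all(c[t <= 24.0] == 0.0)

    def test_closed_form_agrees_with_ode_oracle(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 50:
            ka = float(np.exp(rng.uniform(np.log(0.5), np.log(20))))
            v = float(np.exp(rng.uniform(np.log(50), np.log(6000))))
            cl = float(np.exp(rng.uniform(np.log(5), np.log(120))))
            if abs(ka - cl / v) < 0.05 * ka:
                continue
            params = tp.StructuralParams(ka=ka, v_f=v, cl_f=cl)
            reg = tp.DosingRegimen(float(rng.uniform(0.5, 5)), 12.0, 6)
            times = np.sort(rng.uniform(0.5, 96.0, size=20))
            closed = tp.concentration(params, reg, times)
            oracle = ode_concentration(params, reg, times)
            np.testing.assert_allclose(closed, oracle, rtol=1e-6, atol=1e-9)
            n_checked += 1

    def test_high_ka_limit_is_iv_bolus_profile(self):
        params = tp.StructuralParams(ka=1e4, v_f=FINAL.v_f, cl_f=FINAL.cl_f)
        reg = tp.DosingRegimen(3.0, 12.0, 6)
        ke = params.ke
        t = np.array([6.0, 18.0, 47.9, 71.9])
        doses = reg.dose_times
        iv = np.array(
            [
                sum(3.0 / params.v_f * np.exp(-ke * (ti - td)) * 1000.0
                    for td in doses if td < ti)
                for ti in t
            ]
        )
        np.testing.assert_allclose(tp.concentration(params, reg, t), iv, rtol=1e-3)

    def test_ka_ke_degeneracy_uses_analytic_limit(self):
        # ka == ke exactly: the limit D*ka*dt*e^(-ka dt)/V must be returned,
        # continuous with nearby non-degenerate parameter sets
        ka = 0.1
        v = 100.0
        exact = tp.StructuralParams(ka=ka, v_f=v, cl_f=ka * v)
        near = tp.StructuralParams(ka=ka, v_f=v, cl_f=ka * v * (1 + 1e-6))
        reg = tp.DosingRegimen(1.0, 12.0, 1)
        t = 8.0
        limit = 1.0 * ka * t * np.exp(-ka * t) / v * 1000.0
        assert tp.concentration(exact, reg, t) == pytest.approx(limit, rel=1e-9)
        assert tp.concentration(near, reg, t) == pytest.approx(limit, rel=1e-4)


class TestCovariates:
    def test_zero_thetas_identity(self):
        eff = tp.CovariateEffects()
        cov = tp.SubjectCovariates(c_vrc=2.0, crea=500.0)
        out = tp.apply_covariates(FINAL, eff, cov)
        assert (out.v_f, out.cl_f, out.ka) == (FINAL.v_f, FINAL.cl_f, FINAL.ka)

    def test_reference_covariates_identity(self):
        out = tp.apply_covariates(
            FINAL, tp.FINAL_EFFECTS, tp.SubjectCovariates(c_vrc=0.0, crea=237.0)
        )
        assert out.v_f == pytest.approx(FINAL.v_f)
        assert out.cl_f == pytest.approx(FINAL.cl_f)

    def test_exponential_cl_ratio(self):
        base = tp.apply_covariates(
            FINAL, tp.FINAL_EFFECTS, tp.SubjectCovariates(c_vrc=0.0, crea=237.0)
        )
        one = tp.apply_covariates(
            FINAL, tp.FINAL_EFFECTS, tp.SubjectCovariates(c_vrc=1.0, crea=237.0)
        )
        assert one.cl_f / base.cl_f == pytest.approx(np.exp(-0.28), rel=1e-12)

    def test_nonpositive_crea_rejected(self):
        with pytest.raises(ValueError):
            tp.SubjectCovariates(c_vrc=0.0, crea=0.0)
        with pytest.raises(ValueError):
            covariate_multipliers(tp.FINAL_EFFECTS, 0.0, -5.0)

    @pytest.mark.parametrize("form", ["exponential", "power_shifted", "linear"])
    def test_all_families_defined_and_decreasing_at_zero_cvrc(self, form):
        eff = tp.CovariateEffects(
            theta_vrc_v=-0.2, theta_vrc_cl=-0.28, theta_crea_v=-0.4, form=form
        )
        g_v, g_cl = covariate_multipliers(eff, np.array([0.0, 1.0, 3.0]), 237.0)
        assert np.all(np.isfinite(g_v)) and np.all(g_v > 0)
        assert np.all(np.diff(g_v) < 0) and np.all(np.diff(g_cl) < 0)
        assert g_v[0] == pytest.approx(1.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            tp.CovariateEffects(form="cubic")


class TestRandomEffects:
    def test_median_subject_is_typical(self):
        out = tp.individual_params(FINAL, 0.0, 0.0)
        assert (out.v_f, out.cl_f) == (FINAL.v_f, FINAL.cl_f)

    def test_log2_eta_doubles_cl_only(self):
        out = tp.individual_params(FINAL, 0.0, np.log(2.0))
        assert out.cl_f == pytest.approx(2 * FINAL.cl_f)
        assert out.v_f == FINAL.v_f

    def test_lognormal_median_property(self):
        rng = np.random.default_rng(7)
        eta = rng.normal(0, np.sqrt(0.16), size=100_000)
        cl_i = FINAL.cl_f * np.exp(eta)
        assert np.median(cl_i) == pytest.approx(FINAL.cl_f, rel=0.01)


class TestResidualError:
    def test_noiseless_limit(self):
        rng = np.random.default_rng(0)
        obs = tp.predict_observation(7.0, 1e-12, rng)
        assert obs == pytest.approx(7.0, abs=1e-10)

    def test_sampled_sd_matches_sigma(self):
        rng = np.random.default_rng(3)
        obs = tp.predict_observation(np.full(100_000, 7.0), 3.5, rng)
        assert obs.std() == pytest.approx(3.5, rel=0.02)
        assert np.any(obs < 0)  # additive error implies negatives are possible

    def test_seed_determinism(self):
        a = tp.predict_observation(0.0, 3.5, np.random.default_rng(42))
        b = tp.predict_observation(0.0, 3.5, np.random.default_rng(42))
        assert a == b

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            tp.predict_observation(1.0, 0.0, np.random.default_rng(0))


class TestTroughMonotonicity:
    def test_trough_increases_with_cvrc(self):
        troughs = [
            tp.day3_trough(FINAL, tp.FINAL_EFFECTS,
                           tp.SubjectCovariates(c_vrc=x, crea=237.0), 3.0)
            for x in np.arange(0, 7.1, 0.5)
        ]
        assert np.all(np.diff(troughs) > 0)

    def test_trough_decreases_with_clearance_at_fixed_volume(self):
        troughs = [
            tp.concentration(
                tp.StructuralParams(ka=8.39, v_f=2690.0, cl_f=cl),
                tp.day3_regimen(3.0), 72.0,
            )
            for cl in [20.0, 40.0, 60.0, 80.0]
        ]
        assert np.all(np.diff(troughs) < 0)
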