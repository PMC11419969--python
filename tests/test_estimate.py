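"""Laplace marginal likelihood, information criteria, diagnostics, and
stepwise covariate selection."""

import numpy as np
import pandas as pd
import pytest

import tacropk as tp
from tacropk import estimate
from tacropk.estimate import _Workspace

from conftest import TRUTH_PARAMS, TRUTH_START, toy_dataset


def gauss_hermite_ofv(spec, params, data, n_nodes=40):
    """Independent dense-quadrature oracle for the marginal -2 log likelihood.

    Evaluates the structural model through the public closed form (not the
    estimation workspace) and integrates over (eta_v, eta_cl) with a tensor
    Gauss-Hermite rule.
    """
    params = spec.full_params(params)
    effects = spec.effects(params)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    sd_v = np.sqrt(params["omega2_v"])
    sd_cl = np.sqrt(params["omega2_cl"])
    sigma = params["sigma_add"]
    total = 0.0
    for sid in data.subject_ids:
        g = data.df[data.df["ID"] == sid]
        obs = g[g["EVID"] == 0]
        doses = g[g["EVID"] == 1]
        lik = 0.0
        for i, zi in enumerate(z):
            for j, zj in enumerate(w):
                eta_v = np.sqrt(2) * sd_v * zi
                eta_cl = np.sqrt(2) * sd_cl * z[j]
                f = []
                for _, row in obs.iterrows():
                    adj = tp.apply_covariates(
                        tp.StructuralParams(params["tvKa"], params["tvV"], params["tvCL"]),
                        effects,
                        tp.SubjectCovariates(c_vrc=row["CVRC"], crea=row["CREA"]),
                    )
                    ind = tp.individual_params(adj, eta_v, eta_cl)
                    c = sum(
                        tp.concentration(
                            ind,
                            tp.DosingRegimen(drow["AMT"], 1.0, 1, t_first=drow["TIME"]),
                            row["TIME"],
                        )
                        for _, drow in doses.iterrows()
                        if drow["TIME"] < row["TIME"]
                    )
                    f.append(c)
                resid = obs["DV"].to_numpy() - np.array(f)
                loglik_y = -0.5 * np.sum(
                    resid**2 / sigma**2 + np.log(2 * np.pi * sigma**2)
                )
                lik += w[i] * w[j] / np.pi * np.exp(loglik_y)
        total += -2.0 * np.log(lik)
    return total


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ofv,k,expected_aic,expected_bic",
        [
            (990.2152, 7, 1004.215, 1026.04),  # one-compartment additive row
            (987.55, 6, 999.55, 1018.26),  # fixed-Ka row
        ],
    )
    def test_published_rows_arithmetic(self, ofv, k, expected_aic, expected_bic):
        assert estimate.aic(ofv, k) == pytest.approx(expected_aic, abs=0.01)
        assert estimate.bic(ofv, k, 167) == pytest.approx(expected_bic, abs=0.01)

    def test_zero_parameters(self):
        assert estimate.aic(123.4, 0) == 123.4
        assert estimate.bic(123.4, 0, 167) == 123.4

    def test_fit_result_identities(self, fit19):
        assert fit19.aic == pytest.approx(fit19.ofv + 2 * fit19.k)
        assert fit19.bic == pytest.approx(fit19.ofv + fit19.k * np.log(fit19.n_obs))
        assert fit19.loglik == pytest.approx(-fit19.ofv / 2)


class TestMarginalLikelihood:
    def test_no_random_effect_limit_closed_form(self):
        # one subject, one observation, omega2 = 0: plain Gaussian -2LL
        ds = toy_dataset(n_subjects=1, obs_times=(11.5,), dv=[[5.0]])
        spec = tp.ModelSpec(omega2_v_fix=0.0, omega2_cl_fix=0.0)
        params = {"tvV": 2690.0, "tvCL": 42.87, "sigma_add": 3.5}
        pred = tp.concentration(
            tp.StructuralParams(8.39, 2690.0, 42.87), tp.DosingRegimen(3.0, 12.0, 1), 11.5
        )
        expected = (5.0 - pred) ** 2 / 3.5**2 + np.log(2 * np.pi * 3.5**2)
        got = estimate.neg2_marginal_loglik(spec, params, ds)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_truth_beats_perturbed_parameters(self, final_spec, cohort19):
        data, _ = cohort19
        ofv_true = estimate.neg2_marginal_loglik(final_spec, TRUTH_PARAMS, data)
        perturbed = dict(TRUTH_PARAMS, tvCL=2 * TRUTH_PARAMS["tvCL"])
        ofv_pert = estimate.neg2_marginal_loglik(final_spec, perturbed, data)
        assert ofv_true < ofv_pert

    def test_laplace_matches_dense_quadrature(self):
        ds = toy_dataset(n_subjects=2, obs_times=(11.5, 23.5, 47.5, 71.5),
                         dv=[[4.0, 6.0, 7.5, 8.0], [2.0, 3.5, 5.0, 6.5]])
        spec = tp.ModelSpec()
        params = {"tvV": 2690.0, "tvCL": 42.87, "omega2_v": 0.04,
                  "omega2_cl": 0.16, "sigma_add": 3.5}
        laplace = estimate.neg2_marginal_loglik(spec, params, ds)
        oracle = gauss_hermite_ofv(spec, params, ds)
        assert laplace == pytest.approx(oracle, abs=0.5)

    def test_subject_order_invariance(self, final_spec, cohort19):
        data, _ = cohort19
        shuffled = data.subset(list(reversed(data.subject_ids)))
        a = estimate.neg2_marginal_loglik(final_spec, TRUTH_PARAMS, data)
        b = estimate.neg2_marginal_loglik(final_spec, TRUTH_PARAMS, shuffled)
        assert a == pytest.approx(b, rel=1e-12)

    def test_uniform_time_shift_invariance(self, final_spec, cohort19):
        data, _ = cohort19
        df = data.df.copy()
        df.loc[df["ID"] == df["ID"].iloc[0], "TIME"] += 48.0
        shifted = tp.PKEventDataset(df)
        a = estimate.neg2_marginal_loglik(final_spec, TRUTH_PARAMS, data)
        b = estimate.neg2_marginal_loglik(final_spec, TRUTH_PARAMS, shifted)
        assert a == pytest.approx(b, rel=1e-12)

    def test_inner_derivatives_match_finite_differences(self, final_spec, cohort19):
        data, _ = cohort19
        ws = _Workspace(data, final_spec)
        params = final_spec.full_params(TRUTH_PARAMS)
        rng = np.random.default_rng(5)
        eta = rng.normal(0, 0.3, size=(ws.S, 2))
        h, grad, hess = ws.joint_neg2(params, eta, ["v", "cl"], deriv=True)
        step = 1e-5
        for a in range(2):
            e = np.zeros_like(eta)
            e[:, a] = step
            hp = ws.joint_neg2(params, eta + e, ["v", "cl"])
            hm = ws.joint_neg2(params, eta - e, ["v", "cl"])
            np.testing.assert_allclose(grad[:, a], (hp - hm) / (2 * step), rtol=1e-5, atol=1e-6)
            np.testing.assert_allclose(
                hess[:, a, a], (hp - 2 * h + hm) / step**2, rtol=1e-3, atol=1e-4
            )


class TestFit:
    def test_refit_is_bitwise_deterministic(self, final_spec, cohort19):
        data, _ = cohort19
        r1 = estimate.fit(final_spec, data, start=TRUTH_START, n_starts=2, seed=3,
                          compute_se=False)
        r2 = estimate.fit(final_spec, data, start=TRUTH_START, n_starts=2, seed=3,
                          compute_se=False)
        assert r1.ofv == r2.ofv
        assert r1.params == r2.params

    def test_fixed_omega_v_drops_eta_v_ebes(self, cohort19):
        data, _ = cohort19
        spec = tp.ModelSpec(omega2_v_fix=0.0)
        res = estimate.fit(spec, data, n_starts=1, seed=0, compute_se=False)
        assert res.ebes["eta_v"].isna().all()
        assert res.ebes["eta_cl"].notna().all()
        assert "omega2_v" not in res.params

    def test_k_counts_estimated_quantities_only(self, final_spec):
        # fixed Ka excluded; base model with Ka estimated gains one
        assert final_spec.k == 8
        assert tp.ModelSpec().k == 5
        assert tp.ModelSpec(fix_ka=False).k == 6

    def test_standard_errors_reported(self, final_spec, cohort19):
        data, _ = cohort19
        res = estimate.fit(final_spec, data, start=TRUTH_START, n_starts=1, seed=0)
        assert res.se["tvCL"] is None or res.se["tvCL"] > 0
        summary = res.summary()
        assert set(summary["parameter"]).issuperset({"tvV", "tvCL", "OFV"})


class TestShrinkage:
    def test_no_shrinkage(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 1, 500)
        eta = (eta - eta.mean()) / eta.std(ddof=1) * np.sqrt(0.16)
        assert estimate.shrinkage(eta, 0.16) == pytest.approx(0.0, abs=1e-9)

    def test_full_shrinkage(self):
        assert estimate.shrinkage(np.zeros(10), 0.16) == pytest.approx(100.0)

    def test_half_shrinkage(self):
        eta = np.array([0.2, -0.2])  # sample SD (ddof=1) = 0.2*sqrt(2)... build exact
        eta = np.array([0.1, -0.1, 0.3, -0.3])
        eta = eta / eta.std(ddof=1) * 0.2
        assert estimate.shrinkage(eta, 0.16) == pytest.approx(50.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate.shrinkage(np.array([0.1]), 0.16)
        with pytest.raises(ValueError):
            estimate.shrinkage(np.array([0.1, 0.2]), 0.0)


class TestCwres:
    def test_reduces_to_standardised_residual_without_iiv(self):
        ds = toy_dataset(n_subjects=2)
        spec = tp.ModelSpec(omega2_v_fix=0.0, omega2_cl_fix=0.0)
        res = estimate.fit(spec, ds, n_starts=1, seed=0, compute_se=False)
        pred = estimate.predict_observations(spec, res.params, ds)
        sigma = res.params["sigma_add"]
        expected = (pred["DV"] - pred["PRED"]) / sigma
        np.testing.assert_allclose(res.cwres, expected, rtol=1e-8)

    def test_null_distribution_is_standard_normal(self, final_spec):
        data, _ = tp.generate_cohort(n_subjects=19, seed=77)
        res = estimate.fit(final_spec, data, start=TRUTH_START, n_starts=1, seed=0,
                           compute_se=False)
        assert abs(res.cwres.mean()) < 0.1
        assert 0.8 < res.cwres.std() < 1.2

    def test_gaussian_coverage(self, fit19):
        assert np.mean(np.abs(fit19.cwres) <= 2.0) >= 0.90


class TestStepwise:
    def test_no_candidate_reaches_threshold_returns_base(self, cohort19):
        data, _ = cohort19
        base = tp.ModelSpec()
        final, trace = estimate.stepwise_select(
            base, data=data, forward_dofv=1e9, seed=0
        )
        assert final.covariates == ()
        assert (trace["phase"] == "base").any()

    def test_strong_effect_selected_decoy_not(self):
        # strong CVRC->CL effect in truth; CREA->CL is a null decoy
        effects = tp.CovariateEffects(theta_vrc_cl=-0.6)
        data, _ = tp.generate_cohort(n_subjects=60, effects=effects, seed=31)
        final, trace = estimate.stepwise_select(
            tp.ModelSpec(),
            candidates=(("vrc", "cl"), ("crea", "cl")),
            data=data,
            seed=0,
        )
        assert ("vrc", "cl") in final.covariates
        assert ("crea", "cl") not in final.covariates
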