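"""Laplace-EM population estimation: limiting cases, oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from vancopk.cohort import CohortConfig, generate_cohort, simulate_observations
from vancopk.covariates import CovariateSelection, PopulationModel
from vancopk.estimation import (
    EMPopulationFitter,
    EstimationError,
    e_step,
    fit_population,
    information_criteria,
    m_step,
)
from vancopk.io import TDM_COLUMNS
from vancopk.pk import PKParams, Regimen, conc_steady_state

from conftest import intercept_only_model


def tiny_dataset(concs, times=None, regimen=None, patient_ids=None, obs_type="trough"):
    """Hand-rolled tidy TDM frame with median covariates."""
    regimen = regimen or Regimen(1000, 12.0, 1.0)
    n = len(concs)
    times = times if times is not None else [regimen.interval_h - 0.5] * n
    patient_ids = patient_ids or [f"S{i}" for i in range(n)]
    rows = []
    for pid, t, c in zip(patient_ids, times, concs):
        rows.append(
            {
                "patient_id": pid,
                "dose_mg": regimen.dose_mg,
                "interval_h": regimen.interval_h,
                "tinf_h": regimen.infusion_h,
                "time_in_interval_h": t,
                "conc_ug_ml": c,
                "obs_type": obs_type,
                "at_steady_state": True,
                "DA": 1, "NE": 1, "furosemide": 1, "dobutamine": 1,
                "sex": 1, "VM": 1, "CRRT_S": 2, "Burn_S": 2,
                "cr_umol_l": 71.0, "age_y": 62.0, "tbw_kg": 65.0,
            }
        )
    return pd.DataFrame(rows)[TDM_COLUMNS]


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        ic = information_criteria(-100.0, 4, 50)
        assert ic.aic == pytest.approx(208.0)
        assert ic.bic == pytest.approx(208.0 - 8 + 4 * np.log(50))
        assert ic.aic_per_obs == pytest.approx(208.0 / 50)

    def test_zero_parameters_edge(self):
        ic = information_criteria(-100.0, 0, 10)
        assert ic.aic == pytest.approx(200.0)
        assert ic.bic == pytest.approx(200.0)

    def test_unpacks_as_pair(self):
        aic, bic = information_criteria(-10.0, 2, 5)
        assert aic == pytest.approx(24.0)

    def test_requires_observations(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 1, 0)


class TestEStepLimits:
    def test_uninformative_data_returns_prior(self):
        """With enormous residual error the conditional equals the prior."""
        model = intercept_only_model(3.16, 60.71, 0.30, 0.30, residual_cv=0.10)
        model = model.with_(residual_model="additive", residual_scale=1e6)
        df = tiny_dataset([15.0, 8.0, 25.0])
        out = e_step(df, model)
        # the conditional moments are quadrature approximations; in this
        # limit they should sit on the prior to well under 1%
        np.testing.assert_allclose(out["cl"], 3.16, rtol=0.01)
        np.testing.assert_allclose(out["v"], 60.71, rtol=0.01)
        np.testing.assert_allclose(out["var_cl"], model.omega[0, 0], rtol=0.05)
        np.testing.assert_allclose(out["var_v"], model.omega[1, 1], rtol=0.05)

    def test_degenerate_prior_pins_typical_values(self):
        model = intercept_only_model(3.16, 60.71, 0.30, 0.30)
        model = model.with_(omega=np.zeros((2, 2)))
        df = tiny_dataset([30.0, 2.0])
        out = e_step(df, model)
        np.testing.assert_allclose(out["cl"], 3.16)
        np.testing.assert_allclose(out["v"], 60.71)

    def test_conjugate_normal_posterior_one_trough(self):
        """One trough, near-fixed V, additive error: the conditional mean
        matches the 1-D linear-Gaussian posterior to 1e-6."""
        sigma = 1.0
        omega_cl_sd = 0.002  # small spread keeps the model effectively linear
        model = PopulationModel(
            selection=CovariateSelection(),
            theta_cl=[3.0],
            theta_v=[55.0],
            omega=np.diag([omega_cl_sd**2, 1e-12]),
            residual_model="additive",
            residual_scale=sigma,
        )
        reg = Regimen(1000, 12.0, 1.0)
        y = 14.0
        df = tiny_dataset([y], regimen=reg)
        out = e_step(df, model)
        # linearize the trough prediction in CL around the prior mean
        h = 1e-6
        f0 = conc_steady_state(PKParams(3.0, 55.0), reg, 11.5)
        fp = conc_steady_state(PKParams(3.0 + h, 55.0), reg, 11.5)
        slope = (fp - f0) / h
        post_var = 1.0 / (slope**2 / sigma**2 + 1.0 / omega_cl_sd**2)
        post_mean = 3.0 + post_var * slope * (y - f0) / sigma**2
        assert out["cl"][0] == pytest.approx(post_mean, abs=1e-6)
        assert out["var_cl"][0] == pytest.approx(post_var, rel=1e-3)


class TestMStep:
    def test_degenerate_closed_form(self):
        """Zero conditional covariances + intercept-only selection: θ are the
        sample means and Ω the sample covariance of the conditional means."""
        df = tiny_dataset([10.0, 15.0, 20.0])
        est = pd.DataFrame(
            {
                "patient_id": ["S0", "S1", "S2"],
                "cl": [2.0, 3.0, 4.0],
                "v": [50.0, 70.0, 60.0],
                "var_cl": 0.0,
                "cov_cl_v": 0.0,
                "var_v": 0.0,
            }
        )
        model = m_step(est, df, CovariateSelection())
        assert model.theta_cl[0] == pytest.approx(3.0)
        assert model.theta_v[0] == pytest.approx(60.0)
        m = np.column_stack([est["cl"], est["v"]])
        expected = (m - m.mean(axis=0)).T @ (m - m.mean(axis=0)) / 3
        np.testing.assert_allclose(model.omega, expected, rtol=1e-6)

    def test_duplication_invariance(self):
        df1 = tiny_dataset([10.0, 20.0])
        est1 = pd.DataFrame(
            {
                "patient_id": ["S0", "S1"],
                "cl": [2.5, 3.5],
                "v": [50.0, 60.0],
                "var_cl": 0.1,
                "cov_cl_v": 0.0,
                "var_v": 4.0,
            }
        )
        df2 = tiny_dataset([10.0, 20.0, 10.0, 20.0], patient_ids=["S0", "S1", "T0", "T1"])
        est2 = pd.concat(
            [est1, est1.assign(patient_id=["T0", "T1"])], ignore_index=True
        )
        m1 = m_step(est1, df1, CovariateSelection())
        m2 = m_step(est2, df2, CovariateSelection())
        np.testing.assert_allclose(m1.theta_cl, m2.theta_cl, rtol=1e-8)
        np.testing.assert_allclose(m1.omega, m2.omega, rtol=1e-8)
        assert m1.residual_scale == pytest.approx(m2.residual_scale, rel=1e-6)

    def test_collinear_design_raises(self):
        df = tiny_dataset([10.0, 15.0, 20.0, 12.0])
        df["cr_umol_l"] = 71.0  # constant covariate duplicates the intercept
        est = pd.DataFrame(
            {
                "patient_id": [f"S{i}" for i in range(4)],
                "cl": [2.0, 3.0, 4.0, 3.5],
                "v": [50.0, 60.0, 70.0, 55.0],
                "var_cl": 0.0,
                "cov_cl_v": 0.0,
                "var_v": 0.0,
            }
        )
        with pytest.raises(EstimationError, match="singular"):
            m_step(est, df, CovariateSelection(cl_covariates=("Cr",)))

    def test_against_numerical_maximizer(self):
        """Closed-form M-step vs direct numerical maximization of the
        expected complete-data log-likelihood on a 3-patient fixture."""
        df = tiny_dataset([12.0, 18.0, 9.0])
        est = pd.DataFrame(
            {
                "patient_id": ["S0", "S1", "S2"],
                "cl": [2.2, 3.1, 4.0],
                "v": [48.0, 61.0, 66.0],
                "var_cl": [0.05, 0.08, 0.03],
                "cov_cl_v": [0.01, -0.02, 0.0],
                "var_v": [3.0, 5.0, 2.0],
            }
        )
        fitted = m_step(est, df, CovariateSelection())
        m = np.column_stack([est["cl"], est["v"]])
        covs = np.array(
            [
                [[r["var_cl"], r["cov_cl_v"]], [r["cov_cl_v"], r["var_v"]]]
                for _, r in est.iterrows()
            ]
        )

        def neg_q(p):
            theta = p[:2]
            chol = np.array([[p[2], 0.0], [p[3], p[4]]])
            omega = chol @ chol.T
            oi = np.linalg.inv(omega)
            q = 0.0
            for i in range(3):
                r = m[i] - theta
                q += -0.5 * np.log(np.linalg.det(omega)) - 0.5 * np.trace(
                    oi @ (covs[i] + np.outer(r, r))
                )
            return -q

        start = np.array(
            [fitted.theta_cl[0], fitted.theta_v[0], 1.0, 0.0, 5.0]
        )
        res = minimize(neg_q, start, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
        assert fitted.theta_cl[0] == pytest.approx(res.x[0], abs=1e-4)
        assert fitted.theta_v[0] == pytest.approx(res.x[1], abs=1e-4)
        chol = np.array([[res.x[2], 0.0], [res.x[3], res.x[4]]])
        np.testing.assert_allclose(fitted.omega, chol @ chol.T, atol=1e-3)


class TestFitPopulation:
    def test_noiseless_recovery(self):
        """Zero IIV + tiny residual error: typical values back within 1%."""
        truth = intercept_only_model(3.16, 60.71, 1e-4, 1e-4, residual_cv=0.02)
        cohort = generate_cohort(CohortConfig(n_patients=40, seed=5, truth_model=truth))
        df = simulate_observations(cohort, truth, seed=5, n_troughs=1, p_peak=1.0)
        res = fit_population(df)
        assert res.converged
        assert res.model.theta_cl[0] == pytest.approx(3.16, rel=0.01)
        assert res.model.theta_v[0] == pytest.approx(60.71, rel=0.01)

    def test_loose_tolerance_single_iteration(self, final_truth):
        cohort = generate_cohort(CohortConfig(n_patients=20, seed=3, truth_model=final_truth))
        df = simulate_observations(cohort, final_truth, seed=3, n_troughs=1, p_peak=1.0)
        res = fit_population(df, tol=1.0)
        assert res.converged
        assert res.n_iterations == 1

    def test_patient_order_invariance(self, final_truth):
        cohort = generate_cohort(CohortConfig(n_patients=25, seed=7, truth_model=final_truth))
        df = simulate_observations(cohort, final_truth, seed=7, n_troughs=1, p_peak=1.0)
        res_a = fit_population(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res_b = fit_population(shuffled)
        assert res_a.model.theta_cl[0] == pytest.approx(res_b.model.theta_cl[0], abs=1e-10)
        assert res_a.model.theta_v[0] == pytest.approx(res_b.model.theta_v[0], abs=1e-10)
        a = res_a.individual_conditional_estimates.sort_values("patient_id")
        b = res_b.individual_conditional_estimates.sort_values("patient_id")
        np.testing.assert_allclose(a["cl"].to_numpy(), b["cl"].to_numpy(), atol=1e-10)

    def test_all_zero_concentrations_rejected(self):
        df = tiny_dataset([0.0, 0.0])
        with pytest.raises(EstimationError):
            fit_population(df)

    def test_nonpositive_init_rejected(self):
        df = tiny_dataset([10.0, 12.0])
        with pytest.raises(EstimationError):
            fit_population(df, init_cl=-1.0)

    def test_monotone_loglik_and_psd_omega(self, final_truth):
        cohort = generate_cohort(CohortConfig(n_patients=60, seed=21, truth_model=final_truth))
        df = simulate_observations(cohort, final_truth, seed=21, n_troughs=1, p_peak=1.0)
        est = EMPopulationFitter().fit(df)
        diffs = np.diff(est.loglik_trace_)
        assert diffs.min() > -1e-6
        assert min(est.omega_min_eig_trace_) > 0

    def test_sklearn_params_round_trip(self):
        est = EMPopulationFitter(cl_covariates=("Cr",), tol=0.005)
        params = est.get_params()
        clone = EMPopulationFitter(**params)
        assert clone.get_params() == params
        clone.set_params(tol=0.5)
        assert clone.tol == 0.5

    def test_predict_shapes(self, final_truth):
        cohort = generate_cohort(CohortConfig(n_patients=15, seed=9, truth_model=final_truth))
        df = simulate_observations(cohort, final_truth, seed=9, n_troughs=1, p_peak=1.0)
        est = EMPopulationFitter().fit(df)
        pop = est.predict(df)
        ind = est.predict_individual(df)
        assert pop.shape == (len(df),)
        assert ind.shape == (len(df),)
        # individual predictions should track the data more closely
        assert np.mean((ind - df["conc_ug_ml"]) ** 2) <= np.mean(
            (pop - df["conc_ug_ml"]) ** 2
        )
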