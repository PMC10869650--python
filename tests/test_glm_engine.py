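"""GLM engine: OLS equivalences, Park test recovery, link diagnostics,
family/link selection and recycled-prediction incremental means."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from trialcua import (
    ConfigError,
    EstimationError,
    ModelSpec,
    adjusted_mean_difference,
    fit_glm,
    link_diagnostics,
    modified_park_test,
    select_family_link,
)
from trialcua.glm_engine import FAMILY_ORDER


def sim_frame(rng, n=300, n_centres=10, arm_effect=0.0, log_scale=False):
    centre = rng.integers(1, n_centres + 1, n)
    arm = rng.integers(0, 2, n)
    age = rng.normal(50, 10, n)
    pfmt = rng.integers(0, 2, n)
    u_base = rng.uniform(0.5, 1.0, n)
    eta = 0.5 + 0.02 * age + 0.5 * u_base + arm_effect * arm
    if log_scale:
        y = np.exp(eta / 3) * rng.gamma(4, 1 / 4, n)
    else:
        y = eta + rng.normal(0, 1, n)
    return pd.DataFrame(
        {"y": y, "arm": arm, "age": age, "pfmt": pfmt, "u_baseline": u_base,
         "centre": centre}
    )


SPEC = ModelSpec(outcome="y")


class TestFitGlm:
    def test_gaussian_identity_equals_ols(self, rng):
        frame = sim_frame(rng)
        frame["centre"] = np.arange(len(frame))  # singleton clusters
        fit = fit_glm(frame, SPEC)
        X = sm.add_constant(frame[["arm", "u_baseline", "pfmt", "age"]])
        ols = sm.OLS(frame["y"], X).fit(cov_type="HC1")
        np.testing.assert_allclose(
            np.asarray(fit.params), np.asarray(ols.params), rtol=1e-10
        )
        # singleton-cluster sandwich equals the heteroscedasticity-robust form
        np.testing.assert_allclose(
            np.asarray(fit.cov_params), np.asarray(ols.cov_params()), rtol=1e-8
        )

    def test_gamma_log_coefficient_recovery(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.uniform(0, 1, n)
        arm = rng.integers(0, 2, n)
        mu = np.exp(0.5 + 0.8 * x + 0.3 * arm)
        y = rng.gamma(5, mu / 5)
        frame = pd.DataFrame({"y": y, "arm": arm, "x": x, "centre": rng.integers(1, 11, n)})
        spec = ModelSpec(outcome="y", covariates=("arm", "x"), family="gamma", link="log")
        fit = fit_glm(frame, spec)
        se = fit.result.bse["arm"]
        assert abs(fit.params["arm"] - 0.3) < 2 * se

    def test_duplicating_clusters_leaves_coefficients_unchanged(self, rng):
        frame = sim_frame(rng)
        doubled = pd.concat(
            [frame, frame.assign(centre=frame["centre"] + 100)], ignore_index=True
        )
        a = fit_glm(frame, SPEC)
        b = fit_glm(doubled, SPEC)
        np.testing.assert_allclose(np.asarray(a.params), np.asarray(b.params), rtol=1e-8)

    def test_singular_design_rejected(self, rng):
        frame = sim_frame(rng)
        frame["age"] = 1.0  # collinear with intercept
        with pytest.raises(EstimationError, match="singular"):
            fit_glm(frame, SPEC)

    def test_positive_family_rejects_nonpositive_outcome(self, rng):
        frame = sim_frame(rng)
        frame.loc[frame.index[0], "y"] = 0.0
        spec = ModelSpec(outcome="y", family="gamma", link="log")
        with pytest.raises(EstimationError, match="positive"):
            fit_glm(frame, spec)

    def test_arm_always_required(self):
        with pytest.raises(ConfigError):
            ModelSpec(outcome="y", covariates=("age",))

    def test_covariance_symmetric_psd(self, rng):
        fit = fit_glm(sim_frame(rng), SPEC)
        cov = np.asarray(fit.cov_params)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10


def park_mechanism(rng, lam, n=5000):
    """Outcomes with variance proportional to mean**lam."""
    x = rng.uniform(0, 1, n)
    arm = rng.integers(0, 2, n)
    mu = np.exp(0.5 + 1.2 * x)
    if lam == 0:
        y = mu + rng.normal(0, 1.0, n)
    elif lam == 1:
        y = rng.poisson(mu).astype(float)
    elif lam == 2:
        y = rng.gamma(4.0, mu / 4.0)
    else:  # lam == 3: inverse Gaussian with var = mu^3
        from scipy.stats import invgauss

        y = invgauss.rvs(mu, scale=1.0, random_state=rng)
    return pd.DataFrame({"y": y, "arm": arm, "x": x, "centre": rng.integers(1, 11, n)})


class TestParkTest:
    @pytest.mark.parametrize("lam,family", [(0, "gaussian"), (2, "gamma"), (3, "inverse_gaussian")])
    def test_family_recovery(self, lam, family):
        rng = np.random.default_rng(100 + lam)
        frame = park_mechanism(rng, lam)
        working = fit_glm(
            frame, ModelSpec(outcome="y", covariates=("arm", "x"), family="gaussian", link="log")
        )
        park = modified_park_test(frame["y"].to_numpy(), working)
        assert abs(park.lambda_ - lam) < 0.5
        assert park.recommended_family == family

    def test_nonpositive_fitted_rejected(self, rng):
        frame = sim_frame(rng)
        frame["y"] = frame["y"] - frame["y"].mean()  # centred -> negative fits
        working = fit_glm(frame, SPEC)
        with pytest.raises(EstimationError):
            modified_park_test(frame["y"].to_numpy(), working)


class TestLinkDiagnostics:
    def test_ols_residuals_orthogonal_to_fitted(self, rng):
        fit = fit_glm(sim_frame(rng), SPEC)
        resid = fit.outcome_values - fit.fitted
        corr = np.corrcoef(resid, fit.fitted)[0, 1]
        assert abs(corr) < 1e-10
        diag = link_diagnostics(fit)
        assert diag.pearson_p > 0.99

    def test_wrong_link_detected(self):
        # identity fit to strongly exponential-mean data
        rng = np.random.default_rng(8)
        hits = 0
        reps = 10
        for _ in range(reps):
            n = 800
            x = rng.uniform(0, 2.5, n)
            arm = rng.integers(0, 2, n)
            mu = np.exp(0.2 + 1.4 * x)
            y = mu + rng.normal(0, 1, n)
            frame = pd.DataFrame({"y": y, "arm": arm, "x": x, "centre": rng.integers(1, 6, n)})
            fit = fit_glm(frame, ModelSpec(outcome="y", covariates=("arm", "x")))
            if link_diagnostics(fit).pregibon_p < 0.05:
                hits += 1
        assert hits > reps / 2

    def test_few_fitted_values_warns(self, rng):
        frame = sim_frame(rng, n=100)
        frame["age"] = 0.0
        frame["u_baseline"] = 0.0
        frame["pfmt"] = 0
        fit = fit_glm(frame, ModelSpec(outcome="y", covariates=("arm",), cluster=None))
        with pytest.warns(UserWarning, match="distinct fitted"):
            link_diagnostics(fit)


class TestSelectFamilyLink:
    def test_cost_like_data_selects_inverse_gaussian_log(self):
        rng = np.random.default_rng(31)
        frame = park_mechanism(rng, 3)
        spec, log = select_family_link(
            frame, ModelSpec(outcome="y", covariates=("arm", "x"))
        )
        assert spec.family == "inverse_gaussian"
        assert spec.link == "log"
        assert any(entry.get("step") == "selected" for entry in log)

    def test_gaussian_homoscedastic_selects_gaussian(self, rng):
        frame = sim_frame(rng, n=2000)
        spec, _ = select_family_link(frame, SPEC)
        assert spec.family == "gaussian"

    def test_single_candidate_returned_unchanged(self, rng):
        frame = sim_frame(rng)
        spec, log = select_family_link(frame, SPEC, families=("gaussian",), links=("identity",))
        assert spec.family == "gaussian" and spec.link == "identity"


class TestAdjustedMeanDifference:
    def test_identity_link_equals_arm_coefficient(self, rng):
        fit = fit_glm(sim_frame(rng, arm_effect=0.4), SPEC)
        diff = adjusted_mean_difference(fit, method="delta")
        assert diff.estimate == pytest.approx(float(fit.params["arm"]), abs=1e-12)
        # delta-method variance equals the arm coefficient's sandwich variance
        assert diff.se**2 == pytest.approx(float(fit.cov_params.loc["arm", "arm"]), rel=1e-10)

    def test_log_link_toy_hand_arithmetic(self):
        # two patients per arm, arm-only model: recycled difference equals
        # the difference of the arm-specific means (log-link group MLE)
        frame = pd.DataFrame(
            {"y": [1.0, 2.0, 4.0, 8.0], "arm": [0, 0, 1, 1], "centre": [1, 1, 2, 2]}
        )
        spec = ModelSpec(
            outcome="y", covariates=("arm",), family="gamma", link="log", cluster=None
        )
        fit = fit_glm(frame, spec)
        diff = adjusted_mean_difference(fit, method="delta")
        assert diff.estimate == pytest.approx(6.0 - 1.5, abs=1e-8)

    def test_bootstrap_ci_contains_estimate(self, rng):
        fit = fit_glm(sim_frame(rng, n=200, arm_effect=0.5), SPEC)
        diff = adjusted_mean_difference(fit, method="cluster_bootstrap", n_boot=60, seed=1)
        assert diff.ci[0] <= diff.estimate <= diff.ci[1]

    def test_bootstrap_deterministic(self, rng):
        frame = sim_frame(rng, n=150)
        fit = fit_glm(frame, SPEC)
        a = adjusted_mean_difference(fit, method="cluster_bootstrap", n_boot=40, seed=5)
        b = adjusted_mean_difference(fit, method="cluster_bootstrap", n_boot=40, seed=5)
        assert a.ci == b.ci and a.se == b.se

    def test_family_order_complete(self):
        assert FAMILY_ORDER == ("gaussian", "poisson", "gamma", "inverse_gaussian")
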