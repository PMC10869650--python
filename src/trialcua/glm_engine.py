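"""Covariate-adjusted GLMs for costs and QALYs with family/link selection
diagnostics and cluster-robust inference.

Family choice follows the usual two-step screen for right-skewed outcome
data: a modified Park test (GLM regression of squared raw residuals on the
log fitted mean; the slope indexes the variance-to-mean power law) cross-
checked against AIC, then link checks (Pregibon, modified Hosmer-Lemeshow,
Pearson correlation of residuals with fitted values).  Incremental means
come from recycled predictions: every patient is predicted under both arms
and the prediction means are differenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .errors import ConfigError, ConvergenceError, EstimationError

FAMILY_ORDER = ("gaussian", "poisson", "gamma", "inverse_gaussian")

_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "gamma": sm.families.Gamma,
    "inverse_gaussian": sm.families.InverseGaussian,
}
_LINKS = {
    "identity": sm.families.links.Identity,
    "log": sm.families.links.Log,
}
#: families whose variance function requires a strictly positive outcome
_POSITIVE_FAMILIES = frozenset({"gamma", "inverse_gaussian"})


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, adjustment set, family/link and cluster variable."""

    outcome: str
    covariates: tuple = ("arm", "u_baseline", "pfmt", "age")
    family: str = "gaussian"
    link: str = "identity"
    cluster: str | None = "centre"

    def __post_init__(self):
        if "arm" not in self.covariates:
            raise ConfigError("the arm indicator must always be included")
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.link not in _LINKS:
            raise ConfigError(f"unknown link {self.link!r}")

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.covariates)


@dataclass
class GlmFitResult:
    """A fitted GLM plus the frame it was fitted on."""

    spec: ModelSpec
    result: object  # statsmodels GLMResults
    data: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def cov_params(self) -> pd.DataFrame:
        return self.result.cov_params()

    @property
    def fitted(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    @property
    def outcome_values(self) -> np.ndarray:
        return np.asarray(self.result.model.endog)


def _make_family(family: str, link: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _FAMILIES[family](link=_LINKS[link]())


def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> GlmFitResult:
    """Fit the GLM in ``spec`` with sandwich covariance clustered on centres.

    Raises :class:`EstimationError` for invalid outcomes or singular
    designs and :class:`ConvergenceError` (with the IRLS deviance trace)
    when the fit does not converge.
    """
    model_cols = [spec.outcome, *spec.covariates]
    if spec.cluster is not None:
        model_cols.append(spec.cluster)
    complete = data[model_cols].notna().all(axis=1)
    if not complete.all():
        data = data[complete]  # keep cluster groups aligned with the design
    if len(data) <= len(spec.covariates) + 1:
        raise EstimationError("too few complete rows to fit the model")
    y = data[spec.outcome]
    if spec.family in _POSITIVE_FAMILIES and (y <= 0).any():
        raise EstimationError(
            f"family {spec.family!r} requires a strictly positive outcome; "
            f"{int((y <= 0).sum())} non-positive values in {spec.outcome!r}"
        )
    if spec.family == "poisson" and (y < 0).any():
        raise EstimationError("poisson-type family requires a non-negative outcome")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(
            spec.formula, data=data, family=_make_family(spec.family, spec.link)
        )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise EstimationError(
            f"singular design: rank {rank} < {model.exog.shape[1]} columns"
        )
    fit_kwargs = {"maxiter": 200}
    if spec.cluster is not None:
        fit_kwargs.update(
            cov_type="cluster", cov_kwds={"groups": np.asarray(data[spec.cluster])}
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(**fit_kwargs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise EstimationError(f"GLM estimation failed: {exc}") from exc
    trace = list(getattr(result, "fit_history", {}).get("deviance", []))
    if not getattr(result, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge in {fit_kwargs['maxiter']} iterations",
            trace=trace,
        )
    if not np.isfinite(result.params).all():
        raise EstimationError("non-finite coefficients")
    return GlmFitResult(spec=spec, result=result, data=data)


@dataclass(frozen=True)
class ParkTest:
    lambda_: float
    se: float
    recommended_family: str


def modified_park_test(y: np.ndarray, fit: GlmFitResult) -> ParkTest:
    """Slope of squared raw residuals on log fitted mean (Gamma/log GLM).

    Nearest-integer slope maps to the family: 0 Gaussian, 1 Poisson-type,
    2 Gamma, 3 inverse Gaussian.  Requires strictly positive fitted values.
    """
    mu = fit.fitted
    if (mu <= 0).any():
        raise EstimationError("Park test requires strictly positive fitted values")
    y = np.asarray(y, dtype=float)
    resid2 = (y - mu) ** 2
    floor = 1e-12 * max(float(resid2.mean()), 1e-300)
    resid2 = np.maximum(resid2, floor)  # Gamma deviance needs positive response
    X = sm.add_constant(np.log(mu))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        park = sm.GLM(
            resid2, X, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit(maxiter=200)
    lam = float(park.params[1])
    se = float(park.bse[1])
    idx = int(np.clip(np.round(lam), 0, len(FAMILY_ORDER) - 1))
    return ParkTest(lambda_=lam, se=se, recommended_family=FAMILY_ORDER[idx])


@dataclass(frozen=True)
class LinkDiagnostics:
    pregibon_p: float
    hosmer_lemeshow_p: float
    pearson_p: float

    def passes(self, alpha: float = 0.05) -> int:
        return sum(
            1
            for p in (self.pregibon_p, self.hosmer_lemeshow_p, self.pearson_p)
            if np.isfinite(p) and p > alpha
        )


def link_diagnostics(fit: GlmFitResult, groups: int = 10) -> LinkDiagnostics:
    """Pregibon link test, modified Hosmer-Lemeshow and Pearson correlation.

    Pregibon refits with the squared linear predictor added and reports its
    coefficient's p-value; modified HL F-tests that the mean raw-scale
    residual is zero across deciles of the fitted values (fewer groups are
    used, with a warning, when fitted values tie); Pearson tests the
    correlation between raw residuals and fitted values.
    """
    res = fit.result
    mu = fit.fitted
    y = fit.outcome_values
    resid = y - mu

    eta = res.model.exog @ np.asarray(res.params)
    X_aug = np.column_stack([res.model.exog, eta**2])
    pregibon_p = float("nan")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aug = sm.GLM(
                y, X_aug, family=_make_family(fit.spec.family, fit.spec.link)
            ).fit(maxiter=200)
        pregibon_p = float(aug.pvalues[-1])
    except Exception:
        pass

    n_unique = len(np.unique(mu))
    if n_unique < groups:
        warnings.warn(
            f"only {n_unique} distinct fitted values; reducing HL groups",
            stacklevel=2,
        )
    hl_p = float("nan")
    try:
        cut = pd.qcut(mu, min(groups, n_unique), labels=False, duplicates="drop")
        dummies = pd.get_dummies(cut, dtype=float).to_numpy()
        if dummies.shape[1] >= 2:
            ols = sm.OLS(resid, dummies).fit()
            hl = ols.f_test(np.eye(dummies.shape[1]))
            hl_p = float(hl.pvalue)
    except Exception:
        pass

    try:
        pearson_p = float(st.pearsonr(resid, mu).pvalue)
    except Exception:
        pearson_p = float("nan")

    return LinkDiagnostics(
        pregibon_p=pregibon_p, hosmer_lemeshow_p=hl_p, pearson_p=pearson_p
    )


def select_family_link(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    families: Sequence[str] = FAMILY_ORDER,
    links: Sequence[str] = ("identity", "log"),
):
    """Pick family by modified Park test cross-checked against AIC, then the
    link by diagnostic pass count.

    Returns ``(spec, decision_log)``.  When Park and AIC disagree on
    adjacent families the Park recommendation wins; wider disagreement
    falls back to AIC.  A single candidate is returned unchanged.  Families
    requiring positivity are excluded when the outcome has non-positive
    values.
    """
    families = list(families)
    log: list[dict] = []
    y = data[base_spec.outcome].to_numpy(dtype=float)
    if (y <= 0).any():
        dropped = [f for f in families if f in _POSITIVE_FAMILIES or f == "poisson"]
        families = [f for f in families if f not in dropped]
        if dropped:
            log.append({"step": "positivity", "excluded": dropped})
    if not families:
        raise EstimationError("no admissible family for this outcome")
    if len(families) == 1 and len(links) == 1:
        spec = replace(base_spec, family=families[0], link=links[0])
        log.append({"step": "single_candidate", "spec": spec})
        return spec, log

    # working fit for the Park test: log link keeps fitted values positive
    work_link = "log" if (y > 0).all() else "identity"
    working = fit_glm(data, replace(base_spec, family="gaussian", link=work_link))
    park = modified_park_test(y, working)
    log.append({"step": "park", "lambda": park.lambda_, "recommended": park.recommended_family})

    aics = {}
    for family in families:
        link = "log" if (family != "gaussian" and "log" in links) else (
            "log" if work_link == "log" and "log" in links else "identity"
        )
        try:
            aics[family] = fit_glm(data, replace(base_spec, family=family, link=link)).aic
        except (EstimationError, ConvergenceError):
            aics[family] = float("inf")
    aic_family = min(aics, key=aics.get)
    log.append({"step": "aic", "aics": aics, "recommended": aic_family})

    park_family = park.recommended_family
    if park_family not in families:
        family = aic_family
        log.append({"step": "family", "chosen": family, "note": "park choice inadmissible"})
    elif park_family == aic_family:
        family = park_family
        log.append({"step": "family", "chosen": family, "note": "park and AIC agree"})
    else:
        adjacent = abs(FAMILY_ORDER.index(park_family) - FAMILY_ORDER.index(aic_family)) == 1
        family = park_family if adjacent else aic_family
        log.append(
            {
                "step": "family",
                "chosen": family,
                "note": f"DISAGREEMENT park={park_family} aic={aic_family}; "
                + ("park wins (adjacent)" if adjacent else "aic wins (non-adjacent)"),
            }
        )

    best_link, best_passes = None, -1
    for link in links:
        try:
            cand = fit_glm(data, replace(base_spec, family=family, link=link))
        except (EstimationError, ConvergenceError):
            continue
        passes = link_diagnostics(cand).passes()
        log.append({"step": "link", "link": link, "passes": passes})
        preferred = "log" if family != "gaussian" else "identity"
        if passes > best_passes or (passes == best_passes and link == preferred):
            best_link, best_passes = link, passes
    if best_link is None:
        raise EstimationError("no candidate link could be fitted")
    spec = replace(base_spec, family=family, link=best_link)
    log.append({"step": "selected", "family": family, "link": best_link})
    return spec, log


@dataclass(frozen=True)
class AdjustedDifference:
    estimate: float
    se: float
    ci: tuple
    method: str


def recycled_difference(result, data: pd.DataFrame, arm: str) -> float:
    d1 = data.copy()
    d0 = data.copy()
    d1[arm] = 1
    d0[arm] = 0
    return float(np.mean(result.predict(d1)) - np.mean(result.predict(d0)))


def adjusted_mean_difference(
    fit: GlmFitResult,
    arm: str = "arm",
    method: str = "cluster_bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AdjustedDifference:
    """Incremental mean by recycled predictions, with CI.

    ``method='cluster_bootstrap'`` resamples centres (aligning with the
    clustered analysis) and refits; ``method='delta'`` propagates the
    cluster-robust coefficient covariance through the prediction-mean
    gradient.  For an identity link the estimate equals the arm
    coefficient exactly.
    """
    if arm not in fit.spec.covariates:
        raise ConfigError(f"{arm!r} not in the model covariates")
    res = fit.result
    data = fit.data
    estimate = recycled_difference(res, data, arm)

    if method == "delta":
        design_info = res.model.data.design_info
        d1 = data.copy()
        d0 = data.copy()
        d1[arm] = 1
        d0[arm] = 0
        (X1,) = build_design_matrices([design_info], d1)
        (X0,) = build_design_matrices([design_info], d0)
        X1 = np.asarray(X1)
        X0 = np.asarray(X0)
        beta = np.asarray(res.params)
        link = res.model.family.link
        g1 = link.inverse_deriv(X1 @ beta)
        g0 = link.inverse_deriv(X0 @ beta)
        grad = (X1 * g1[:, None]).mean(axis=0) - (X0 * g0[:, None]).mean(axis=0)
        variance = float(grad @ np.asarray(res.cov_params()) @ grad)
        se = float(np.sqrt(max(variance, 0.0)))
        if fit.spec.cluster is not None:
            n_clusters = data[fit.spec.cluster].nunique()
            quantile = st.t.ppf(1 - alpha / 2, max(n_clusters - 1, 1))
        else:
            quantile = st.norm.ppf(1 - alpha / 2)
        ci = (estimate - quantile * se, estimate + quantile * se)
        return AdjustedDifference(estimate=estimate, se=se, ci=ci, method="delta")

    if method != "cluster_bootstrap":
        raise ConfigError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    cluster = fit.spec.cluster
    draws = []
    for _ in range(n_boot):
        if cluster is not None:
            ids = data[cluster].unique()
            chosen = rng.choice(ids, size=len(ids), replace=True)
            parts = []
            for k, cid in enumerate(chosen):
                part = data[data[cluster] == cid].copy()
                part[cluster] = k  # keep resampled clusters distinct
                parts.append(part)
            sample = pd.concat(parts, ignore_index=True)
        else:
            sample = data.sample(n=len(data), replace=True, random_state=rng.integers(2**31))
        try:
            refit = fit_glm(sample, fit.spec)
        except (EstimationError, ConvergenceError):
            continue
        draws.append(recycled_difference(refit.result, sample, arm))
    draws = np.asarray(draws)
    if len(draws) < max(10, n_boot // 2):
        raise EstimationError("too many bootstrap replicates failed")
    ci = (
        float(np.quantile(draws, alpha / 2)),
        float(np.quantile(draws, 1 - alpha / 2)),
    )
    return AdjustedDifference(
        estimate=estimate, se=float(draws.std(ddof=1)), ci=ci, method="cluster_bootstrap"
    )
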