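"""Missingness diagnostics, predictive-mean-matching multiple imputation,
and Rubin's-rules pooling.

The imputation is "proper": each of the ``m`` completed datasets is built
from a fresh approximate Bayesian draw of the regression coefficients and
residual variance, so between-imputation variance is a valid component of
Rubin's total variance.  Matching is type-1 PMM: donors are the ``knn``
observed cases whose OLS predictions are nearest the drawn-parameter
prediction of the missing case; equidistant donors all enter the pool
before the uniform draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ConfigError, InsufficientDataError

MI_THRESHOLD = 0.05  # fraction missing above which MI is triggered


@dataclass(frozen=True)
class VariableMissingness:
    variable: str
    fraction: float
    coefficients: Mapping[str, float]
    pvalues: Mapping[str, float]
    converged: bool

    @property
    def mi_triggered(self) -> bool:
        return self.fraction > MI_THRESHOLD


@dataclass(frozen=True)
class MissingnessReport:
    variables: Mapping[str, VariableMissingness]

    @property
    def mi_triggered(self) -> bool:
        return any(v.mi_triggered for v in self.variables.values())

    def frame(self) -> pd.DataFrame:
        rows = []
        for name, v in self.variables.items():
            row = {
                "variable": name,
                "fraction_missing": v.fraction,
                "mi_triggered": v.mi_triggered,
                "converged": v.converged,
            }
            for term, coef in v.coefficients.items():
                row[f"coef[{term}]"] = coef
                row[f"p[{term}]"] = v.pvalues.get(term, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def missingness_model(
    frame: pd.DataFrame,
    variables: Sequence[str],
    formula_rhs: str = "age + pfmt + u_baseline + C(baseline_ui_type)",
) -> MissingnessReport:
    """Logistic model of each variable's missing indicator on baseline covariates.

    Separation or non-convergence is reported (``converged=False``) rather
    than raised.  Variables with no missing (or no observed) values get an
    empty coefficient table.
    """
    out = {}
    work = frame.copy()
    for var in variables:
        indicator = work[var].isna().astype(int)
        fraction = float(indicator.mean())
        coefs, pvals, converged = {}, {}, False
        if 0.0 < fraction < 1.0:
            work["_missing"] = indicator
            try:
                fit = smf.glm(
                    f"_missing ~ {formula_rhs}", data=work, family=sm.families.Binomial()
                ).fit(maxiter=100)
                converged = bool(fit.converged) and bool(
                    np.isfinite(fit.params).all() and np.isfinite(fit.bse).all()
                )
                coefs = dict(fit.params)
                pvals = dict(fit.pvalues)
            except Exception:
                converged = False
        out[var] = VariableMissingness(
            variable=var,
            fraction=fraction,
            coefficients=coefs,
            pvalues=pvals,
            converged=converged,
        )
    return MissingnessReport(variables=out)


@dataclass
class ImputationSet:
    """``m`` completed copies of an analysis frame plus provenance."""

    datasets: list
    m: int
    knn: int
    seed: int
    columns: tuple
    predictors: tuple

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return len(self.datasets)

    def __getitem__(self, i):
        return self.datasets[i]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.datasets):
            frame.to_csv(directory / f"imputation_{i:02d}.csv", index=True)
        manifest = {
            "m": self.m,
            "knn": self.knn,
            "seed": self.seed,
            "columns": list(self.columns),
            "predictors": list(self.predictors),
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")


def _design_matrix(frame: pd.DataFrame, predictors: Sequence[str]):
    X = pd.get_dummies(frame[list(predictors)], drop_first=True, dtype=float)
    X.insert(0, "Intercept", 1.0)
    return X.to_numpy(dtype=float)


def impute_pmm(
    frame: pd.DataFrame,
    columns: Sequence[str],
    m: int = 20,
    knn: int = 5,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
    proper: bool = True,
) -> ImputationSet:
    """Multiply impute ``columns`` by predictive mean matching.

    For each target column with missing values: regress on ``predictors``
    among observed cases; per imputation draw residual variance from its
    scaled inverse chi-square and coefficients from their sampling normal
    (skipped when ``proper`` is off); predict; match each missing case to
    its ``knn`` nearest observed predictions and copy one donor's observed
    value, chosen uniformly.  Columns without missing values are returned
    unchanged in every copy.
    """
    if m < 1:
        raise ConfigError("m must be >= 1")
    if knn < 1:
        raise ConfigError("knn must be >= 1")
    columns = list(columns)
    for col in columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ConfigError(f"imputation target {col!r} must be numeric")
    if predictors is None:
        predictors = [c for c in frame.columns if c not in columns]
    predictors = tuple(predictors)
    X = _design_matrix(frame, predictors)
    rng = np.random.default_rng(seed)
    completed = [frame.copy() for _ in range(m)]

    for col in columns:
        y = frame[col].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        n_mis = int((~obs).sum())
        if n_mis == 0:
            continue
        n_obs = int(obs.sum())
        if n_obs < max(knn, X.shape[1] + 1):
            raise InsufficientDataError(
                f"{col!r}: {n_obs} complete cases < required "
                f"max(knn={knn}, p+1={X.shape[1] + 1})"
            )
        Xo, yo = X[obs], y[obs]
        beta, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ beta
        sse = float(resid @ resid)
        df_resid = max(n_obs - rank, 1)
        xtx_inv = np.linalg.pinv(Xo.T @ Xo)
        pred_obs = Xo @ beta
        mis_idx = np.flatnonzero(~obs)
        for i in range(m):
            if proper:
                sigma2 = sse / rng.chisquare(df_resid)
                cov = sigma2 * xtx_inv
                cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(len(beta))
                try:
                    chol = np.linalg.cholesky(cov)
                    beta_i = beta + chol @ rng.standard_normal(len(beta))
                except np.linalg.LinAlgError:
                    beta_i = rng.multivariate_normal(beta, cov, method="svd")
            else:
                beta_i = beta
            pred_mis = X[mis_idx] @ beta_i
            dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
            kth = np.partition(dist, knn - 1, axis=1)[:, knn - 1]
            values = np.empty(n_mis)
            for r in range(n_mis):
                donors = np.flatnonzero(dist[r] <= kth[r] + 1e-12)
                values[r] = yo[rng.choice(donors)]
            completed[i].loc[frame.index[mis_idx], col] = values

    return ImputationSet(
        datasets=completed,
        m=m,
        knn=knn,
        seed=seed,
        columns=tuple(columns),
        predictors=predictors,
    )


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    within: float
    between: float
    df: float
    ci: tuple
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def rubins_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool ``m`` per-imputation estimates and variances by Rubin's rules.

    pooled = mean(estimates); T = W + (1 + 1/m) B with W the mean
    within-imputation variance and B the between-imputation sample variance;
    degrees of freedom by the standard small-sample formula; CI from the
    t distribution (normal when B = 0).
    """
    est = np.asarray(list(estimates), dtype=float)
    var = np.asarray(list(variances), dtype=float)
    if est.shape != var.shape:
        raise ConfigError("estimates and variances must have the same length")
    m = len(est)
    if m < 1:
        raise ConfigError("need at least one estimate")
    pooled = float(est.mean())
    if m == 1:
        total = float(var[0])
        half = st.norm.ppf(1 - alpha / 2) * np.sqrt(total)
        return PooledEstimate(
            estimate=pooled, variance=total, within=total, between=0.0,
            df=float("inf"), ci=(pooled - half, pooled + half), m=1,
        )
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        with np.errstate(over="ignore"):
            df = float((m - 1) * (1.0 + np.float64(within) / ((1.0 + 1.0 / m) * np.float64(between))) ** 2)
        quantile = st.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else st.norm.ppf(1 - alpha / 2)
    else:
        df = float("inf")
        quantile = st.norm.ppf(1 - alpha / 2)
    half = quantile * np.sqrt(total)
    return PooledEstimate(
        estimate=pooled, variance=float(total), within=within, between=between,
        df=float(df), ci=(pooled - half, pooled + half), m=m,
    )
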