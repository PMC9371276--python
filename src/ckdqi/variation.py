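"""Physician-level variation of QI achievement.

Random-intercept logistic regression: for patient *i* of cluster (GP) *g*,

    logit P(y_ig = 1) = x_ig' beta + b_g,   b_g ~ N(0, sigma_b^2).

The marginal likelihood integrates the cluster intercepts out; here each
one-dimensional integral is approximated by the Laplace method (default)
or adaptive Gauss-Hermite quadrature with a configurable node count, and
the approximate likelihood is maximised by bounded quasi-Newton over
(beta, log sigma_b). Predicted intercepts are the posterior modes of the
b_g at the maximum-likelihood estimates.

Between-cluster variation is summarised on two scales:

* latent-scale intraclass correlation, ICC = sigma_b^2 / (sigma_b^2 + pi^2/3),
  the share of latent outcome variance attributable to the GP;
* range odds ratio, rOR = exp(q95 - q05) of the predicted intercepts —
  the odds multiplier separating a 95th- from a 5th-percentile GP. The
  central 90% range de-emphasises outlying clusters.

Both are conventionally read off the *null* model, which omits GP-level
fixed effects so that GP influence loads entirely on the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, logsumexp

Z_95 = 1.959964  # two-sided 95% normal quantile

#: fixed effects describing the GP rather than the patient
GP_LEVEL_EFFECTS = ("gp_gender", "gp_age_cat", "urban_location")


class FitError(RuntimeError):
    """Model could not be fitted (degenerate data or non-convergence)."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    fixed_effects: tuple[str, ...]
    cluster: str = "gp_id"
    variant: str = "full"  # 'full' | 'null'

    def effects(self) -> tuple[str, ...]:
        if self.variant == "null":
            return tuple(e for e in self.fixed_effects if e not in GP_LEVEL_EFFECTS)
        return self.fixed_effects


@dataclass
class FittedClusterModel:
    beta: pd.Series                 # log-odds scale, incl. intercept
    beta_cov: pd.DataFrame
    sigma2_b: float
    intercepts: pd.Series           # posterior modes, index = cluster id
    loglik: float
    n_obs: int
    n_clusters: int
    converged: bool
    spec: ModelSpec | None = None

    @property
    def sigma_b(self) -> float:
        return float(np.sqrt(self.sigma2_b))


def _design_matrix(df: pd.DataFrame, effects) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for categoricals, numeric as-is."""
    X = pd.DataFrame({"(Intercept)": np.ones(len(df))}, index=df.index)
    for col in effects:
        s = df[col]
        if s.dtype == bool:
            X[col] = s.astype(float)
        elif s.dtype.kind in "ifu":
            X[col] = s.astype(float)
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
    return X


def _cluster_loglik_terms(y, eta, idx, n_clusters):
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(idx, weights=ll, minlength=n_clusters)


def _find_modes(y, eta0, idx, n_clusters, sigma2, b, max_iter=100, tol=1e-10):
    """Vectorised Newton ascent for the per-cluster posterior modes."""
    inv_s2 = 1.0 / sigma2
    for _ in range(max_iter):
        eta = eta0 + b[idx]
        mu = expit(eta)
        grad = np.bincount(idx, weights=y - mu, minlength=n_clusters) - b * inv_s2
        W = np.bincount(idx, weights=mu * (1.0 - mu), minlength=n_clusters) + inv_s2
        step = grad / W
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(grad)) < tol:
            break
    eta = eta0 + b[idx]
    mu = expit(eta)
    W = np.bincount(idx, weights=mu * (1.0 - mu), minlength=n_clusters) + inv_s2
    return b, W


def _approx_loglik(params, X, y, idx, n_clusters, b_work, agh_nodes=1):
    """Laplace (agh_nodes=1) or adaptive Gauss-Hermite marginal loglik."""
    beta, log_sigma = params[:-1], params[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    b, W = _find_modes(y, eta0, idx, n_clusters, sigma2, b_work)
    if agh_nodes <= 1:
        ll_data = _cluster_loglik_terms(y, eta0 + b[idx], idx, n_clusters)
        per_cluster = ll_data - 0.5 * b**2 / sigma2 - 0.5 * np.log(sigma2 * W)
        return float(per_cluster.sum()), b
    nodes, weights = np.polynomial.hermite.hermgauss(agh_nodes)
    scale = np.sqrt(2.0 / W)  # (n_clusters,)
    # h(b) = data loglik + N(0, sigma2) log-density, evaluated at shifted nodes
    terms = np.empty((agh_nodes, n_clusters))
    for k, (x_k, w_k) in enumerate(zip(nodes, weights)):
        b_k = b + scale * x_k
        ll_data = _cluster_loglik_terms(y, eta0 + b_k[idx], idx, n_clusters)
        h = ll_data - 0.5 * b_k**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        terms[k] = np.log(w_k) + x_k**2 + h
    per_cluster = np.log(scale) + logsumexp(terms, axis=0)
    return float(per_cluster.sum()), b


def _num_hessian(f, x, rel_step=1e-4):
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_random_intercept_logistic(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects=(),
    cluster: str = "gp_id",
    *,
    agh_nodes: int = 1,
    start_sigma_b: float = 0.5,
    tol: float = 1e-8,
    spec: ModelSpec | None = None,
) -> FittedClusterModel:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Rows with any missing outcome/covariate/cluster value are removed
    first (listwise deletion). ``agh_nodes=1`` gives the Laplace
    approximation; larger odd counts give adaptive Gauss-Hermite.

    Raises
    ------
    FitError
        For a single cluster, a constant outcome, or non-convergence.
    """
    cols = [outcome, cluster, *fixed_effects]
    df = data[cols].dropna()
    y = df[outcome].astype(float).to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        raise FitError("outcome must be binary 0/1")
    codes, uniques = pd.factorize(df[cluster], sort=True)
    n_clusters = len(uniques)
    if n_clusters < 2:
        raise FitError("need at least 2 clusters")
    if y.min() == y.max():
        raise FitError("outcome is constant after listwise deletion")

    X_df = _design_matrix(df, fixed_effects)
    X = X_df.to_numpy(dtype=float)
    names = list(X_df.columns)
    p = X.shape[1]

    # starting values: plain logistic fit (separation etc. only degrades the
    # start point, so its warnings are irrelevant here)
    import warnings

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
        if not np.all(np.isfinite(start_beta)) or np.max(np.abs(start_beta)) > 20:
            raise ValueError
    except Exception:
        start_beta = np.zeros(p)
        start_beta[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    x0 = np.append(start_beta, np.log(start_sigma_b))

    b_work = np.zeros(n_clusters)

    def nll(params):
        ll, b = _approx_loglik(params, X, y, codes, n_clusters, b_work, agh_nodes)
        b_work[:] = b
        return -ll

    bounds = [(None, None)] * p + [(-7.0, 3.0)]
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise FitError(f"optimizer failed: {res.message}")

    theta = res.x
    loglik, b_hat = _approx_loglik(theta, X, y, codes, n_clusters, b_work, agh_nodes)
    sigma2_b = float(np.exp(2.0 * theta[-1]))

    H = _num_hessian(nll, theta)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    beta_cov = pd.DataFrame(cov_all[:p, :p], index=names, columns=names)

    return FittedClusterModel(
        beta=pd.Series(theta[:p], index=names),
        beta_cov=beta_cov,
        sigma2_b=sigma2_b,
        intercepts=pd.Series(b_hat, index=pd.Index(uniques, name=cluster)),
        loglik=float(loglik),
        n_obs=len(df),
        n_clusters=n_clusters,
        converged=bool(res.success),
        spec=spec,
    )


def odds_ratios(model: FittedClusterModel) -> pd.DataFrame:
    """Fixed-effect odds ratios with Wald 95% confidence intervals."""
    diag = np.diag(model.beta_cov.to_numpy())
    # a negative variance from the numeric Hessian marks an unidentified
    # coefficient; report a missing SE rather than a spurious one
    se = np.where(diag >= 0, np.sqrt(np.maximum(diag, 0.0)), np.nan)
    beta = model.beta.to_numpy()
    with np.errstate(over="ignore"):  # near-separation gives an unbounded CI
        return pd.DataFrame(
            {
                "covariate": model.beta.index,
                "or": np.exp(beta),
                "ci_low": np.exp(beta - Z_95 * se),
                "ci_high": np.exp(beta + Z_95 * se),
            }
        )


def icc_latent(sigma2_b: float) -> float:
    """Latent-scale ICC: sigma2_b / (sigma2_b + pi^2/3)."""
    if sigma2_b < 0:
        raise ValueError("sigma2_b must be non-negative")
    return float(sigma2_b / (sigma2_b + np.pi**2 / 3.0))


def range_or(intercepts) -> float:
    """exp(q95 - q05) over predicted cluster intercepts (central 90% range).

    Percentiles use linear interpolation between order statistics.
    """
    arr = np.asarray(intercepts, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 cluster intercepts")
    q05, q95 = np.percentile(arr, [5.0, 95.0])
    return float(np.exp(q95 - q05))


@dataclass
class VariationSummary:
    """Per-QI variation report: full-model ORs, null-model ICC and rOR."""

    qi_id: int
    or_table: pd.DataFrame
    icc: float
    ror: float
    full_model: FittedClusterModel | None = None
    null_model: FittedClusterModel | None = None
    achievement_rate: float = float("nan")


def analyse_qi_variation(
    qi_result,
    covariates: pd.DataFrame,
    fixed_effects=None,
    *,
    agh_nodes: int = 1,
    keep_models: bool = True,
) -> VariationSummary:
    """Fit the full and null models for one QI's achievement flags.

    ``covariates`` is a per-patient table (keyed ``patient_id``) carrying
    the model covariates; patients of "other" gender are excluded from the
    model rows, and listwise deletion handles remaining missingness. The
    OR table comes from the full model; ICC and rOR from the null model.
    """
    rows = qi_result.per_patient.merge(
        covariates.drop(columns=["gp_id"], errors="ignore"), on="patient_id", how="left"
    )
    if "patient_gender" in rows:
        rows = rows.loc[rows["patient_gender"] != "other"]
    if fixed_effects is None:
        fixed_effects = tuple(
            c
            for c in (
                "patient_gender",
                "patient_age_cat",
                "has_diabetes",
                "has_hypertension",
                "has_ecvd",
                "gp_gender",
                "gp_age_cat",
                "urban_location",
            )
            if c in rows.columns
        )
    rows = rows.copy()
    rows["achieved"] = rows["achieved"].astype(float)

    full_spec = ModelSpec("achieved", tuple(fixed_effects), "gp_id", "full")
    null_spec = ModelSpec("achieved", tuple(fixed_effects), "gp_id", "null")
    full = fit_random_intercept_logistic(
        rows, "achieved", full_spec.effects(), "gp_id", agh_nodes=agh_nodes, spec=full_spec
    )
    null = fit_random_intercept_logistic(
        rows, "achieved", null_spec.effects(), "gp_id", agh_nodes=agh_nodes, spec=null_spec
    )
    return VariationSummary(
        qi_id=qi_result.qi_id,
        or_table=odds_ratios(full),
        icc=icc_latent(null.sigma2_b),
        ror=range_or(null.intercepts),
        full_model=full if keep_models else None,
        null_model=null if keep_models else None,
        achievement_rate=qi_result.achievement_rate,
    )
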