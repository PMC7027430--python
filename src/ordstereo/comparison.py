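"""Comparator model families under the shared FitResult contract.

Three families the stereotype model is routinely benchmarked against:

* proportional odds (cumulative logit), oriented as
  ``logit P(Y <= k | x) = alpha_k + beta' x`` — note a *positive* beta
  increases the probability of lower categories under this convention;
* baseline-category logit (unrestricted multinomial logistic regression),
  which nests the stereotype model;
* ordinary least squares on the raw 1..q codes, the "treat it as
  continuous" strawman.

Estimation is delegated to statsmodels (OrderedModel, MNLogit, OLS); the
results are normalized into :class:`~ordstereo.results.FitResult` so AIC
and BIC are computed from the one shared formula across families.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .data import OrdinalDataset
from .results import FitResult
from .stereotype import FitOptions, fit_stereotype

__all__ = [
    "PropOddsParams",
    "BaselineLogitParams",
    "LinearParams",
    "fit_proportional_odds",
    "fit_baseline_logit",
    "fit_linear",
    "coef_test",
]


class PropOddsParams:
    """Cut intercepts alpha_1..alpha_{q-1} (strictly increasing) and beta."""

    def __init__(self, alpha: np.ndarray, beta: np.ndarray):
        self.alpha = np.asarray(alpha, dtype=float)
        self.beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if np.any(np.diff(self.alpha) <= 0):
            raise ValueError("cut intercepts must be strictly increasing")


class BaselineLogitParams:
    """Intercepts alpha_2..alpha_q and a (q-1) x p slope matrix."""

    def __init__(self, alpha: np.ndarray, beta_mat: np.ndarray):
        self.alpha = np.asarray(alpha, dtype=float)
        self.beta_mat = np.atleast_2d(np.asarray(beta_mat, dtype=float))
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta_mat).all()):
            raise ValueError("parameters must be finite")


class LinearParams:
    """OLS intercept, slopes, and residual variance."""

    def __init__(self, intercept: float, beta: np.ndarray, sigma2: float):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        self.intercept = float(intercept)
        self.beta = np.atleast_1d(np.asarray(beta, dtype=float))
        self.sigma2 = float(sigma2)


def _wald_ci(est, se, level):
    z = stats.norm.ppf(0.5 + level / 2.0)
    return np.column_stack([est - z * se, est + z * se])


def fit_proportional_odds(data: OrdinalDataset, ci_level: float = 0.95) -> FitResult:
    """ML fit of the cumulative-logit proportional odds model.

    Reported on the orientation ``logit P(Y <= k) = alpha_k + beta' x``
    (the underlying statsmodels fit uses ``F(cut_k - x'b)``; slopes are
    sign-flipped accordingly and cut SEs are delta-mapped from the
    increment parametrization).
    """
    q, p, n = data.q, data.p, data.n
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = OrderedModel(data.y, data.X, distr="logit")
        res = model.fit(method="bfgs", disp=0, maxiter=500)
    converged = bool(res.mle_retvals.get("converged", True))
    raw = res.params  # [slopes (p), threshold params (q-1)]
    cuts_full = model.transform_threshold_params(raw)
    alpha = np.asarray(cuts_full[1:q], dtype=float)  # finite cuts
    beta = -raw[:p]

    # delta method: cuts = [t0, t0+exp(t1), t0+exp(t1)+exp(t2), ...]
    cov = np.asarray(res.cov_params())
    J = np.zeros((q - 1 + p, q - 1 + p))
    J[:p, :p] = -np.eye(p)
    thr = raw[p:]
    for k in range(q - 1):
        J[p + k, p] = 1.0
        for j in range(1, k + 1):
            J[p + k, p + j] = np.exp(thr[j])
    cov_rep = J @ cov @ J.T
    se = np.sqrt(np.clip(np.diag(cov_rep), 0.0, None))
    se_beta, se_alpha = se[:p], se[p:]

    names = [f"alpha{k}" for k in range(1, q)] + list(data.column_names)
    est = np.concatenate([alpha, beta])
    se_all = np.concatenate([se_alpha, se_beta])
    n_params = (q - 1) + p
    return FitResult(
        family="proportional_odds",
        params=PropOddsParams(alpha, beta),
        param_names=names,
        estimates=est,
        loglik=float(res.llf),
        n_params=n_params,
        n_obs=n,
        se=se_all,
        ci=_wald_ci(est, se_all, ci_level),
        ci_level=ci_level,
        converged=converged,
        data=data,
        extra={"sm_result": res},
    )


def fit_baseline_logit(data: OrdinalDataset, ci_level: float = 0.95) -> FitResult:
    """ML fit of the baseline-category (multinomial) logit model.

    The first ordinal level is the reference; the fit has
    ``(q-1)(p+1)`` free parameters and its log-likelihood bounds every
    stereotype fit on the same data from above (the stereotype model is
    the special case ``beta_k = phi_k * beta``).
    """
    q, p, n = data.q, data.p, data.n
    exog = sm.add_constant(data.X, has_constant="add")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = sm.MNLogit(data.y - 1, exog)
        try:
            res = model.fit(method="newton", disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except np.linalg.LinAlgError:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
            converged = bool(res.mle_retvals.get("converged", True))
    coefs = np.asarray(res.params)  # (p+1, q-1)
    alpha = coefs[0, :]
    beta_mat = coefs[1:, :].T  # (q-1, p)
    bse = np.asarray(res.bse)

    names, est, se = [], [], []
    for k in range(q - 1):
        names.append(f"alpha{k + 2}")
        est.append(alpha[k])
        se.append(bse[0, k])
    for k in range(q - 1):
        for j in range(p):
            names.append(f"{data.column_names[j]}[{k + 2}]")
            est.append(beta_mat[k, j])
            se.append(bse[j + 1, k])
    est = np.asarray(est)
    se = np.asarray(se)
    return FitResult(
        family="baseline_logit",
        params=BaselineLogitParams(alpha, beta_mat),
        param_names=names,
        estimates=est,
        loglik=float(res.llf),
        n_params=(q - 1) * (p + 1),
        n_obs=n,
        se=se,
        ci=_wald_ci(est, se, ci_level),
        ci_level=ci_level,
        converged=converged,
        data=data,
        extra={"sm_result": res},
    )


def fit_linear(
    data: OrdinalDataset,
    with_interaction: bool = False,
    ci_level: float = 0.95,
) -> FitResult:
    """OLS on the integer response codes 1..q.

    This is the "treat ordinal as equally spaced continuous" baseline; the
    parameter count includes the residual variance so the shared AIC/BIC
    formula applies.  When ``with_interaction`` the product of the first
    two covariates enters as ``x1:x2``.
    """
    d = data.with_interaction() if with_interaction else data
    exog = sm.add_constant(d.X, has_constant="add")
    res = sm.OLS(d.y.astype(float), exog).fit()
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _warnings.warn("design matrix is rank deficient (collinear covariates)")
    coef = np.asarray(res.params)
    names = ["intercept"] + list(d.column_names)
    se = np.asarray(res.bse)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=res.df_resid)
    ci = np.column_stack([coef - tcrit * se, coef + tcrit * se])
    sigma2 = float(res.ssr / d.n)  # MLE variance, consistent with llf
    return FitResult(
        family="linear",
        params=LinearParams(coef[0], coef[1:], sigma2),
        param_names=names,
        estimates=coef,
        loglik=float(res.llf),
        n_params=len(coef) + 1,  # + sigma2
        n_obs=d.n,
        se=se,
        ci=ci,
        ci_level=ci_level,
        converged=True,
        data=d,
        extra={"sm_result": res, "pvalues": dict(zip(names, np.asarray(res.pvalues))),
               "df_resid": float(res.df_resid), "with_interaction": with_interaction},
    )


def _refit_without(fit: FitResult, coefficient: str) -> FitResult:
    data = fit.data
    reduced = data.drop_column(coefficient)
    if fit.family == "stereotype":
        opts = fit.extra.get("options", FitOptions())
        return fit_stereotype(
            reduced,
            n_restarts=opts.n_restarts,
            tol=opts.tol,
            max_iter=opts.max_iter,
            seed=opts.seed,
        )
    if fit.family == "proportional_odds":
        return fit_proportional_odds(reduced)
    if fit.family == "baseline_logit":
        return fit_baseline_logit(reduced)
    if fit.family == "linear":
        return fit_linear(reduced, with_interaction=False)
    raise ValueError(f"unsupported family {fit.family!r}")


def coef_test(fit: FitResult, coefficient: str, method: str = "lrt") -> dict:
    """Test ``H0: coefficient = 0`` by likelihood ratio or Wald.

    The LRT refits the model with the covariate column removed.  Degrees of
    freedom: 1 per dropped slope, except a stereotype model with a single
    covariate where the scores lose identification under H0 and the LRT
    reference is chi-square with ``1 + (q - 2)`` df; a baseline-category
    logit drops ``q - 1`` slopes at once.
    """
    if coefficient not in fit.param_names and coefficient not in fit.data.column_names:
        raise KeyError(f"no coefficient named {coefficient!r} in this fit")
    if method == "wald":
        est = fit.coef(coefficient)
        se = fit.coef_se(coefficient)
        zstat = est / se
        if fit.family == "linear":
            pv = 2.0 * stats.t.sf(abs(zstat), df=fit.extra["df_resid"])
        else:
            pv = 2.0 * stats.norm.sf(abs(zstat))
        return {"statistic": float(zstat**2), "df": 1, "p_value": float(pv)}
    if method != "lrt":
        raise ValueError("method must be 'lrt' or 'wald'")
    if not fit.converged:
        raise RuntimeError("refusing a likelihood-ratio test on an unconverged fit")
    if fit.family == "linear" and fit.extra.get("with_interaction") \
            and coefficient not in fit.data.column_names:
        raise KeyError(f"no covariate named {coefficient!r}")
    null_fit = _refit_without(fit, coefficient)
    stat = max(2.0 * (fit.loglik - null_fit.loglik), 0.0)
    if fit.family == "stereotype":
        p = fit.params.p
        q = fit.params.q
        df = 1 if p >= 2 else 1 + (q - 2)
    elif fit.family == "baseline_logit":
        df = fit.data.q - 1
    else:
        df = 1
    return {"statistic": float(stat), "df": int(df),
            "p_value": float(stats.chi2.sf(stat, df))}
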