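"""The ordered stereotype model: likelihood, constrained ML fit, spacing.

The model for an ordinal response :math:`Y_i \\in \\{1,\\dots,q\\}` with
covariates :math:`x_i` is the multinomial logit

.. math::

    \\log \\frac{P(Y_i = k \\mid x_i)}{P(Y_i = 1 \\mid x_i)}
        = \\alpha_k + \\phi_k \\, \\beta' x_i , \\qquad k = 2, \\dots, q,

with the monotone score constraint
:math:`0 = \\phi_1 \\le \\phi_2 \\le \\dots \\le \\phi_q = 1` that makes the
response genuinely ordinal, and the identifiability pins
:math:`\\alpha_1 = \\phi_1 = 0`, :math:`\\phi_q = 1`.  Unlike the
proportional odds model, the spacing of the categories is estimated from
the data through the scores :math:`\\phi_k`; equal spacing recovers the
adjacent-categories proportional-odds model.

Fitting maximizes the likelihood over an unconstrained reparametrization of
the interior scores (cumulative softmax of positive increments), so a
smooth quasi-Newton optimizer can be used while the constraint holds by
construction.  Standard errors come from the inverse observed information
in the unconstrained space, delta-mapped to the reporting scale
:math:`(\\alpha, \\phi, \\beta)`.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import OrdinalDataset
from .results import FitResult

__all__ = [
    "StereotypeParams",
    "FitOptions",
    "phi_from_unconstrained",
    "phi_to_unconstrained",
    "stereotype_probabilities",
    "log_likelihood",
    "fit_stereotype",
    "rescale_scores",
    "score_gaps",
    "spacing_report",
]


@dataclass
class StereotypeParams:
    """Parameters ``(alpha, phi, beta)`` with identifiability pins applied.

    ``alpha`` has length ``q`` with ``alpha[0] = 0``; ``phi`` has length
    ``q`` with ``phi[0] = 0``, ``phi[-1] = 1`` and non-decreasing entries;
    ``beta`` has length ``p``.
    """

    alpha: np.ndarray
    phi: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        q = self.alpha.shape[0]
        if self.phi.shape[0] != q:
            raise ValueError("alpha and phi must both have length q")
        if q < 2:
            raise ValueError("q >= 2 required")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.phi).all()
                and np.isfinite(self.beta).all()):
            raise ValueError("parameters must be finite")
        if self.alpha[0] != 0.0:
            raise ValueError("alpha[0] must equal 0 (baseline category)")
        if abs(self.phi[0]) > 1e-12 or abs(self.phi[-1] - 1.0) > 1e-12:
            raise ValueError("phi must be pinned to phi_1 = 0, phi_q = 1")
        if np.any(np.diff(self.phi) < -1e-12):
            raise ValueError("phi must be non-decreasing")

    @property
    def q(self) -> int:
        return self.alpha.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass
class FitOptions:
    """Tuning knobs of the constrained ML fit."""

    n_restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 500
    ci_level: float = 0.95
    seed: int | None = None
    jitter_sd: float = 0.5
    fixed_phi: np.ndarray | None = None


def phi_from_unconstrained(u: np.ndarray, q: int | None = None) -> np.ndarray:
    """Map an unconstrained vector ``u`` (length q-2) to a valid score vector.

    The q-1 positive spacing increments are ``softmax([u, 0])``; the scores
    are their cumulative sums, so ``phi[0] = 0 < phi[1] < ... < phi[-1] = 1``
    for any finite ``u``.  Pinning the last log-increment to 0 makes the map
    a smooth bijection onto strictly ordered interiors.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if q is None:
        q = u.shape[0] + 2
    if u.shape[0] != q - 2:
        raise ValueError(f"u must have length q-2 = {q - 2}")
    w = np.concatenate([u, [0.0]])
    incr = special.softmax(w)
    phi = np.concatenate([[0.0], np.cumsum(incr)])
    phi[-1] = 1.0  # kill cumulative-sum round-off at the pinned endpoint
    return phi


def phi_to_unconstrained(phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`phi_from_unconstrained` for strictly increasing phi."""
    phi = np.asarray(phi, dtype=float)
    incr = np.diff(phi)
    if np.any(incr <= 0):
        raise ValueError("inverse map needs strictly increasing scores")
    return np.log(incr[:-1]) - np.log(incr[-1])


def _dphi_du(u: np.ndarray) -> np.ndarray:
    """Jacobian of the interior scores phi_2..phi_{q-1} w.r.t. ``u``.

    Returns shape ``(q-2, q-2)``; row ``k`` is the gradient of ``phi[k+1]``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    m = u.shape[0]  # = q - 2
    if m == 0:
        return np.zeros((0, 0))
    w = np.concatenate([u, [0.0]])
    e = np.exp(w - w.max())
    S = e.sum()
    phi_int = np.cumsum(e)[:-1] / S  # phi_2..phi_{q-1}
    # d phi_k / d u_j = e_j (1[j <= k-1] - phi_k) / S, 1-based k=2..q-1
    ind = (np.arange(m)[None, :] <= np.arange(m)[:, None]).astype(float)
    return (e[:m][None, :] / S) * (ind - phi_int[:, None])


def stereotype_probabilities(params: StereotypeParams, X: np.ndarray) -> np.ndarray:
    """Response-probability matrix ``theta`` with ``theta[i, k-1] = P(Y_i=k)``.

    Computed as a row-wise softmax of the category logits
    ``alpha_k + phi_k * beta' x_i`` (shifted by the row maximum for
    numerical stability); every row sums to one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.p:
        raise ValueError(
            f"X has {X.shape[1]} columns but beta has length {params.p}"
        )
    t = X @ params.beta
    eta = params.alpha[None, :] + np.outer(t, params.phi)
    return special.softmax(eta, axis=1)


def log_likelihood(params: StereotypeParams, data: OrdinalDataset) -> float:
    """Multinomial log-likelihood ``sum_i log theta_{i, y_i}``."""
    if params.q != data.q:
        raise ValueError("params and data disagree on q")
    t = data.X @ params.beta
    eta = params.alpha[None, :] + np.outer(t, params.phi)
    ll = eta[np.arange(data.n), data.y - 1] - special.logsumexp(eta, axis=1)
    out = float(ll.sum())
    if not np.isfinite(out):
        raise FloatingPointError("log-likelihood is non-finite (degenerate parameters)")
    return out


def _unpack(z: np.ndarray, q: int, p: int, fixed_phi: np.ndarray | None):
    a = z[: q - 1]
    if fixed_phi is None:
        u = z[q - 1 : 2 * q - 3]
        phi = phi_from_unconstrained(u, q) if q > 2 else np.array([0.0, 1.0])
        b = z[2 * q - 3 :]
    else:
        u = np.zeros(0)
        phi = fixed_phi
        b = z[q - 1 :]
    return a, u, phi, b


def _negloglik_grad(z, y0, X, q, fixed_phi):
    """Negative log-likelihood and gradient in the unconstrained space."""
    n, p = X.shape
    a, u, phi, b = _unpack(z, q, p, fixed_phi)
    t = X @ b
    eta = np.empty((n, q))
    eta[:, 0] = 0.0
    eta[:, 1:] = a[None, :]
    eta += np.outer(t, phi)
    lse = special.logsumexp(eta, axis=1)
    ll = eta[np.arange(n), y0] - lse
    theta = np.exp(eta - lse[:, None])
    resid = -theta
    resid[np.arange(n), y0] += 1.0

    grad_a = resid[:, 1:].sum(axis=0)
    grad_b = X.T @ (phi[y0] - theta @ phi)
    if fixed_phi is None and q > 2:
        g_phi = t @ resid[:, 1 : q - 1]  # score w.r.t. interior phi
        grad_u = _dphi_du(u).T @ g_phi
        grad = np.concatenate([grad_a, grad_u, grad_b])
    else:
        grad = np.concatenate([grad_a, grad_b])
    return -float(ll.sum()), -grad


def _numeric_hessian(fun_grad, z, args, step=1e-5):
    """Central finite differences of the analytic gradient."""
    k = z.shape[0]
    H = np.zeros((k, k))
    for j in range(k):
        h = step * (1.0 + abs(z[j]))
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        _, gp = fun_grad(zp, *args)
        _, gm = fun_grad(zm, *args)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_stereotype(
    data: OrdinalDataset,
    options: FitOptions | None = None,
    **kwargs,
) -> FitResult:
    """Maximum-likelihood fit of the ordered stereotype model.

    The likelihood is maximized with BFGS over ``(alpha_2..alpha_q,
    u, beta)`` where ``u`` encodes the interior scores through the monotone
    map; the surface can be multimodal because of the ``phi_k * beta``
    product, so ``n_restarts`` seeded jittered starts are tried and the best
    converged optimum kept.  Wald CIs use delta-method SEs on the
    ``(alpha, phi, beta)`` scale.

    Keyword arguments override individual :class:`FitOptions` fields.
    """
    opts = options or FitOptions()
    for key, val in kwargs.items():
        if not hasattr(opts, key):
            raise TypeError(f"unknown fit option {key!r}")
        setattr(opts, key, val)
    q, p, n = data.q, data.p, data.n
    fixed_phi = None
    if opts.fixed_phi is not None:
        fixed_phi = np.asarray(opts.fixed_phi, dtype=float)
        if fixed_phi.shape[0] != q:
            raise ValueError("fixed_phi must have length q")
    n_free = (q - 1) + (0 if fixed_phi is not None or q == 2 else q - 2) + p
    n_params = (q - 1) + (q - 2) + p if fixed_phi is None else (q - 1) + p
    if q == 2 and fixed_phi is None:
        data_warn = "q = 2: the score parameters carry no information; the fit " \
                    "coincides with binary logistic regression"
        _warnings.warn(data_warn)
    if n <= n_params:
        _warnings.warn(
            f"n = {n} does not exceed the parameter count {n_params}; "
            "estimates may be unstable"
        )

    rng = np.random.default_rng(opts.seed)
    y0 = data.y - 1
    args = (y0, data.X, q, fixed_phi)
    z0 = np.zeros(n_free)
    starts = [z0] + [
        z0 + rng.normal(0.0, opts.jitter_sd, size=n_free)
        for _ in range(max(opts.n_restarts - 1, 0))
    ]

    best = None
    best_converged = False
    used = 0
    for start in starts:
        used += 1
        res = optimize.minimize(
            _negloglik_grad, start, args=args, jac=True, method="BFGS",
            options={"gtol": opts.tol, "maxiter": opts.max_iter},
        )
        # BFGS can stop on line-search precision loss at a genuine optimum
        # when gtol is stricter than the objective's floating-point scale;
        # accept a stationary point by a scaled gradient criterion.
        ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-6 * max(
            1.0, abs(float(res.fun))
        )
        better = best is None or res.fun < best.fun - 1e-10
        if ok and not best_converged:
            best, best_converged = res, True
        elif ok == best_converged and better:
            best = res
    converged = best_converged
    z = best.x

    a_hat, u_hat, phi_hat, b_hat = _unpack(z, q, p, fixed_phi)
    params = StereotypeParams(
        alpha=np.concatenate([[0.0], a_hat]), phi=phi_hat, beta=b_hat
    )
    loglik = -float(best.fun)

    # observed information -> delta-method SEs on the reporting scale
    H = _numeric_hessian(_negloglik_grad, z, args)
    try:
        cov_u = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_u = np.linalg.pinv(H)
        _warnings.warn("observed information is singular; using pseudo-inverse")
    if fixed_phi is None and q > 2:
        J = np.zeros((n_free, n_free))
        J[: q - 1, : q - 1] = np.eye(q - 1)
        J[q - 1 : 2 * q - 3, q - 1 : 2 * q - 3] = _dphi_du(u_hat)
        J[2 * q - 3 :, 2 * q - 3 :] = np.eye(p)
    else:
        J = np.eye(n_free)
    cov = J @ cov_u @ J.T
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)

    names = [f"alpha{k}" for k in range(2, q + 1)]
    est = list(a_hat)
    if fixed_phi is None and q > 2:
        names += [f"phi{k}" for k in range(2, q)]
        est += list(phi_hat[1 : q - 1])
    names += list(data.column_names)
    est += list(b_hat)
    est = np.asarray(est)
    zcrit = stats.norm.ppf(0.5 + opts.ci_level / 2.0)
    ci = np.column_stack([est - zcrit * se, est + zcrit * se])

    family = "stereotype" if fixed_phi is None else "stereotype_fixed_phi"
    return FitResult(
        family=family,
        params=params,
        param_names=names,
        estimates=est,
        loglik=loglik,
        n_params=n_params,
        n_obs=n,
        se=se,
        ci=ci,
        ci_level=opts.ci_level,
        converged=converged,
        n_restarts_used=used,
        data=data,
        extra={
            "u": u_hat,
            "phi_se": se[q - 1 : 2 * q - 3] if fixed_phi is None and q > 2 else np.zeros(0),
            "options": opts,
            "grad_norm": float(np.linalg.norm(best.jac)),
        },
    )


def rescale_scores(phi: np.ndarray, q: int) -> np.ndarray:
    """Map scores from ``[0, 1]`` back to the original range ``[1, q]``.

    ``nu_k = 1 + (q - 1) * phi_k``, so ``nu_1 = 1`` and ``nu_q = q``; the
    rescaled scores are the data-dictated positions of the categories on
    the familiar ``1..q`` axis.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] != q:
        raise ValueError("phi must have length q")
    return 1.0 + (q - 1) * phi


def score_gaps(phi: np.ndarray) -> np.ndarray:
    """Adjacent-category distances ``phi_{k+1} - phi_k``."""
    return np.diff(np.asarray(phi, dtype=float))


def spacing_report(fit: FitResult, ci_level: float = 0.95) -> pd.DataFrame:
    """Adjacent-gap table with distinguishability flags.

    For each pair of adjacent categories reports the fitted gap
    ``phi_{k+1} - phi_k`` and flags the pair "indistinguishable" when the
    Wald CIs of the two scores overlap (the endpoints ``phi_1`` and
    ``phi_q`` are pinned constants with zero-width intervals).  A zero gap
    means the covariates do not separate the two categories, suggesting
    they could be collapsed — a decision left to the analyst.
    """
    if fit.family != "stereotype":
        raise ValueError("spacing_report requires a free-score stereotype fit")
    if not fit.converged:
        raise RuntimeError("refusing to report spacing from an unconverged fit")
    phi = fit.params.phi
    q = phi.shape[0]
    se = np.zeros(q)
    if q > 2:
        se[1 : q - 1] = fit.extra["phi_se"]
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo = phi - zcrit * se
    hi = phi + zcrit * se
    gaps = score_gaps(phi)
    overlap = hi[:-1] >= lo[1:]
    df = pd.DataFrame({
        "pair": [f"{k + 1}-{k + 2}" for k in range(q - 1)],
        "phi_lower": phi[:-1],
        "phi_upper": phi[1:],
        "gap": gaps,
        "ci_lower_lo": lo[:-1], "ci_lower_hi": hi[:-1],
        "ci_upper_lo": lo[1:], "ci_upper_hi": hi[1:],
        "indistinguishable": overlap | (gaps < 1e-6),
    })
    df.attrs["largest_gap_pair"] = df.loc[df["gap"].idxmax(), "pair"]
    df.attrs["smallest_gap_pair"] = df.loc[df["gap"].idxmin(), "pair"]
    df.attrs["ci_level"] = ci_level
    return df
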