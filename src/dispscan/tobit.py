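"""Left-bounded Gaussian regression (truncated and censored Tobit variants).

Absolute residuals live on [0, inf) with a hard lower bound, so dispersion
is regressed on genotype with a bounded-Gaussian likelihood rather than
OLS.  Two variants are supported:

* ``truncated`` — every observation is above the bound tau and the
  Gaussian density is renormalized by P(y > tau):
  L = prod f(y_i) / (1 - Phi((tau - x_i b)/sigma)).
* ``censored`` — observations at or below tau contribute the mass
  Phi((tau - x_i b)/sigma); the rest contribute the plain density.

Fitting is by quasi-Newton (BFGS) maximum likelihood on (beta, log sigma)
with an analytic gradient; standard errors come from the numerically
differentiated observed information at the optimum, reported on the
natural (beta, sigma) scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

log = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ContrastError(ValueError):
    """Raised for an ill-posed Wald contrast."""


@dataclass
class TobitSpec:
    """Bound and variant for a left-bounded fit."""

    tau: float = 0.0
    variant: str = "truncated"

    def __post_init__(self) -> None:
        if self.variant not in ("truncated", "censored"):
            raise ValueError(f"unknown Tobit variant {self.variant!r}")


@dataclass
class TobitFit:
    """Maximum-likelihood fit of a left-bounded Gaussian regression.

    ``vcov`` covers (beta, sigma) on the natural scale, shape (p+1, p+1).
    """

    beta: np.ndarray
    sigma: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    n: int
    iterations: int
    colnames: list[str] = field(default_factory=list)
    spec: TobitSpec = field(default_factory=TobitSpec)
    grad_norm: float = np.nan
    X: np.ndarray | None = None
    y: np.ndarray | None = None

    @property
    def vcov_beta(self) -> np.ndarray:
        return self.vcov[: len(self.beta), : len(self.beta)]

    def linear_predictor(self) -> np.ndarray:
        if self.X is None:
            raise ValueError("fit retains no design matrix")
        return self.X @ self.beta


def _hazard(a: np.ndarray) -> np.ndarray:
    """phi(a) / (1 - Phi(a)), computed in log space for stability."""
    return np.exp(-0.5 * a**2 - _LOG_SQRT_2PI - log_ndtr(-a))


def _inv_mills(a: np.ndarray) -> np.ndarray:
    """phi(a) / Phi(a)."""
    return np.exp(-0.5 * a**2 - _LOG_SQRT_2PI - log_ndtr(a))


def negloglik(
    params: np.ndarray, y: np.ndarray, X: np.ndarray, spec: TobitSpec
) -> float:
    """Negative log-likelihood at params = (beta, log sigma)."""
    beta, s = params[:-1], params[-1]
    sigma = np.exp(s)
    mu = X @ beta
    z = (y - mu) / sigma
    a = (spec.tau - mu) / sigma
    if spec.variant == "truncated":
        # -log[ phi(z) / (sigma * (1 - Phi(a))) ]; log_ndtr(-a) = log(1 - Phi(a))
        terms = _LOG_SQRT_2PI + 0.5 * z**2 + s + log_ndtr(-a)
        return float(terms.sum())
    cens = y <= spec.tau
    out = np.empty_like(y)
    out[~cens] = _LOG_SQRT_2PI + 0.5 * z[~cens] ** 2 + s
    out[cens] = -log_ndtr(a[cens])
    return float(out.sum())


def negloglik_grad(
    params: np.ndarray, y: np.ndarray, X: np.ndarray, spec: TobitSpec
) -> np.ndarray:
    """Analytic gradient of ``negloglik`` w.r.t. (beta, log sigma)."""
    beta, s = params[:-1], params[-1]
    sigma = np.exp(s)
    mu = X @ beta
    z = (y - mu) / sigma
    a = (spec.tau - mu) / sigma
    if spec.variant == "truncated":
        lam = _hazard(a)
        dmu = (lam - z) / sigma
        ds = 1.0 - z**2 + a * lam
        return np.concatenate([X.T @ dmu, [ds.sum()]])
    cens = y <= spec.tau
    dmu = np.empty_like(y)
    ds = np.empty_like(y)
    dmu[~cens] = -z[~cens] / sigma
    ds[~cens] = 1.0 - z[~cens] ** 2
    mills = _inv_mills(a[cens])
    dmu[cens] = mills / sigma
    ds[cens] = a[cens] * mills
    return np.concatenate([X.T @ dmu, [ds.sum()]])


def _negloglik_natural(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, spec: TobitSpec
) -> float:
    """nll parameterized by (beta, sigma) for observed-information SEs."""
    if theta[-1] <= 0:
        return np.inf
    params = np.concatenate([theta[:-1], [np.log(theta[-1])]])
    return negloglik(params, y, X, spec)


def _numerical_hessian(f, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, step 1e-5 * (1 + |theta_k|)."""
    p = len(theta)
    h = 1e-5 * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_tobit(
    y: np.ndarray,
    X: np.ndarray,
    spec: TobitSpec | None = None,
    colnames: list[str] | None = None,
    start: np.ndarray | None = None,
) -> TobitFit:
    """Fit a left-bounded Gaussian regression by BFGS maximum likelihood.

    Start values come from OLS; convergence requires a gradient 2-norm
    below 1e-6 at the optimum (one restart is attempted otherwise and a
    failure is returned flagged, not raised).
    """
    spec = spec or TobitSpec()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    if spec.variant == "truncated" and (y < spec.tau).any():
        raise ValueError("truncated variant requires all y >= tau")

    if start is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        s0 = np.log(max(np.sqrt(resid @ resid / max(n - p, 1)), 1e-3))
        start = np.concatenate([beta0, [s0]])

    args = (y, X, spec)
    res = optimize.minimize(
        negloglik, start, args=args, jac=negloglik_grad,
        method="BFGS", options={"gtol": 1e-9, "maxiter": 500},
    )
    x, fval = res.x, float(res.fun)
    grad = negloglik_grad(x, *args)
    # Newton polish: BFGS often stops a hair short of the gradient target
    # on flat likelihoods; a couple of damped Newton steps with the
    # numerically differentiated Hessian close the gap.
    for _ in range(5):
        if np.linalg.norm(grad) < 1e-8:
            break
        H = _numerical_hessian(lambda t: negloglik(t, *args), x)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = x - damp * step
            fcand = negloglik(cand, *args)
            if np.isfinite(fcand) and fcand <= fval + 1e-12:
                x, fval = cand, fcand
                break
        else:
            break
        grad = negloglik_grad(x, *args)
    grad_norm = float(np.linalg.norm(grad))
    converged = grad_norm < 1e-6
    if not converged:
        log.warning("Tobit fit did not converge (|grad|=%.3g)", grad_norm)

    beta = x[:-1]
    sigma = float(np.exp(x[-1]))
    theta = np.concatenate([beta, [sigma]])
    H = _numerical_hessian(lambda t: _negloglik_natural(t, y, X, spec), theta)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        log.warning("observed information singular; using pseudo-inverse")
        vcov = np.linalg.pinv(H)
    return TobitFit(
        beta=beta,
        sigma=sigma,
        vcov=vcov,
        loglik=-fval,
        converged=converged,
        n=n,
        iterations=int(res.nit),
        colnames=list(colnames or [f"x{i}" for i in range(p)]),
        spec=spec,
        grad_norm=grad_norm,
        X=X,
        y=y,
    )


@dataclass
class ContrastResult:
    """A Wald contrast C @ beta = 0."""

    estimate: float | np.ndarray
    se: float | None
    stat: float
    df: int
    p: float


def wald_contrast(fit: TobitFit, C: np.ndarray) -> ContrastResult:
    """Wald chi-square test of C beta = 0 against the fit's vcov.

    Single-row contrasts additionally report the signed estimate and SE.
    """
    C = np.atleast_2d(np.asarray(C, float))
    p = len(fit.beta)
    if C.shape[1] != p:
        raise ContrastError(f"contrast has {C.shape[1]} columns, fit has {p} coefficients")
    if (np.abs(C).sum(axis=1) == 0).any():
        raise ContrastError("all-zero contrast row")
    est = C @ fit.beta
    V = C @ fit.vcov_beta @ C.T
    try:
        stat = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError as exc:
        raise ContrastError(f"singular contrast covariance for C={C.tolist()}") from exc
    if stat < 0:  # numerically indefinite vcov
        stat = 0.0
    df = C.shape[0]
    pval = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    if df == 1:
        se = float(np.sqrt(V[0, 0])) if V[0, 0] > 0 else np.nan
        return ContrastResult(estimate=float(est[0]), se=se, stat=stat, df=1, p=pval)
    return ContrastResult(estimate=est, se=None, stat=stat, df=df, p=pval)
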