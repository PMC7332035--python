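"""Poisson regression with log link, optionally with a pond-level random intercept.

The response model is

    y_i ~ Poisson(Y_i),    ln(Y_i) = alpha + sum_k beta_k x_{k,i} + r_i,

with r_i ~ N(0, sigma^2) a per-pond random effect.  The fixed model sets
sigma = 0 in advance; the mixed model estimates sigma by maximum marginal
likelihood, integrating the Poisson likelihood over the Gaussian random
effect with adaptive (mode-centred) Gauss-Hermite quadrature.

Model quality is compared by AIC = -2*loglik + 2*(number of free parameters),
where the free parameters are the intercept, the K slopes, and sigma for the
mixed model.

The fixed-effects solver is a small damped Newton iteration: best-subset
selection embedded inside permutation resampling performs millions of tiny
fits, so per-fit overhead matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FitResult",
    "PoissonRegression",
    "PoissonMixedRegression",
    "fit_fixed",
    "fit_mixed",
    "aic",
    "poisson_loglik",
    "mixed_loglik",
]

_ETA_MAX = 500.0  # cap on the linear predictor inside exp()


@dataclass
class FitResult:
    """One fitted Poisson model (fixed or mixed).

    ``sigma`` is exactly 0.0 for fixed fits.  ``cov`` is the covariance of
    (intercept, beta_1..beta_K[, sigma]) used for Wald intervals.
    ``residuals`` are observed minus fitted on the response scale.
    """

    intercept: float
    coef: np.ndarray
    sigma: float
    loglik: float
    aic: float
    cov: np.ndarray | None
    fitted: np.ndarray
    residuals: np.ndarray
    mixed: bool
    converged: bool
    n_free: int
    names: list[str] = field(default_factory=list)
    sigma_boundary: bool = False

    @property
    def valid(self) -> bool:
        return self.converged and np.isfinite(self.aic)

    def coef_table(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef))

    def se(self) -> np.ndarray:
        """Standard errors of (intercept, coefs[, sigma])."""
        if self.cov is None:
            raise ValueError("covariance unavailable for this fit")
        return np.sqrt(np.diag(self.cov))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": dict(zip(self.names, self.coef.tolist())),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "aic": self.aic,
            "mixed": self.mixed,
            "converged": self.converged,
            "n_free": self.n_free,
        }


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Poisson log-pmf with log-mean ``eta``."""
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def _design(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return np.column_stack([np.ones(n), X])


def _newton_poisson(Z: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 100) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Damped Newton maximisation of the Poisson log-likelihood.

    Z includes the intercept column.  Returns (theta, loglik, hessian, ok).
    """
    n, p = Z.shape
    theta = np.zeros(p)
    theta[0] = np.log(max(y.mean(), 1e-8))
    eta = Z @ theta
    ll = poisson_loglik(y, eta)
    H = None
    ok = False
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        grad = Z.T @ (y - mu)
        H = (Z * mu[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return theta, ll, H, False
        # backtracking line search
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            ll_new = poisson_loglik(y, Z @ cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            return theta, ll, H, False
        theta = theta + t * step
        eta = Z @ theta
        improved = ll_new - ll
        ll = ll_new
        if abs(improved) < tol * (1.0 + abs(ll)):
            ok = True
            break
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    H = (Z * mu[:, None]).T @ Z
    return theta, ll, H, ok


def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = hermgauss(n_quad)
    return t, np.log(w)


def _random_effect_modes(eta: np.ndarray, y: np.ndarray, sigma: float,
                         max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Per-pond mode and curvature of the log joint in the random effect."""
    inv_s2 = 1.0 / (sigma * sigma)
    r = np.zeros_like(eta)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta + r, -_ETA_MAX, _ETA_MAX))
        g1 = y - mu - r * inv_s2
        g2 = mu + inv_s2  # = -d2/dr2
        step = np.clip(g1 / g2, -4.0, 4.0)
        r = r + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(np.clip(eta + r, -_ETA_MAX, _ETA_MAX))
    h = mu + inv_s2
    return r, h


def mixed_loglik(beta: np.ndarray, sigma: float, Z: np.ndarray, y: np.ndarray,
                 nodes: np.ndarray, log_w: np.ndarray) -> float:
    """Marginal log-likelihood of the random-intercept Poisson model.

    Each pond's Poisson pmf is integrated over its Gaussian random effect by
    adaptive Gauss-Hermite quadrature centred at the per-pond posterior mode
    (Liu-Pierce).  At sigma = 0 this degenerates to the fixed likelihood.
    """
    eta = Z @ beta
    if sigma < 1e-10:
        return poisson_loglik(y, eta)
    r_hat, h = _random_effect_modes(eta, y, sigma)
    scale = np.sqrt(2.0 / h)  # (M,)
    rq = r_hat[:, None] + scale[:, None] * nodes[None, :]  # (M, Q)
    lin = np.clip(eta[:, None] + rq, -_ETA_MAX, _ETA_MAX)
    log_joint = (
        y[:, None] * lin - np.exp(lin) - gammaln(y + 1.0)[:, None]
        - 0.5 * rq * rq / (sigma * sigma) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    )
    log_li = np.log(scale) + logsumexp(log_w[None, :] + nodes[None, :] ** 2 + log_joint, axis=1)
    return float(np.sum(log_li))


def _mixed_loglik_grad(beta: np.ndarray, sigma: float, Z: np.ndarray,
                       y: np.ndarray, nodes: np.ndarray,
                       log_w: np.ndarray) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood and its gradient in (beta, sigma).

    The gradient uses posterior expectations over the same quadrature
    nodes (Fisher's identity); the tiny inconsistency from differentiating
    through the adaptive node placement is far below optimiser tolerances.
    """
    eta = Z @ beta
    if sigma < 1e-10:
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        ll = poisson_loglik(y, eta)
        return ll, np.concatenate([Z.T @ (y - mu), [0.0]])
    r_hat, h = _random_effect_modes(eta, y, sigma)
    scale = np.sqrt(2.0 / h)
    rq = r_hat[:, None] + scale[:, None] * nodes[None, :]
    lin = np.clip(eta[:, None] + rq, -_ETA_MAX, _ETA_MAX)
    log_joint = (
        y[:, None] * lin - np.exp(lin) - gammaln(y + 1.0)[:, None]
        - 0.5 * rq * rq / (sigma * sigma) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    )
    log_terms = log_w[None, :] + nodes[None, :] ** 2 + log_joint
    log_li = logsumexp(log_terms, axis=1)
    post = np.exp(log_terms - log_li[:, None])  # posterior node weights per pond
    mu_q = np.exp(lin)
    e_score = np.sum(post * (y[:, None] - mu_q), axis=1)   # E[y - mu(r)]
    e_r2 = np.sum(post * rq * rq, axis=1)                  # E[r^2]
    g_beta = Z.T @ e_score
    g_sigma = float(np.sum(e_r2) / sigma ** 3 - len(y) / sigma)
    ll = float(np.sum(np.log(scale) + log_li))
    return ll, np.concatenate([g_beta, [g_sigma]])


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


class PoissonRegression(RegressorMixin, BaseEstimator):
    """Fixed-effects Poisson regression with log link (sigma = 0 in advance).

    Parameters
    ----------
    tol : float
        Relative log-likelihood convergence tolerance.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (K,)
    loglik_ : float
    aic_ : float
        AIC with K + 1 free parameters.
    cov_params_ : ndarray
        Inverse observed information for (intercept, coefs).
    result_ : FitResult
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, X, y):
        X, y, names = _validate_Xy(X, y)
        Z = _design(X)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            return self._invalid(X, y, names)
        theta, ll, H, ok = _newton_poisson(Z, y, tol=self.tol)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov, ok = None, False
        eta = Z @ theta
        fitted = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        k_free = Z.shape[1]
        res = FitResult(
            intercept=float(theta[0]), coef=theta[1:].copy(), sigma=0.0,
            loglik=ll, aic=-2.0 * ll + 2.0 * k_free, cov=cov,
            fitted=fitted, residuals=y - fitted, mixed=False,
            converged=ok, n_free=k_free, names=names,
        )
        self._store(res)
        return self

    def _invalid(self, X, y, names):
        res = FitResult(
            intercept=np.nan, coef=np.full(X.shape[1], np.nan), sigma=0.0,
            loglik=-np.inf, aic=np.inf, cov=None, fitted=np.full_like(y, np.nan, dtype=float),
            residuals=np.full_like(y, np.nan, dtype=float), mixed=False,
            converged=False, n_free=X.shape[1] + 1, names=names,
        )
        self._store(res)
        return self

    def _store(self, res: FitResult):
        self.result_ = res
        self.intercept_ = res.intercept
        self.coef_ = res.coef
        self.sigma_ = res.sigma
        self.loglik_ = res.loglik
        self.aic_ = res.aic
        self.cov_params_ = res.cov

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        eta = self.intercept_ + X @ self.coef_
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


class PoissonMixedRegression(PoissonRegression):
    """Poisson regression with a Gaussian pond-level random intercept.

    Fixed effects by maximum likelihood and sigma by maximum marginal
    likelihood, jointly optimised; the marginal likelihood integrates each
    pond's Poisson pmf over its random effect with adaptive Gauss-Hermite
    quadrature (``n_quad`` nodes, default 21).

    A fit whose optimum lies at sigma = 0 is returned as a valid fit with
    ``result_.sigma_boundary = True``; its AIC still counts sigma as a free
    parameter.
    """

    def __init__(self, tol: float = 1e-10, n_quad: int = 21,
                 sigma_max: float = 5.0, compute_cov: bool = True):
        super().__init__(tol=tol)
        self.n_quad = n_quad
        self.sigma_max = sigma_max
        self.compute_cov = compute_cov

    def fit(self, X, y):
        from scipy.optimize import minimize

        X, y, names = _validate_Xy(X, y)
        Z = _design(X)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            return self._invalid(X, y, names)
        nodes, log_w = _gh_nodes(self.n_quad)

        theta0, ll_fixed, _, ok0 = _newton_poisson(Z, y, tol=self.tol)
        p = Z.shape[1]

        def nll(params):
            ll, g = _mixed_loglik_grad(params[:p], params[p], Z, y, nodes, log_w)
            return -ll, -g

        x0 = np.concatenate([theta0, [0.2]])
        bounds = [(None, None)] * p + [(0.0, self.sigma_max)]
        opt = minimize(nll, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        ll = -opt.fun
        params = opt.x
        boundary = False
        # sigma = 0 is in the parameter space: never report worse than fixed
        if ll < ll_fixed or params[p] < 1e-6:
            params = np.concatenate([theta0, [0.0]])
            ll = ll_fixed
            boundary = True
        k_free = p + 1
        cov = (self._covariance(params, p, Z, y, nodes, log_w, boundary)
               if self.compute_cov else None)
        eta = Z @ params[:p]
        fitted = np.exp(np.clip(eta + 0.5 * params[p] ** 2, -_ETA_MAX, _ETA_MAX))
        res = FitResult(
            intercept=float(params[0]), coef=params[1:p].copy(), sigma=float(params[p]),
            loglik=ll, aic=-2.0 * ll + 2.0 * k_free, cov=cov,
            fitted=fitted, residuals=y - fitted, mixed=True,
            converged=bool(opt.success or boundary or ok0), n_free=k_free,
            names=names, sigma_boundary=boundary,
        )
        self._store(res)
        return self

    def _covariance(self, params, p, Z, y, nodes, log_w, boundary):
        if boundary:
            # curvature in sigma is one-sided at the boundary; report the
            # fixed-effects block only, padded with zeros for sigma
            mu = np.exp(np.clip(Z @ params[:p], -_ETA_MAX, _ETA_MAX))
            H = (Z * mu[:, None]).T @ Z
            try:
                cov_b = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return None
            cov = np.zeros((p + 1, p + 1))
            cov[:p, :p] = cov_b
            return cov
        def nll(q):
            return -mixed_loglik(q[:p], max(q[p], 1e-8), Z, y, nodes, log_w)
        try:
            H = _numeric_hessian(nll, params)
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None

    def predict(self, X):
        """Marginal mean exp(eta + sigma^2/2)."""
        X = np.asarray(X, dtype=float)
        eta = self.intercept_ + X @ self.coef_ + 0.5 * self.sigma_ ** 2
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def _validate_Xy(X, y):
    try:
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    except AttributeError:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(y) != X.shape[0]:
        raise ValueError("X and y have incompatible lengths")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integer counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (missing values disallowed)")
    return X, y, names


def fit_fixed(X, y) -> FitResult:
    """Maximum-likelihood Poisson GLM with log link (sigma = 0)."""
    return PoissonRegression().fit(X, y).result_


def fit_mixed(X, y, n_quad: int = 21, compute_cov: bool = True) -> FitResult:
    """Random-intercept Poisson model; sigma by maximum marginal likelihood."""
    return PoissonMixedRegression(n_quad=n_quad,
                                  compute_cov=compute_cov).fit(X, y).result_


def aic(fit: FitResult) -> float:
    """AIC = -2 loglik + 2 (free parameters); intercept and sigma counted."""
    if not np.isfinite(fit.loglik):
        raise ValueError("AIC undefined for an invalid fit")
    return -2.0 * fit.loglik + 2.0 * fit.n_free
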