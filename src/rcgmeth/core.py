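"""Densities and log-likelihood of the RCG model.

All density work is done in log space.  The Bessel factor of the bivariate
density uses the exponentially scaled ``ive`` so it stays finite where the
unscaled function overflows.  The discriminant-like term

    D = ((theta-1)b + 1)^2 - 4 rho theta b (1-b)

is evaluated through the factorization D = (A - 2s)(A + 2s) with
A = (theta-1)b+1 and s = sqrt(rho theta b(1-b)), where

    A - 2s = (sqrt(theta b) - sqrt(1-b))^2 + 2(1-sqrt(rho)) sqrt(theta b (1-b))

which avoids catastrophic cancellation as rho -> 1 with theta near 1.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import BivariateGammaParams, RCGParams, RHO_MAX

__all__ = [
    "kibble_density",
    "kibble_logpdf",
    "rcg_density",
    "rcg_logpdf",
    "rcg_loglik",
    "rcg_score",
    "rcg_score_and_hessian",
    "NumericalFailure",
]


class NumericalFailure(FloatingPointError):
    """Raised when a likelihood evaluation produces a non-finite value."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


def kibble_logpdf(m, u, params: BivariateGammaParams):
    """Log joint density of (M, U) under the Wicksell-Kibble distribution."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(m <= 0) or np.any(u <= 0):
        raise ValueError("m and u must be strictly positive")
    a, lm, lu, rho = params.alpha, params.lambda_m, params.lambda_u, params.rho
    if rho == 0.0:
        # independence limit: product of the marginal gamma log-densities
        lp = (a * np.log(lm) + (a - 1.0) * np.log(m) - lm * m - special.gammaln(a)
              + a * np.log(lu) + (a - 1.0) * np.log(u) - lu * u - special.gammaln(a))
        return lp
    z = 2.0 * np.sqrt(rho * lm * lu * m * u) / (1.0 - rho)
    # log I_{a-1}(z) via the exponentially scaled Bessel function
    log_bessel = np.log(special.ive(a - 1.0, z)) + z
    lp = (a * np.log(lm * lu)
          - np.log1p(-rho)
          - special.gammaln(a)
          + 0.5 * (a - 1.0) * (np.log(m * u) - np.log(rho * lm * lu))
          - (lm * m + lu * u) / (1.0 - rho)
          + log_bessel)
    return lp


def kibble_density(m, u, params: BivariateGammaParams):
    """Joint density f_{M,U}(m, u) of correlated gamma signal intensities."""
    return np.exp(kibble_logpdf(m, u, params))


def _log_D(b, theta, rho):
    """log of ((theta-1)b+1)^2 - 4 rho theta b(1-b), cancellation-safe."""
    tb = theta * b
    omb = 1.0 - b
    root = np.sqrt(tb * omb)
    sqrho = np.sqrt(rho)
    lo = (np.sqrt(tb) - np.sqrt(omb)) ** 2 + 2.0 * (1.0 - sqrho) * root
    hi = tb + omb + 2.0 * sqrho * root
    return np.log(lo) + np.log(hi)


def rcg_logpdf(b, alpha: float, rho: float, theta):
    """Log density of the ratio b = M/(M+U) in the identifiable
    parameterization (lambda_m = theta, lambda_u = 1)."""
    b = np.asarray(b, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("b must lie strictly inside (0, 1)")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    rho = min(rho, RHO_MAX)
    A = (theta - 1.0) * b + 1.0
    lp = (special.gammaln(2.0 * alpha) - 2.0 * special.gammaln(alpha)
          + alpha * np.log(theta)
          + alpha * np.log1p(-rho)
          + np.log(A)
          + (alpha - 1.0) * np.log(b * (1.0 - b))
          - (alpha + 0.5) * _log_D(b, theta, rho))
    return lp


def rcg_density(b, alpha: float, rho: float, theta):
    """Density of the ratio of correlated gammas on (0, 1).

    Reduces to the Beta(alpha, alpha) density at rho=0, theta=1 and satisfies
    the reflection identity f(b; alpha, rho, theta) = f(1-b; alpha, rho, 1/theta).
    """
    return np.exp(rcg_logpdf(b, alpha, rho, theta))


def _linpred(X: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    eta = X @ gamma
    # exp(eta) appears directly in the density; keep it in a safe range
    return np.clip(eta, -300.0, 300.0)


def rcg_loglik(b: np.ndarray, X: np.ndarray, params: RCGParams) -> float:
    """Log-likelihood sum_i log f_b(b_i; alpha, rho, theta_i) with
    theta_i = exp(X_i' gamma)."""
    b = np.asarray(b, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != b.shape[0]:
        raise ValueError("b and X must have the same number of rows")
    if X.shape[1] != params.n_coef:
        raise ValueError("gamma length does not match design columns")
    theta = np.exp(_linpred(X, params.gamma))
    lp = rcg_logpdf(b, params.alpha, params.rho, theta)
    if not np.all(np.isfinite(lp)):
        idx = int(np.flatnonzero(~np.isfinite(lp))[0])
        raise NumericalFailure(
            f"non-finite log-density at observation {idx} (b={b[idx]!r})", idx)
    return float(np.sum(lp))


def rcg_score(b: np.ndarray, X: np.ndarray, params: RCGParams) -> np.ndarray:
    """Analytic gradient of the log-likelihood over (gamma, alpha, rho).

    Returned in the order (gamma_0..gamma_p, alpha, rho).
    """
    b = np.asarray(b, dtype=float)
    X = np.asarray(X, dtype=float)
    a, rho = params.alpha, min(params.rho, RHO_MAX)
    eta = _linpred(X, params.gamma)
    theta = np.exp(eta)
    tb = theta * b
    omb = 1.0 - b
    A = tb + omb
    bb = b * omb
    root = np.sqrt(tb * omb)
    sqrho = np.sqrt(rho)
    D = ((np.sqrt(tb) - np.sqrt(omb)) ** 2 + 2.0 * (1.0 - sqrho) * root) \
        * (tb + omb + 2.0 * sqrho * root)
    # d/d eta (per observation), with dA/deta = theta*b, dD/deta = 2A theta b - 4 rho theta b(1-b)
    dl_deta = a + tb / A - (a + 0.5) * (2.0 * A * tb - 4.0 * rho * theta * bb) / D
    g_gamma = X.T @ dl_deta
    dl_dalpha = np.sum(2.0 * special.digamma(2.0 * a) - 2.0 * special.digamma(a)
                       + eta + np.log1p(-rho) + np.log(bb) - np.log(D))
    dl_drho = np.sum(-a / (1.0 - rho) + (a + 0.5) * 4.0 * theta * bb / D)
    return np.concatenate([g_gamma, [dl_dalpha, dl_drho]])


def rcg_score_and_hessian(
    b: np.ndarray,
    X: np.ndarray,
    params: RCGParams,
    step: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the log-likelihood over (gamma, alpha, rho).

    The gradient is analytic; the Hessian is formed by central differences of
    the analytic gradient (one-sided at the rho boundaries) and symmetrized.
    """
    if params.rho <= 0.0 or params.rho >= RHO_MAX:
        import warnings
        warnings.warn("rho at its boundary: using one-sided differences; "
                      "curvature in rho may be unreliable", stacklevel=2)
    grad = rcg_score(b, X, params)
    p1 = params.n_coef
    k = p1 + 2

    def grad_at(v: np.ndarray) -> np.ndarray:
        pp = RCGParams(gamma=v[:p1], alpha=v[p1], rho=v[p1 + 1])
        return rcg_score(b, X, pp)

    v0 = np.concatenate([params.gamma, [params.alpha, params.rho]])
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(v0[j]))
        lo, hi = v0.copy(), v0.copy()
        hi[j] += h
        lo[j] -= h
        # keep alpha positive and rho inside [0, RHO_MAX]
        if j == p1:
            lo[j] = max(lo[j], 1e-8)
        if j == p1 + 1:
            hi[j] = min(hi[j], RHO_MAX)
            lo[j] = max(lo[j], 0.0)
        H[:, j] = (grad_at(hi) - grad_at(lo)) / (hi[j] - lo[j])
    H = 0.5 * (H + H.T)
    return grad, H
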