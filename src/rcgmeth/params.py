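"""Parameter containers and design-matrix utilities.

The RCG ("ratio of correlated gammas") model describes a methylation beta
value b = M/(M+U) through the joint distribution of the methylated (M) and
unmethylated (U) signal intensities.  (M, U) follow a Wicksell-Kibble
bivariate gamma distribution with common shape ``alpha``, rates
``lambda_m``/``lambda_u`` and Pearson correlation ``rho``.  Only the mean
ratio theta = lambda_m/lambda_u = E(U)/E(M) is identifiable from beta values,
and the regression model links it to covariates via log theta = X'gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: beta values are clamped to [BETA_EPS, 1-BETA_EPS] on ingestion; the ratio
#: density is only defined on the open interval.
BETA_EPS = 1e-6

#: upper bound for the correlation parameter in all evaluations.
RHO_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class BivariateGammaParams:
    """Wicksell-Kibble bivariate gamma parameters.

    Marginals are Gamma(alpha, rate=lambda_m) and Gamma(alpha, rate=lambda_u)
    with means alpha/lambda_m, alpha/lambda_u and variances alpha/lambda_m^2,
    alpha/lambda_u^2; corr(M, U) = rho.
    """

    alpha: float
    lambda_m: float
    lambda_u: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.lambda_m > 0 and self.lambda_u > 0):
            raise ValueError("alpha, lambda_m and lambda_u must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")

    @property
    def theta(self) -> float:
        """Mean ratio lambda_m/lambda_u = E(U)/E(M)."""
        return self.lambda_m / self.lambda_u


@dataclass(frozen=True)
class RCGParams:
    """Identifiable parameters of the RCG regression model.

    ``gamma`` is the coefficient vector of the log mean-ratio link
    (gamma[0] is the intercept), ``alpha`` the common gamma shape and
    ``rho`` the intensity correlation.
    """

    gamma: np.ndarray
    alpha: float
    rho: float

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "gamma", g)
        if not np.all(np.isfinite(g)):
            raise ValueError("gamma must be finite")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")

    @property
    def n_coef(self) -> int:
        return self.gamma.shape[0]


def clamp_beta(b: np.ndarray, eps: float = BETA_EPS) -> tuple[np.ndarray, int]:
    """Clamp beta values into [eps, 1-eps]; returns (clamped, n_clamped)."""
    b = np.asarray(b, dtype=float)
    out = np.clip(b, eps, 1.0 - eps)
    return out, int(np.sum((b < eps) | (b > 1.0 - eps)))


def build_design(covariates: pd.DataFrame, columns: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix (1, X_1, ..., X_p) from a covariate table.

    Factor (non-numeric) columns are dummy-coded with the lexicographically
    first level as reference.  Returns the matrix and its column labels.
    """
    if columns is not None:
        missing = [c for c in columns if c not in covariates.columns]
        if missing:
            raise KeyError(f"covariates not found: {missing}")
        covariates = covariates[columns]
    parts: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                parts.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
        else:
            parts.append(s.to_numpy(dtype=float))
            names.append(col)
    X = np.column_stack(parts)
    validate_design(X, names)
    return X, names


def validate_design(X: np.ndarray, names: list[str] | None = None) -> None:
    """Check intercept, full column rank and n > p+1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    n, p1 = X.shape
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first design column must be the intercept (all ones)")
    if n <= p1:
        raise ValueError(f"need more observations ({n}) than columns ({p1})")
    if np.linalg.matrix_rank(X) < p1:
        labels = names if names is not None else [f"col{j}" for j in range(p1)]
        raise ValueError(f"design matrix is rank deficient (columns: {labels})")
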