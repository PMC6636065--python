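"""Multivariate Poisson-log normal (MPLN) mixture model: containers and densities.

The MPLN distribution is a two-layer hierarchical model for a d-dimensional
count vector Y_i = (Y_i1, ..., Y_id):

    Y_ij | theta_ij  ~  Poisson(exp{theta_ij + log s_j})
    (theta_i1, ..., theta_id)' ~ N_d(mu, Sigma)

where s_j > 0 is a fixed per-sample normalization offset (an effective
library-size multiplier).  The latent Gaussian layer induces overdispersion
and arbitrary-sign correlations between samples, which a plain (univariate)
Poisson or negative-binomial model cannot represent.

A G-component mixture attaches mixing weights pi_g and component parameters
(mu_g, Sigma_g); cluster membership is latent and recovered through posterior
responsibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import cho_solve
from scipy.special import gammaln

__all__ = [
    "CountMatrix",
    "NormalizationOffsets",
    "ComponentParams",
    "MixtureParams",
    "poisson_layer_loglik",
    "latent_prior_loglik",
    "marginal_mean",
    "marginal_variance",
    "complete_data_loglik",
    "marginal_pmf_quadrature",
]

_SYM_TOL = 1e-8


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


def _as_2d_int(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise InputError(f"count matrix must be 2-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise InputError("count matrix must have at least one row and one column")
    if not np.isfinite(arr.astype(float)).all():
        raise InputError("count matrix contains missing or non-finite entries")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise InputError(f"negative count at row {i}, column {j}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-9):
        i, j = np.argwhere(~np.isclose(arr, rounded, atol=1e-9))[0]
        raise InputError(f"non-integer count at row {i}, column {j}")
    return rounded.astype(np.int64)


@dataclass
class CountMatrix:
    """Observed n x d matrix of non-negative integer read counts.

    Rows are observations (genes), columns are samples.
    """

    values: np.ndarray
    row_ids: list[str] = field(default=None)
    col_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = _as_2d_int(self.values)
        n, d = self.values.shape
        if self.row_ids is None:
            self.row_ids = [f"gene_{i}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = [f"sample_{j}" for j in range(d)]
        if len(self.row_ids) != n or len(self.col_ids) != d:
            raise InputError("row/column identifier lengths do not match the matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationOffsets:
    """Strictly positive per-sample multipliers s_j on the Poisson rate."""

    s: np.ndarray
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if self.s.ndim != 1:
            raise InputError("offsets must be a 1-d vector")
        if not np.isfinite(self.s).all() or np.any(self.s <= 0):
            raise InputError("offsets must be finite and strictly positive")
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j}" for j in range(len(self.s))]

    @property
    def log_s(self) -> np.ndarray:
        return np.log(self.s)

    @classmethod
    def ones(cls, d: int) -> "NormalizationOffsets":
        return cls(np.ones(d))


@dataclass
class ComponentParams:
    """One mixture component: log-scale mean mu and covariance Sigma."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        d = self.mu.shape[0]
        if self.sigma.shape != (d, d):
            raise InputError(
                f"sigma shape {self.sigma.shape} incompatible with mu length {d}"
            )
        asym = np.max(np.abs(self.sigma - self.sigma.T)) if d > 1 else 0.0
        if asym > _SYM_TOL:
            raise InputError(f"sigma is asymmetric beyond tolerance ({asym:.2e})")
        # silent symmetrization below tolerance, then a factorization check
        self.sigma = 0.5 * (self.sigma + self.sigma.T)
        try:
            self._chol = np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "sigma is not positive definite (Cholesky factorization failed); "
                f"smallest eigenvalue {np.linalg.eigvalsh(self.sigma).min():.3e}"
            ) from exc

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    @property
    def chol(self) -> np.ndarray:
        return self._chol

    @property
    def log_det(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Sigma^{-1} @ rhs via the cached Cholesky factor."""
        return cho_solve((self._chol, True), rhs)


@dataclass
class MixtureParams:
    """Everything Theta in the G-component MPLN mixture density."""

    weights: np.ndarray
    components: list[ComponentParams]

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if len(self.components) != self.weights.shape[0]:
            raise InputError("number of components does not match weight vector")
        if np.any(self.weights <= 0):
            raise InputError("all mixing weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise InputError(f"mixing weights sum to {self.weights.sum():.12f}, not 1")
        d = self.components[0].d
        if any(c.d != d for c in self.components):
            raise InputError("components have inconsistent dimension")

    @property
    def G(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.components[0].d


# ---------------------------------------------------------------------------
# densities and moments


def poisson_layer_loglik(y, theta, s) -> float:
    """Log of the product of independent Poisson pmfs with rates exp(theta_j + log s_j).

    sum_j [ y_j (theta_j + log s_j) - exp(theta_j + log s_j) - log y_j! ]

    log y! uses the log-gamma function so counts up to ~1e6 are safe.
    """
    y = _as_2d_int(np.atleast_2d(y))[0]
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    s = s if isinstance(s, NormalizationOffsets) else NormalizationOffsets(s)
    if not (y.shape[0] == theta.shape[0] == s.s.shape[0]):
        raise InputError(
            f"dimension mismatch: y has {y.shape[0]}, theta {theta.shape[0]}, "
            f"s {s.s.shape[0]}"
        )
    log_rate = theta + s.log_s
    return float(np.sum(y * log_rate - np.exp(log_rate) - gammaln(y + 1.0)))


def latent_prior_loglik(theta, comp: ComponentParams) -> float:
    """Multivariate Gaussian log-density of the latent log-mean vector."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape[0] != comp.d:
        raise InputError("theta dimension does not match component")
    resid = theta - comp.mu
    quad = float(resid @ comp.solve(resid))
    return -0.5 * (comp.d * np.log(2.0 * np.pi) + comp.log_det + quad)


def marginal_mean(mu_j: float, sigma_jj: float) -> float:
    """Marginal mean of one coordinate: m = exp(mu + sigma_jj / 2)."""
    if sigma_jj < 0:
        raise InputError("sigma_jj must be non-negative")
    return float(np.exp(mu_j + 0.5 * sigma_jj))


def marginal_variance(m: float, sigma_jj: float) -> float:
    """Marginal variance m + m^2 (exp(sigma_jj) - 1); always >= m (overdispersion)."""
    if m <= 0:
        raise InputError("marginal mean must be positive")
    if sigma_jj < 0:
        raise InputError("sigma_jj must be non-negative")
    return float(m + m * m * np.expm1(sigma_jj))


def complete_data_loglik(
    y: CountMatrix,
    z: np.ndarray,
    theta: np.ndarray,
    params: MixtureParams,
    s: NormalizationOffsets,
) -> float:
    """Complete-data log-likelihood l_c(Theta) of the MPLN mixture.

    ``theta`` has shape (n, G, d): one latent vector per observation and
    component.  ``z`` is n x G, rows soft (summing to 1) or one-hot.
    Equals sum_{i,g} z_ig [log pi_g + Poisson layer + Gaussian layer].
    """
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, G = z.shape
    if theta.shape != (n, G, params.d):
        raise InputError(f"theta shape {theta.shape} != {(n, G, params.d)}")
    rows = z.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise InputError("membership rows must sum to 1")
    total = float(z.sum(axis=0) @ np.log(params.weights))
    for g, comp in enumerate(params.components):
        for i in range(n):
            if z[i, g] == 0.0:
                continue
            total += z[i, g] * (
                poisson_layer_loglik(y.values[i], theta[i, g], s)
                + latent_prior_loglik(theta[i, g], comp)
            )
    return total


def marginal_pmf_quadrature(
    y_i, comp: ComponentParams, s: NormalizationOffsets, nodes: int = 64
) -> float:
    """MPLN marginal pmf by Gauss-Hermite quadrature; testing oracle, d <= 2 only.

    The integral over the Gaussian layer is standardized by the Cholesky
    factor of Sigma, so probabilist's Hermite nodes apply directly.
    """
    if comp.d > 2:
        raise InputError("quadrature oracle supports d <= 2 only")
    if nodes < 20:
        raise InputError("use at least 20 quadrature nodes")
    y_i = _as_2d_int(np.atleast_2d(y_i))[0]
    x, w = hermegauss(nodes)
    w = w / np.sqrt(2.0 * np.pi)
    L = comp.chol
    if comp.d == 1:
        thetas = comp.mu[0] + L[0, 0] * x  # (nodes,)
        grid_w = w
        grid_theta = thetas[:, None]
    else:
        xx1, xx2 = np.meshgrid(x, x, indexing="ij")
        zs = np.stack([xx1.ravel(), xx2.ravel()], axis=1)  # (nodes^2, 2)
        grid_theta = comp.mu + zs @ L.T
        grid_w = np.outer(w, w).ravel()
    log_rate = grid_theta + np.log(s.s)
    log_pois = np.sum(y_i * log_rate - np.exp(log_rate) - gammaln(y_i + 1.0), axis=1)
    return float(np.sum(grid_w * np.exp(log_pois)))
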