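"""Starting values for the MCMC-EM run.

Component means and covariances start from data moments (log of column means,
covariance of log1p counts); responsibilities start from k-means memberships
or random simplex rows, refined by 10-iteration short EM runs when several
candidates compete (highest final surrogate log-likelihood wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .model import CountMatrix, InputError, NormalizationOffsets

__all__ = [
    "InitConfig",
    "init_params_moments",
    "init_responsibilities_kmeans",
    "init_responsibilities_random",
    "short_run_select",
]

_VAR_FLOOR = 1e-6


@dataclass
class InitConfig:
    method: str = "kmeans"          # "kmeans" | "random"
    n_runs: int = 3
    short_run_iters: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("kmeans", "random"):
            raise InputError(f"unknown initialization method {self.method!r}")
        if self.n_runs < 1 or self.short_run_iters < 1:
            raise InputError("n_runs and short_run_iters must be >= 1")


def init_params_moments(y: CountMatrix):
    """Moment-based (mu0, Sigma0) on the latent log scale.

    mu0 is the elementwise log of column means (columns whose mean is zero
    are shifted by +1 so the log stays finite); Sigma0 is the covariance of
    log1p-transformed counts with a variance floor, guaranteed symmetric
    positive definite.
    """
    if y.n < 2:
        raise InputError("need at least 2 observations for moment initialization")
    col_means = y.values.mean(axis=0).astype(float)
    col_means[col_means == 0.0] += 1.0
    mu0 = np.log(col_means)
    logs = np.log1p(y.values.astype(float))
    sigma0 = np.cov(logs, rowvar=False)
    sigma0 = np.atleast_2d(sigma0)
    diag = np.diag(sigma0).copy()
    fix = diag < _VAR_FLOOR
    if fix.any():
        sigma0[np.diag_indices_from(sigma0)] = np.where(fix, _VAR_FLOOR, diag)
    # ridge until factorizable (correlated columns can make cov singular)
    eps = 1e-8 * max(float(np.mean(np.diag(sigma0))), 1.0)
    for _ in range(40):
        try:
            np.linalg.cholesky(sigma0)
            break
        except np.linalg.LinAlgError:
            sigma0 = sigma0 + eps * np.eye(sigma0.shape[0])
            eps *= 10.0
    return mu0, sigma0


def _one_hot(labels: np.ndarray, G: int) -> np.ndarray:
    z = np.zeros((labels.shape[0], G))
    z[np.arange(labels.shape[0]), labels] = 1.0
    return z


def init_responsibilities_kmeans(y: CountMatrix, G: int, n_runs: int = 3,
                                 seed: int = 0) -> np.ndarray:
    """One-hot memberships from the best of n_runs k-means fits on log1p counts."""
    if G > y.n:
        raise InputError("more clusters than observations")
    X = np.log1p(y.values.astype(float))
    if G > np.unique(X, axis=0).shape[0]:
        raise InputError("more clusters than distinct observations")
    km = KMeans(n_clusters=G, n_init=n_runs, random_state=_to_int_seed(seed))
    labels = km.fit_predict(X)
    return _one_hot(labels, G)


def init_responsibilities_random(n: int, G: int, seed: int = 0) -> np.ndarray:
    """Rows drawn uniformly on the simplex (flat Dirichlet), strictly positive."""
    if n < 1 or G < 1:
        raise InputError("n and G must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.dirichlet(np.ones(G), size=n)
    return np.clip(z, 1e-12, None) / np.clip(z, 1e-12, None).sum(1, keepdims=True)


def short_run_select(y: CountMatrix, s: NormalizationOffsets, G: int,
                     candidate_inits, config: InitConfig = None,
                     controls=None, seed=0) -> np.ndarray:
    """Run short EM bursts per candidate and keep the best final z.

    Each candidate initialization is advanced ``short_run_iters`` EM
    iterations (fixed 1000-iteration chains, no outer convergence test); the
    candidate with the highest final surrogate log-likelihood wins, ties
    broken by candidate order.
    """
    from .em import EMControls, fit_single_G

    config = config or InitConfig()
    candidates = list(candidate_inits)
    if not candidates:
        raise InputError("need at least one candidate initialization")
    short = controls or EMControls()
    short = EMControls(
        start_iter=short.start_iter, chain_growth=0,
        chain_increment=short.chain_increment, n_chains=short.n_chains,
        rhat_threshold=short.rhat_threshold, ess_threshold=short.ess_threshold,
        sampler_max_attempts=short.sampler_max_attempts,
        gate_diagnostics=False, min_em_iter=config.short_run_iters,
        max_em_iter=config.short_run_iters, use_hw=False,
        collapse_restarts=short.collapse_restarts, ridge_rel=short.ridge_rel,
    )
    best_z, best_ll = None, -np.inf
    errors = []
    for k, cand in enumerate(candidates):
        try:
            fit = fit_single_G(y, s, G, cand, short, seed=_cat(seed, k))
            if fit.failed:
                errors.append(f"candidate {k}: component collapse")
                continue
        except Exception as exc:  # aggregate and keep trying others
            errors.append(f"candidate {k}: {exc}")
            continue
        if fit.loglik > best_ll:
            best_ll, best_z = fit.loglik, fit.z
    if best_z is None:
        raise RuntimeError("all initialization candidates failed: "
                           + "; ".join(errors))
    return best_z


def _to_int_seed(seed) -> int:
    if np.isscalar(seed):
        return int(seed) % (2**32)
    seq = np.random.SeedSequence([int(v) for v in seed])
    return int(seq.generate_state(1)[0])


def _cat(seed, *extra):
    if np.isscalar(seed):
        return [int(seed), *[int(v) for v in extra]]
    return [*[int(v) for v in seed], *[int(v) for v in extra]]
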