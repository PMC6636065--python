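"""MCMC-EM engine for the MPLN mixture.

Each EM iteration alternates:

  E-step (Monte Carlo): for every observation i and component g, draw from
    the latent posterior f(theta_ig | y_i, mu_g, Sigma_g) by MCMC (gated on
    R-hat/ESS), reduce to the posterior mean E(theta_ig | y_i) and second
    moment; then update the responsibilities z_ig from the plug-in joint
    density pi_g f(y_i | E theta_ig, s) f(E theta_ig | mu_g, Sigma_g).

  M-step (closed form):
    pi_g    = sum_i z_ig / n
    mu_g    = sum_i z_ig E(theta_ig) / sum_i z_ig
    Sigma_g = sum_i z_ig E[(theta_ig - mu_g)(theta_ig - mu_g)'] / sum_i z_ig

  where the covariance expectation averages over all retained draws (via the
  posterior second moment), not just the draw mean -- using only the mean
  would systematically shrink Sigma by the posterior spread.

The observed-data log-likelihood has no closed form (it is an intractable
d-dimensional integral), so the trace tracked across iterations is the same
plug-in joint used for the responsibilities; outer-loop convergence is
declared when the Heidelberger-Welch stationarity test accepts this trace at
level alpha, after a minimum number of iterations.  The per-observation
chain length starts at 1000 and grows by 100 with each EM iteration to damp
persistent Monte-Carlo error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln, logsumexp
from statsmodels.regression.linear_model import yule_walker

from .model import (
    ComponentParams,
    CountMatrix,
    InputError,
    MixtureParams,
    NormalizationOffsets,
)
from .sampler import ChainSet, grouped_latent_stats

__all__ = [
    "EMControls",
    "FitResult",
    "expected_latent",
    "update_responsibilities",
    "update_mixing",
    "update_mean",
    "update_covariance",
    "surrogate_loglik",
    "heidelberger_welch_stationary",
    "fit_single_G",
]


@dataclass
class EMControls:
    """Tunable controls of the MCMC-EM loop (defaults follow the method)."""

    start_iter: int = 1000          # chain length at EM iteration 0
    chain_growth: int = 100         # added to the chain length per EM iteration
    chain_increment: int = 100      # added on a diagnostics-gate failure
    n_chains: int = 3
    rhat_threshold: float = 1.1
    ess_threshold: float = 100.0
    sampler_max_attempts: int = 50
    gate_diagnostics: bool = True
    min_em_iter: int = 10
    max_em_iter: int = 100
    hw_alpha: float = 0.05
    use_hw: bool = True
    collapse_restarts: int = 3
    ridge_rel: float = 1e-6


@dataclass
class FitResult:
    """Outcome of one MCMC-EM run at a fixed number of components G."""

    params: MixtureParams
    z: np.ndarray                   # (n, G) responsibilities
    expected_theta: np.ndarray      # (n, G, d) posterior latent means
    loglik_trace: list
    iterations: int
    converged: bool
    failed: bool
    diagnostics_summary: dict
    seed: object

    @property
    def G(self) -> int:
        return self.params.G

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# E-step pieces


def expected_latent(chains: ChainSet) -> np.ndarray:
    """Coordinatewise mean of all retained draws across chains."""
    if chains.draws.size == 0:
        raise InputError("empty retained draw set")
    return chains.draws.mean(axis=(0, 1))


def _log_joint_matrix(y, expected_theta, params, s):
    """log [pi_g f(y_i | E theta_ig, s) f(E theta_ig | mu_g, Sigma_g)], (n, G)."""
    Y = y.values if isinstance(y, CountMatrix) else np.asarray(y)
    Y = Y.astype(float)
    n, d = Y.shape
    G = params.G
    log_s = s.log_s
    const = -gammaln(Y + 1.0).sum(axis=1)
    out = np.empty((n, G))
    for g, comp in enumerate(params.components):
        th = expected_theta[:, g, :]
        log_rate = th + log_s
        pois = np.sum(Y * log_rate - np.exp(log_rate), axis=1) + const
        r = th - comp.mu
        half = solve_triangular(comp.chol, r.T, lower=True).T
        quad = np.sum(half * half, axis=1)
        prior = -0.5 * (d * np.log(2 * np.pi) + comp.log_det + quad)
        out[:, g] = np.log(params.weights[g]) + pois + prior
    return out


def update_responsibilities(y, expected_theta, params: MixtureParams,
                            s: NormalizationOffsets) -> np.ndarray:
    """Posterior membership probabilities, computed in log space.

    Rows are normalized with log-sum-exp; a row whose every component has
    log-density -inf raises an error naming the observation.
    """
    logj = _log_joint_matrix(y, expected_theta, params, s)
    norm = logsumexp(logj, axis=1)
    bad = ~np.isfinite(norm)
    if bad.any():
        raise FloatingPointError(
            f"all component densities vanished for observation(s) "
            f"{np.where(bad)[0].tolist()}"
        )
    return np.exp(logj - norm[:, None])


def surrogate_loglik(y, expected_theta, params: MixtureParams,
                     s: NormalizationOffsets) -> float:
    """Plug-in joint log-likelihood sum_i log sum_g pi_g f(y_i|E theta_ig) f(E theta_ig|...).

    The same quantity whose ratios define the responsibilities, so the EM
    trace is internally consistent.
    """
    logj = _log_joint_matrix(y, expected_theta, params, s)
    norm = logsumexp(logj, axis=1)
    if not np.isfinite(norm).all():
        raise FloatingPointError("surrogate log-likelihood is -inf for some row")
    return float(norm.sum())


# ---------------------------------------------------------------------------
# M-step


def update_mixing(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return z.mean(axis=0)


def update_mean(z: np.ndarray, expected_theta: np.ndarray) -> np.ndarray:
    """Per-component weighted average of expected latents, (G, d)."""
    z = np.asarray(z, dtype=float)
    n_g = z.sum(axis=0)
    if np.any(n_g <= 1e-12):
        raise FloatingPointError("empty component in mean update")
    return np.einsum("ig,igd->gd", z, expected_theta) / n_g[:, None]


def update_covariance(z, draws_per_obs, mu_new) -> np.ndarray:
    """Weighted Monte-Carlo covariance for one component.

    ``draws_per_obs`` is a sequence of (N_i, d) retained-draw arrays, one per
    observation; ``z`` the component's responsibility column.  The inner
    expectation averages (theta - mu)(theta - mu)' over the draws.
    """
    z = np.asarray(z, dtype=float)
    mu_new = np.asarray(mu_new, dtype=float)
    d = mu_new.shape[0]
    acc = np.zeros((d, d))
    for zi, draws in zip(z, draws_per_obs):
        dev = np.asarray(draws, dtype=float) - mu_new
        acc += zi * (dev.T @ dev) / dev.shape[0]
    sigma = acc / z.sum()
    return 0.5 * (sigma + sigma.T)


def _covariance_from_stats(z_g, mean_g, cov_g, mu_new) -> np.ndarray:
    """Same update from posterior sufficient statistics.

    E[(theta-mu)(theta-mu)'] = Cov(theta | y) + (E theta - mu)(E theta - mu)'.
    """
    dev = mean_g - mu_new
    sigma = (np.einsum("i,ide->de", z_g, cov_g)
             + np.einsum("i,id,ie->de", z_g, dev, dev)) / z_g.sum()
    return 0.5 * (sigma + sigma.T)


def _repair_pd(sigma: np.ndarray, ridge_rel: float) -> np.ndarray:
    """Ridge-repair a covariance that fails factorization: Sigma + eps I."""
    try:
        np.linalg.cholesky(sigma)
        return sigma
    except np.linalg.LinAlgError:
        eps = max(ridge_rel * float(np.mean(np.diag(sigma))), 1e-10)
        d = sigma.shape[0]
        for _ in range(40):
            cand = sigma + eps * np.eye(d)
            try:
                np.linalg.cholesky(cand)
                warnings.warn("covariance ridge-repaired to positive definite",
                              RuntimeWarning)
                return cand
            except np.linalg.LinAlgError:
                eps *= 10.0
    raise np.linalg.LinAlgError("covariance could not be repaired")


# ---------------------------------------------------------------------------
# Heidelberger-Welch stationarity test on the EM log-likelihood trace

_CVM_TABLE = [  # upper tail critical values of the Cramer-von Mises limit law
    (0.50, 0.1189), (0.25, 0.2090), (0.10, 0.3473), (0.05, 0.4614),
    (0.025, 0.5806), (0.01, 0.7435), (0.005, 0.8694), (0.001, 1.1679),
]


def _cvm_critical(alpha: float) -> float:
    alphas = np.array([a for a, _ in _CVM_TABLE])
    crits = np.array([c for _, c in _CVM_TABLE])
    if alpha >= alphas[0]:
        return float(crits[0])
    if alpha <= alphas[-1]:
        return float(crits[-1])
    return float(np.interp(np.log(alpha), np.log(alphas[::-1]), crits[::-1]))


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit.

    A segment that is exactly linear in time (zero residual variance about a
    fitted line) has no stochastic component; its spectral variance is 0,
    which makes the bridge statistic infinite and the test fail -- a
    deterministic ramp is the textbook non-stationary trace.
    """
    n = len(x)
    if np.var(x) == 0:
        return 0.0
    t = np.arange(n, dtype=float)
    slope = np.cov(t, x, bias=True)[0, 1] / np.var(t)
    resid = x - x.mean() - slope * (t - t.mean())
    if np.std(resid) < 1e-10 * max(1.0, np.std(x)):
        return 0.0
    max_order = min(n - 2, int(10 * np.log10(n)))
    best = (np.inf, 0.0)
    var0 = float(np.var(x))
    for p in range(0, max_order + 1):
        if p == 0:
            sigma2, rho = var0, np.array([])
        else:
            try:
                rho, sigma = yule_walker(x, order=p, method="mle")
            except (np.linalg.LinAlgError, ValueError):
                continue
            sigma2 = float(sigma) ** 2
        sigma2 *= n / (n - p - 1)  # finite-sample prediction-variance factor
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best[0]:
            denom = (1.0 - rho.sum()) ** 2 if p else 1.0
            if denom <= 0:
                continue
            best = (aic, sigma2 / denom)
    return best[1]


HW_DISCARDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def heidelberger_welch_stationary(trace, alpha: float = 0.05,
                                  discard_fracs=(0.0,)) -> bool:
    """Stationarity test of a scalar trace (Cramer-von Mises on the Brownian bridge).

    The spectral variance at frequency zero is estimated from the second half
    of the trace (assumed closest to stationarity); the Schruben bridge
    statistic is then compared with the level-alpha critical value of the
    Cramer-von Mises limit law.  With the default single window the test has
    exact asymptotic level alpha, so an iid trace is accepted with
    probability ~= 1 - alpha.  Passing ``discard_fracs=HW_DISCARDS``
    reproduces the classical recipe that retries after discarding the
    initial 10%, ..., 50% of the trace (the convention of the usual R
    implementation, and what the EM convergence gate uses); that variant
    accepts whenever any window passes, hence more often than 1 - alpha.

    A constant trace is stationary by convention; a deterministic ramp has
    zero spectral variance and fails.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise InputError("trace must be 1-d with at least 10 values")
    if np.ptp(x) == 0:
        return True
    s0 = _spectrum0_ar(x[len(x) // 2:])
    if s0 <= 0:
        return False
    crit = _cvm_critical(alpha)
    for frac in discard_fracs:
        y = x[int(frac * len(x)):]
        n = len(y)
        bridge = np.cumsum(y) - y.mean() * np.arange(1, n + 1)
        if float(np.sum(bridge * bridge) / (n * n * s0)) < crit:
            return True
    return False


# ---------------------------------------------------------------------------
# full EM loop at fixed G


def _moment_start(y: CountMatrix) -> tuple:
    # deferred import: initialization also exposes this publicly
    from .initialization import init_params_moments

    return init_params_moments(y)


def fit_single_G(
    y: CountMatrix,
    s: NormalizationOffsets,
    G: int,
    init_z: np.ndarray,
    controls: EMControls = None,
    seed=0,
) -> FitResult:
    """Run MCMC-EM at a fixed component count G.

    ``init_z`` seeds the first M-step (the initial component parameters all
    start at the moment-based global estimate, so the first round of latent
    sampling is shared across components).  Iteration stops when the
    Heidelberger-Welch test declares the surrogate log-likelihood trace
    stationary (after ``min_em_iter`` iterations) or at ``max_em_iter``.
    """
    controls = controls or EMControls()
    Y = y.values
    n, d = Y.shape
    init_z = np.asarray(init_z, dtype=float)
    if init_z.shape != (n, G):
        raise InputError(f"init_z shape {init_z.shape} != {(n, G)}")
    if not np.allclose(init_z.sum(axis=1), 1.0, atol=1e-8):
        raise InputError("init_z rows must sum to 1")

    mu0, sigma0 = _moment_start(y)
    params = MixtureParams(np.full(G, 1.0 / G),
                           [ComponentParams(mu0.copy(), sigma0.copy())
                            for _ in range(G)])
    z = init_z
    trace: list = []
    expected_theta = np.zeros((n, G, d))
    gate_failures = 0
    restarts_used = 0
    failed = False
    converged = False
    rng = np.random.default_rng(_path(seed, 999))

    t = 0
    for t in range(controls.max_em_iter):
        total_iter = controls.start_iter + controls.chain_growth * t
        post_cov = np.zeros((n, G, d, d))
        shared = t == 0  # all components start identical: sample once
        comps_to_sample = params.components[:1] if shared else params.components
        stats_list = grouped_latent_stats(
            Y, comps_to_sample, s, total_iter,
            n_chains=controls.n_chains, seed=_path(seed, t),
            gate=controls.gate_diagnostics,
            max_attempts=controls.sampler_max_attempts,
            rhat_threshold=controls.rhat_threshold,
            ess_threshold=controls.ess_threshold,
            increment=controls.chain_increment,
        )
        for g in range(G):
            stats = stats_list[0 if shared else g]
            expected_theta[:, g] = stats.mean
            post_cov[:, g] = stats.cov
            gate_failures += stats.gate_failures if (not shared or g == 0) else 0

        if t > 0:
            z = update_responsibilities(y, expected_theta, params, s)

        n_g = z.sum(axis=0)
        collapsed = np.where(n_g < max(d, 2))[0]
        if collapsed.size:
            if restarts_used >= controls.collapse_restarts:
                failed = True
                warnings.warn(
                    f"component collapse persisted after "
                    f"{controls.collapse_restarts} restarts (G={G})",
                    RuntimeWarning)
                break
            restarts_used += 1
            pooled = sum(float(w) * c.sigma
                         for w, c in zip(params.weights, params.components))
            comps = list(params.components)
            for g in collapsed:
                i_star = int(rng.integers(n))
                comps[g] = ComponentParams(
                    expected_theta[i_star, g].copy(),
                    _repair_pd(pooled.copy(), controls.ridge_rel))
            weights = np.maximum(n_g, 0.5) / np.maximum(n_g, 0.5).sum()
            params = MixtureParams(weights, comps)
            continue

        pi = update_mixing(z)
        mu = update_mean(z, expected_theta)
        comps = []
        for g in range(G):
            sigma = _covariance_from_stats(
                z[:, g], expected_theta[:, g], post_cov[:, g], mu[g])
            comps.append(ComponentParams(mu[g],
                                         _repair_pd(sigma, controls.ridge_rel)))
        params = MixtureParams(pi, comps)

        trace.append(surrogate_loglik(y, expected_theta, params, s))

        if (controls.use_hw and len(trace) >= controls.min_em_iter
                and heidelberger_welch_stationary(trace, controls.hw_alpha,
                                                  discard_fracs=HW_DISCARDS)):
            converged = True
            break

    if not trace:
        failed = True
        trace = [-np.inf]
        z = init_z

    return FitResult(
        params=params,
        z=z,
        expected_theta=expected_theta,
        loglik_trace=trace,
        iterations=len(trace),
        converged=converged,
        failed=failed,
        diagnostics_summary={"sampler_gate_failures": gate_failures,
                             "collapse_restarts": restarts_used},
        seed=seed,
    )


def _path(seed, *extra) -> list:
    if np.isscalar(seed):
        base = [int(seed)]
    else:
        base = [int(v) for v in seed]
    return base + [int(v) for v in extra]
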