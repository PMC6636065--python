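"""Synthetic mixture datasets with known labels.

Two generating families:

* MPLN mixtures — labels from pi, latent log-means from the labeled
  component's Gaussian, counts Poisson with rate exp(theta_ij + log s_j);
  the same hierarchy the clustering model assumes.
* Negative-binomial mixtures — counts drawn independently per sample with
  component-specific means and a mean/dispersion parameterization
  (variance = m + m^2 / phi), a misspecification stress test for the
  MPLN fit.

Default scenarios mirror the simulation designs used to validate the
method: n=1000 x d=6 MPLN mixtures with G=1 (S1), G=2 with
pi=(0.79, 0.21) (S2) and G=3 with pi=(0.3, 0.5, 0.2) (S3), plus an
n=200 x d=6 two-component negative-binomial mixture (S4).  Component means
and covariances are chosen here so that components are well separated
(pairwise Mahalanobis distance >= 4) and counts fall near a 5-95% range of
roughly (205, 3652), matching the magnitude of a bulk RNA-seq experiment
with ~1e6-scale library sizes over ~1e3 genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import CountMatrix, InputError, NormalizationOffsets

__all__ = [
    "SimulationScenario",
    "random_pd_covariance",
    "simulate_mpln_mixture",
    "simulate_nb_mixture",
    "default_scenarios",
]


@dataclass
class SimulationScenario:
    name: str
    n: int
    d: int
    weights: np.ndarray
    means: np.ndarray               # (G, d): log scale (mpln) or count scale (nb)
    covariances: np.ndarray = None  # (G, d, d), mpln only
    dispersions: np.ndarray = None  # (G,), nb only
    offsets: NormalizationOffsets = None
    family: str = "mpln"
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.family not in ("mpln", "negative_binomial"):
            raise InputError(f"unknown family {self.family!r}")
        if abs(self.weights.sum() - 1.0) > 1e-10 or np.any(self.weights <= 0):
            raise InputError("weights must be a strictly positive simplex vector")
        if self.means.shape != (self.G, self.d):
            raise InputError("means must have shape (G, d)")
        if self.n * self.weights.min() < 1:
            raise InputError("smallest component would be empty on average")
        if self.offsets is None:
            self.offsets = NormalizationOffsets.ones(self.d)
        if self.family == "mpln":
            self.covariances = np.asarray(self.covariances, dtype=float)
            if self.covariances.shape != (self.G, self.d, self.d):
                raise InputError("covariances must have shape (G, d, d)")
            for g in range(self.G):
                np.linalg.cholesky(self.covariances[g])  # PD check
        else:
            self.dispersions = np.asarray(self.dispersions, dtype=float)
            if self.dispersions.shape != (self.G,) or np.any(self.dispersions <= 0):
                raise InputError("need one positive dispersion per component")

    @property
    def G(self) -> int:
        return len(self.weights)

    @classmethod
    def from_json(cls, path) -> "SimulationScenario":
        """Build a scenario from a JSON file with the dataclass fields."""
        import json

        with open(path) as fh:
            fields = json.load(fh)
        if fields.get("offsets") is not None:
            fields["offsets"] = NormalizationOffsets(
                np.asarray(fields["offsets"], dtype=float))
        for key in ("covariances", "dispersions"):
            if fields.get(key) is not None:
                fields[key] = np.asarray(fields[key], dtype=float)
        return cls(**fields)


def random_pd_covariance(d: int, var_range: tuple, seed=0) -> np.ndarray:
    """Random symmetric PD matrix whose diagonal lies inside ``var_range``.

    A random orthogonal basis (QR of a Gaussian matrix) with uniform
    eigenvalues gives a random correlation structure; the matrix is then
    rescaled so each diagonal entry equals a uniform draw from the range.
    """
    low, high = var_range
    if not (0 < low <= high):
        raise InputError("need 0 < low <= high")
    rng = np.random.default_rng(seed)
    if d == 1:
        return np.array([[rng.uniform(low, high)]])
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q *= np.sign(np.diag(r))
    lam = rng.uniform(1.0, 10.0, size=d)
    raw = (q * lam) @ q.T
    corr_scale = 1.0 / np.sqrt(np.diag(raw))
    corr = raw * np.outer(corr_scale, corr_scale)
    v = rng.uniform(low, high, size=d)
    return corr * np.outer(np.sqrt(v), np.sqrt(v))


def _draw_labels(rng, n, weights) -> np.ndarray:
    return rng.choice(len(weights), size=n, p=weights)


def simulate_mpln_mixture(scenario: SimulationScenario):
    """Generate (CountMatrix, true_labels) from an MPLN mixture."""
    if scenario.family != "mpln":
        raise InputError("scenario family must be 'mpln'")
    rng = np.random.default_rng(scenario.seed)
    labels = _draw_labels(rng, scenario.n, scenario.weights)
    theta = np.empty((scenario.n, scenario.d))
    for g in range(scenario.G):
        idx = labels == g
        L = np.linalg.cholesky(scenario.covariances[g])
        theta[idx] = (scenario.means[g]
                      + rng.standard_normal((int(idx.sum()), scenario.d)) @ L.T)
    rate = np.exp(theta + scenario.offsets.log_s)
    counts = rng.poisson(rate)
    _range_check(counts)
    return CountMatrix(counts), labels


def simulate_nb_mixture(scenario: SimulationScenario):
    """Generate (CountMatrix, true_labels) from a negative-binomial mixture.

    Mean/dispersion parameterization: variance = m + m^2/phi; phi -> inf
    recovers the Poisson.
    """
    if scenario.family != "negative_binomial":
        raise InputError("scenario family must be 'negative_binomial'")
    rng = np.random.default_rng(scenario.seed)
    labels = _draw_labels(rng, scenario.n, scenario.weights)
    counts = np.empty((scenario.n, scenario.d), dtype=np.int64)
    for g in range(scenario.G):
        idx = labels == g
        m = scenario.means[g] * scenario.offsets.s
        phi = scenario.dispersions[g]
        p = phi / (phi + m)
        counts[idx] = rng.negative_binomial(phi, p, size=(int(idx.sum()),
                                                          scenario.d))
    _range_check(counts)
    return CountMatrix(counts), labels


_SOFT_RANGE = (205.0, 3652.0)


def _range_check(counts) -> None:
    lo, hi = np.percentile(counts, [5, 95])
    ref_lo, ref_hi = _SOFT_RANGE
    if hi < ref_lo / 10 or lo > ref_hi * 10:
        warnings.warn(
            f"simulated 5-95% count range ({lo:.0f}, {hi:.0f}) is far from "
            f"the reference magnitude ({ref_lo:.0f}, {ref_hi:.0f})",
            RuntimeWarning)


# fixed, well-separated default settings (log scale for MPLN)
_BASE_MU = np.array([6.2, 6.5, 6.1, 6.6, 6.3, 6.4])
_SHIFT_A = 1.5 * np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
_SHIFT_B = 1.4 * np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
_VAR_RANGE = (0.1, 0.5)
_NB_MEAN_1 = np.array([320.0, 540.0, 380.0, 610.0, 450.0, 520.0])
_NB_RATIO = 12.0


def default_scenarios(n_mpln: int = 1000, n_nb: int = 200,
                      seed: int = 1234) -> list:
    """The four canonical simulation settings (S1-S4).

    ``n_mpln``/``n_nb`` set the observation counts, so reduced-scale runs of
    the same designs are one argument away; weights, dimensions and
    separations are fixed.
    """
    d = 6
    covs = lambda G, s0: np.stack([  # noqa: E731
        random_pd_covariance(d, _VAR_RANGE, seed=[seed, s0, g]) for g in range(G)
    ])
    return [
        SimulationScenario(
            name="S1", n=n_mpln, d=d, weights=[1.0], means=[_BASE_MU],
            covariances=covs(1, 1), family="mpln", seed=seed),
        SimulationScenario(
            name="S2", n=n_mpln, d=d, weights=[0.79, 0.21],
            means=[_BASE_MU + 0.5 * _SHIFT_A, _BASE_MU - _SHIFT_A],
            covariances=covs(2, 2), family="mpln", seed=seed),
        SimulationScenario(
            name="S3", n=n_mpln, d=d, weights=[0.3, 0.5, 0.2],
            means=[_BASE_MU + _SHIFT_A, _BASE_MU, _BASE_MU + _SHIFT_B],
            covariances=covs(3, 3), family="mpln", seed=seed),
        SimulationScenario(
            name="S4", n=n_nb, d=d, weights=[0.79, 0.21],
            means=[_NB_MEAN_1, _NB_RATIO * _NB_MEAN_1],
            dispersions=[2.0, 2.0], family="negative_binomial", seed=seed),
    ]
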