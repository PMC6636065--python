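"""Orchestration: offsets -> initialization -> per-G fits -> model selection.

Each candidate G is an independent job (there is no dependency between
cluster sizes), so the range is dispatched to parallel workers; seeds are
split per G from the master seed, which makes results identical between
serial and parallel execution.
"""

from __future__ import annotations

import logging

from joblib import Parallel, delayed

from .em import fit_single_G
from .initialization import (
    init_responsibilities_kmeans,
    init_responsibilities_random,
    short_run_select,
)
from .io import RunConfig
from .model import CountMatrix, NormalizationOffsets
from .normalization import library_size_offsets, tmm_norm_factors
from .selection import SelectionReport

logger = logging.getLogger("mplnmix")

__all__ = ["compute_offsets", "fit_one_g", "run_clustering_range"]


def compute_offsets(y: CountMatrix, config: RunConfig,
                    user_offsets=None) -> NormalizationOffsets:
    method = config.normalization.method
    if method == "user_supplied":
        if user_offsets is None:
            raise ValueError("normalization method is user_supplied but no "
                             "offsets were provided")
        return user_offsets
    if method == "library_size":
        return library_size_offsets(y)
    return tmm_norm_factors(y, config.normalization)


def fit_one_g(y: CountMatrix, s: NormalizationOffsets, G: int,
              config: RunConfig):
    """Initialization (k-means or random + short runs) then the full EM fit."""
    seed = [int(config.master_seed), int(G)]
    init = config.init
    if init.method == "kmeans":
        candidates = [init_responsibilities_kmeans(
            y, G, n_runs=init.n_runs, seed=[*seed, 1])]
    else:
        candidates = [init_responsibilities_random(y.n, G, seed=[*seed, 1, r])
                      for r in range(init.n_runs)]
    z0 = short_run_select(y, s, G, candidates, init, config.em,
                          seed=[*seed, 2])
    fit = fit_single_G(y, s, G, z0, config.em, seed=[*seed, 3])
    logger.info(
        "G=%d: loglik=%.2f iterations=%d converged=%s failed=%s "
        "sampler_gate_failures=%d", G, fit.loglik, fit.iterations,
        fit.converged, fit.failed, fit.diagnostics_summary.get(
            "sampler_gate_failures", 0))
    return G, fit


def run_clustering_range(y: CountMatrix, config: RunConfig,
                         user_offsets=None):
    """Fit every G in [g_min, g_max] and build the cross-G selection report.

    Returns (SelectionReport, {G: FitResult}, offsets).  Individual G
    failures are recorded and the run continues; if every G fails, an error
    is raised.
    """
    s = compute_offsets(y, config, user_offsets)
    gs = list(range(config.g_min, config.g_max + 1))
    results = Parallel(n_jobs=config.parallel_workers, prefer="processes")(
        delayed(fit_one_g)(y, s, G, config) for G in gs
    )
    report = SelectionReport(criterion=config.criterion)
    fits = {}
    for G, fit in results:
        fits[G] = fit
        report.add(G, y.d, y.n, fit.loglik, fit.z,
                   converged=fit.converged, failed=fit.failed)
    if all(rec["failed"] for rec in report.records):
        raise RuntimeError("every candidate G failed to fit")
    return report, fits, s
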