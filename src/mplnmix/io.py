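"""File-format surface: delimited count matrices and run artifacts."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .em import EMControls
from .initialization import InitConfig
from .model import CountMatrix, InputError
from .normalization import NormalizationConfig
from .selection import CRITERIA, SelectionReport

logger = logging.getLogger("mplnmix")

__all__ = ["RunConfig", "load_counts", "save_run", "load_params"]


@dataclass
class RunConfig:
    """Everything that determines a clustering run (and nothing else).

    Outputs are a pure function of the input file and this configuration,
    including ``master_seed``; worker count affects wall time only.
    """

    g_min: int = 1
    g_max: int = 3
    init: InitConfig = field(default_factory=InitConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    em: EMControls = field(default_factory=EMControls)
    criterion: str = "BIC"
    parallel_workers: int = 1
    master_seed: int = 0

    def __post_init__(self):
        if not (1 <= self.g_min <= self.g_max):
            raise InputError("need 1 <= g_min <= g_max")
        if self.criterion.upper() not in CRITERIA:
            raise InputError(f"unknown criterion {self.criterion!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_counts(path, id_column=None) -> CountMatrix:
    """Read a genes x samples matrix of counts from delimited text.

    Auto-detects comma/tab delimiters and the presence of a leading
    identifier column; negatives, non-integers and missing cells are
    rejected with cell-addressed messages.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise InputError(f"{path} contains no data")
    first = df.columns[0]
    if id_column is None:
        id_column = not pd.api.types.is_numeric_dtype(df[first])
    if id_column:
        row_ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    else:
        row_ids = None
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise InputError(f"missing value at row {i} ({path}), column "
                         f"{df.columns[j]!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise InputError(f"non-numeric column {col!r} in {path}")
    values = df.to_numpy()
    return CountMatrix(values, row_ids=row_ids, col_ids=[str(c) for c in df.columns])


def save_run(outdir, y: CountMatrix, report: SelectionReport, fits: dict,
             config: RunConfig, offsets=None) -> dict:
    """Persist a clustering run: criteria, parameters, responsibilities, labels.

    Returns the manifest (also written as JSON) recording configuration,
    seeds and artifact paths, sufficient to reproduce the run bit for bit.
    """
    from .evaluation import map_classify

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    p = os.path.join(outdir, "criteria.csv")
    report.to_csv(p)
    paths["criteria"] = p

    if offsets is not None:
        from .normalization import write_offsets

        p = os.path.join(outdir, "offsets.csv")
        write_offsets(p, offsets)
        paths["offsets"] = p

    for G, fit in sorted(fits.items()):
        tag = f"G{G}"
        pd.DataFrame(fit.params.weights, columns=["weight"]).to_csv(
            os.path.join(outdir, f"{tag}_weights.csv"), index=False)
        pd.DataFrame(np.stack([c.mu for c in fit.params.components]),
                     columns=y.col_ids).to_csv(
            os.path.join(outdir, f"{tag}_means.csv"), index=False)
        sig = np.stack([c.sigma for c in fit.params.components])
        pd.DataFrame(sig.reshape(G * y.d, y.d), columns=y.col_ids).to_csv(
            os.path.join(outdir, f"{tag}_covariances.csv"), index=False)
        zdf = pd.DataFrame(fit.z, columns=[f"z{g+1}" for g in range(G)])
        zdf.insert(0, "gene", y.row_ids)
        zdf.to_csv(os.path.join(outdir, f"{tag}_responsibilities.csv"),
                   index=False)

    best = report.best(config.criterion)
    labels = map_classify(fits[best].z)
    p = os.path.join(outdir, "labels.csv")
    pd.DataFrame({"gene": y.row_ids, "cluster": labels + 1}).to_csv(p,
                                                                    index=False)
    paths["labels"] = p

    # per-cluster mean log-expression profiles (cluster expression patterns)
    logs = np.log1p(y.values.astype(float))
    prof = pd.DataFrame(
        [logs[labels == g].mean(axis=0) for g in range(fits[best].G)],
        columns=y.col_ids)
    prof.insert(0, "cluster", np.arange(1, fits[best].G + 1))
    p = os.path.join(outdir, "cluster_profiles.csv")
    prof.to_csv(p, index=False)
    paths["profiles"] = p

    logpath = os.path.join(outdir, "run.log")
    with open(logpath, "w") as fh:
        fh.write(f"n={y.n} d={y.d} criterion={config.criterion} "
                 f"master_seed={config.master_seed}\n")
        for G, fit in sorted(fits.items()):
            fh.write(f"G={G} loglik={fit.loglik:.4f} "
                     f"iterations={fit.iterations} "
                     f"converged={fit.converged} failed={fit.failed} "
                     f"diagnostics={fit.diagnostics_summary}\n")
        fh.write(f"chosen_G[{config.criterion}]={best}\n")
    paths["log"] = logpath

    manifest = {
        "config": config.to_dict(),
        "chosen_G": {c: _safe_choice(report, c) for c in CRITERIA},
        "paths": paths,
        "n": y.n,
        "d": y.d,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _safe_choice(report, criterion):
    try:
        return report.best(criterion)
    except Exception:
        return None


def load_params(outdir, G: int, d: int):
    """Reload fitted (weights, means, covariances) saved by save_run."""
    from .model import ComponentParams, MixtureParams

    tag = f"G{G}"
    w = pd.read_csv(os.path.join(outdir, f"{tag}_weights.csv"))["weight"].to_numpy()
    mu = pd.read_csv(os.path.join(outdir, f"{tag}_means.csv")).to_numpy()
    sig = pd.read_csv(os.path.join(outdir, f"{tag}_covariances.csv")).to_numpy()
    comps = [ComponentParams(mu[g], sig[g * d:(g + 1) * d]) for g in range(G)]
    return MixtureParams(w, comps)
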