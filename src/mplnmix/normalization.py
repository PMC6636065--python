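"""Per-sample normalization offsets s_j.

The default is the trimmed mean of M-values (TMM): a between-sample scaling
factor computed from doubly trimmed, precision-weighted log2 count ratios
against a reference sample, multiplied by the library-size ratio.  Offsets
are centered to geometric mean 1 so they stay identifiable against the
component means (any common constant would be absorbed by mu_g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CountMatrix, InputError, NormalizationOffsets

__all__ = [
    "NormalizationConfig",
    "tmm_norm_factors",
    "library_size_offsets",
    "read_offsets",
    "write_offsets",
]


@dataclass
class NormalizationConfig:
    method: str = "tmm"             # "tmm" | "library_size" | "user_supplied"
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    ref_sample: int = None

    def __post_init__(self):
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_trim < 0.5):
            raise InputError("trim fractions must lie in [0, 0.5)")
        if self.method not in ("tmm", "library_size", "user_supplied"):
            raise InputError(f"unknown normalization method {self.method!r}")


def library_size_offsets(y: CountMatrix) -> NormalizationOffsets:
    """s_j = library size / geometric mean of library sizes."""
    totals = y.values.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise InputError("every sample needs a positive total count")
    s = totals / np.exp(np.mean(np.log(totals)))
    return NormalizationOffsets(s, sample_ids=list(y.col_ids))


def _tmm_factor_pair(obs, ref, n_obs, n_ref, logratio_trim, abs_trim):
    """TMM factor of one sample against the reference (log2 scale -> ratio)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return None
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method precision weights of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return None
    if np.max(np.abs(m)) < 1e-6:      # identical composition: factor 1
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - np.floor(n * abs_trim)
    rank_m = m.argsort().argsort() + 1
    rank_a = a.argsort().argsort() + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_norm_factors(y: CountMatrix,
                     config: NormalizationConfig = None) -> NormalizationOffsets:
    """Trimmed-mean-of-M-values effective offsets.

    The reference sample is the one whose 75th percentile of count fractions
    is closest to the mean across samples.  Factors are computed over genes
    positive in both sample and reference, doubly trimmed (30% on the log
    ratio M, 5% on the average abundance A), precision-weighted, rescaled to
    geometric mean 1 and multiplied by the centered library sizes.
    """
    config = config or NormalizationConfig()
    counts = y.values.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise InputError("every sample needs a positive total count")
    frac75 = np.percentile(counts / totals, 75, axis=0)
    if config.ref_sample is not None:
        ref_idx = int(config.ref_sample)
    else:
        ref_idx = int(np.argmin(np.abs(frac75 - frac75.mean())))
    factors = np.ones(y.d)
    for j in range(y.d):
        if j == ref_idx:
            continue
        f = _tmm_factor_pair(counts[:, j], counts[:, ref_idx],
                             totals[j], totals[ref_idx],
                             config.logratio_trim, config.abs_trim)
        if f is None:
            warnings.warn(
                f"sample {y.col_ids[j]} shares no positive genes with the "
                "reference; TMM factor set to 1", RuntimeWarning)
            f = 1.0
        factors[j] = f
    factors /= np.exp(np.mean(np.log(factors)))
    s = factors * totals / np.exp(np.mean(np.log(totals)))
    s /= np.exp(np.mean(np.log(s)))  # exact geometric-mean-1 centering
    return NormalizationOffsets(s, sample_ids=list(y.col_ids))


def write_offsets(path, offsets: NormalizationOffsets) -> None:
    pd.DataFrame({"sample": offsets.sample_ids, "offset": offsets.s}
                 ).to_csv(path, index=False)


def read_offsets(path) -> NormalizationOffsets:
    df = pd.read_csv(path)
    if "offset" not in df.columns:
        raise InputError("offsets file needs an 'offset' column")
    ids = df["sample"].astype(str).tolist() if "sample" in df.columns else None
    return NormalizationOffsets(df["offset"].to_numpy(float), sample_ids=ids)
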