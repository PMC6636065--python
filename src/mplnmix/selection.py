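"""Information-criterion model selection across candidate component counts.

Free-parameter count for a G-component, d-dimensional MPLN mixture:

    K = (G - 1) + G d + G d (d + 1) / 2

(mixing weights, means, covariances).  Criteria are reported in the familiar
minimize orientation:

    AIC  = -2 log L + 2 K
    BIC  = -2 log L + K log n
    AIC3 = -2 log L + 3 K
    ICL  = BIC  - 2 sum_i sum_g MAP{z_ig} log z_ig

ICL's entropy correction penalizes uncertain assignments: the sum of
MAP-selected log-responsibilities is <= 0, so ICL >= BIC, with equality for
one-hot responsibilities.  Selection minimizes the chosen criterion, ties
broken toward the smaller G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import InputError

__all__ = ["CriteriaSet", "SelectionReport", "n_free_params", "criteria",
           "select_model"]

CRITERIA = ("AIC", "BIC", "AIC3", "ICL")


def n_free_params(G: int, d: int) -> int:
    """K = (G-1) + Gd + Gd(d+1)/2, exactly."""
    if G < 1 or d < 1:
        raise InputError("G and d must be >= 1")
    return (G - 1) + G * d + G * d * (d + 1) // 2


@dataclass
class CriteriaSet:
    aic: float
    bic: float
    aic3: float
    icl: float

    def value(self, criterion: str) -> float:
        return {"AIC": self.aic, "BIC": self.bic,
                "AIC3": self.aic3, "ICL": self.icl}[criterion.upper()]


def criteria(loglik: float, K: int, n: int, z: np.ndarray) -> CriteriaSet:
    """All four criteria (minimize orientation) from one fitted model."""
    if n < 1:
        raise InputError("n must be >= 1")
    z = np.asarray(z, dtype=float)
    aic = -2.0 * loglik + 2.0 * K
    bic = -2.0 * loglik + K * np.log(n)
    aic3 = -2.0 * loglik + 3.0 * K
    map_probs = z[np.arange(z.shape[0]), z.argmax(axis=1)]
    entropy_term = 2.0 * np.sum(np.log(np.maximum(map_probs, 1e-300)))
    icl = bic - entropy_term
    return CriteriaSet(aic=float(aic), bic=float(bic), aic3=float(aic3),
                       icl=float(icl))


@dataclass
class SelectionReport:
    """Per-G summaries and the cross-G choice for each criterion."""

    records: list = field(default_factory=list)  # dicts with G, K, loglik, ...
    criterion: str = "BIC"

    def add(self, G: int, d: int, n: int, loglik: float, z: np.ndarray,
            converged: bool = True, failed: bool = False) -> None:
        K = n_free_params(G, d)
        cs = criteria(loglik, K, n, z)
        self.records.append({
            "G": G, "K": K, "loglik": loglik, "AIC": cs.aic, "BIC": cs.bic,
            "AIC3": cs.aic3, "ICL": cs.icl, "converged": bool(converged),
            "failed": bool(failed),
        })

    @property
    def chosen_G(self) -> dict:
        return {c: select_model(self.records, c) for c in CRITERIA}

    def best(self, criterion: str = None) -> int:
        return select_model(self.records, criterion or self.criterion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records).sort_values("G").reset_index(drop=True)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False)
        with open(path, "a") as fh:
            for c in CRITERIA:
                try:
                    fh.write(f"# chosen_G[{c}] = {select_model(self.records, c)}\n")
                except (RuntimeError, InputError):
                    fh.write(f"# chosen_G[{c}] = NA\n")


def select_model(reports, criterion: str = "BIC") -> int:
    """G minimizing the criterion among usable fits; ties go to the smaller G.

    Fits that failed outright (component collapse, sampler error) are
    excluded with a warning; completed-but-not-yet-stationary fits are kept,
    also with a warning.
    """
    criterion = criterion.upper()
    if criterion not in CRITERIA:
        raise InputError(f"unknown criterion {criterion!r}")
    usable = []
    for rec in reports:
        rec = rec if isinstance(rec, dict) else dict(rec)
        if rec.get("failed", False):
            warnings.warn(f"G={rec['G']} excluded from selection (fit failed)",
                          RuntimeWarning)
            continue
        if not rec.get("converged", True):
            warnings.warn(f"G={rec['G']} did not reach stationarity; "
                          "kept in selection", RuntimeWarning)
        usable.append(rec)
    if not usable:
        raise RuntimeError("no usable fit to select from")
    usable.sort(key=lambda r: (r[criterion], r["G"]))
    return int(usable[0]["G"])
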