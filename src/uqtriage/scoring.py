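"""Entropy-based uncertainty score and ensemble risk.

The uncertainty score of a nodule is the mean binary entropy (in bits)
of its N member predictions,

    H_bar = (1/N) * sum_i -[p_i log2 p_i + (1 - p_i) log2 (1 - p_i)],

which is 1 when every member predicts 0.5 and 0 when every member is
fully confident (p_i in {0, 1}), regardless of whether the members agree
with each other. The ensemble malignancy risk is the unweighted mean of
the member probabilities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["binary_entropy", "mean_entropy", "ensemble_risk", "score_records"]


def binary_entropy(p):
    """Binary entropy in bits, with the exact 0*log2(0) = 0 convention.

    Accepts a scalar or array of probabilities in [0, 1]; returns the
    same shape. Values outside [0, 1] raise :class:`DomainError`.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr))):
        raise DomainError("probabilities must lie in [0, 1]")
    out = np.zeros_like(arr)
    interior = (arr > 0) & (arr < 1)
    q = arr[interior]
    out[interior] = -(q * np.log2(q) + (1.0 - q) * np.log2(1.0 - q))
    if np.ndim(p) == 0:
        return float(out)
    return out


def mean_entropy(members) -> float:
    """Mean of per-member binary entropies (bits)."""
    arr = np.asarray(members, dtype=float)
    if arr.size == 0:
        raise DomainError("mean_entropy requires at least one member prediction")
    return float(np.mean(binary_entropy(arr)))


def ensemble_risk(members) -> float:
    """Unweighted mean of the member probabilities."""
    arr = np.asarray(members, dtype=float)
    if arr.size == 0:
        raise DomainError("ensemble_risk requires at least one member prediction")
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise DomainError("probabilities must lie in [0, 1]")
    return float(np.mean(arr))


def score_records(records: Sequence) -> pd.DataFrame:
    """Score a cohort: one row per nodule with ``mean_entropy`` and
    ``ensemble_risk`` (plus identity/metadata columns for downstream
    joins)."""
    if not records:
        raise DomainError("score_records requires a non-empty cohort")
    rows = [
        {
            "nodule_id": rec.nodule_id,
            "cohort": rec.cohort,
            "label": int(rec.label),
            "diameter_mm": float(rec.diameter_mm),
            "nodule_type": rec.nodule_type,
            "mean_entropy": mean_entropy(rec.members),
            "ensemble_risk": ensemble_risk(rec.members),
        }
        for rec in records
    ]
    return pd.DataFrame(rows)
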