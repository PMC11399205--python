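"""Percentile-threshold calibration and certain/uncertain triage.

Thresholds are empirical quantiles of the development cohort's
mean-entropy distribution. The quantile uses linear interpolation at
plotting position ``q * (n + 1)`` (R type 6 / "weibull"): with this
convention, calibrating at the q-th percentile and re-classifying the
calibration scores retains at least q% as certain, so the nominal
"90%/95% retained" reading holds exactly on the development data.

A nodule is *uncertain* iff its mean entropy strictly exceeds the
cutoff; a score exactly equal to the cutoff is certain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ThresholdLookupError

__all__ = ["QUANTILE_METHOD", "ThresholdSet", "calibrate_thresholds", "assign_groups"]

#: Quantile interpolation convention used everywhere in the package.
QUANTILE_METHOD = "weibull"

_MIN_STABLE_N = 20


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated percentile cutoffs with their provenance."""

    percentiles: tuple[float, ...]
    cutoffs: tuple[float, ...]
    source_cohort: str
    n_source: int

    def cutoff_for(self, percentile: float) -> float:
        for p, c in zip(self.percentiles, self.cutoffs):
            if math.isclose(p, percentile, rel_tol=0.0, abs_tol=1e-9):
                return c
        raise ThresholdLookupError(
            f"percentile {percentile!r} not calibrated (have {self.percentiles})"
        )

    def to_json(self) -> str:
        payload = [
            {
                "percentile": p,
                "cutoff": c,
                "source_cohort": self.source_cohort,
                "n_source": self.n_source,
            }
            for p, c in zip(self.percentiles, self.cutoffs)
        ]
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        payload = json.loads(text)
        if not payload:
            raise DomainError("empty threshold JSON")
        return cls(
            percentiles=tuple(item["percentile"] for item in payload),
            cutoffs=tuple(item["cutoff"] for item in payload),
            source_cohort=payload[0]["source_cohort"],
            n_source=int(payload[0]["n_source"]),
        )


def calibrate_thresholds(
    scores: Sequence[float],
    percentiles: Sequence[float] = (90.0, 95.0),
    source_cohort: str = "development",
) -> ThresholdSet:
    """Calibrate mean-entropy cutoffs at the given percentiles.

    Fewer than 20 scores triggers a stability warning (not an error);
    an empty input is a :class:`DomainError`.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot calibrate thresholds on an empty score set")
    if np.any(np.isnan(arr)):
        raise DomainError("scores must not contain NaN")
    pcts = tuple(float(p) for p in percentiles)
    if not pcts:
        raise DomainError("at least one percentile is required")
    for p in pcts:
        if not 0.0 < p < 100.0:
            raise DomainError(f"percentile {p!r} must lie strictly between 0 and 100")
    if arr.size < _MIN_STABLE_N:
        warnings.warn(
            f"only {arr.size} scores: percentile cutoffs may be unstable",
            UserWarning,
            stacklevel=2,
        )
    cutoffs = tuple(
        float(np.quantile(arr, p / 100.0, method=QUANTILE_METHOD)) for p in pcts
    )
    return ThresholdSet(
        percentiles=pcts,
        cutoffs=cutoffs,
        source_cohort=source_cohort,
        n_source=int(arr.size),
    )


def assign_groups(
    scores: pd.DataFrame,
    thresholds: ThresholdSet,
    percentile: float,
) -> pd.DataFrame:
    """Split a scored cohort into certain/uncertain at one percentile.

    ``scores`` must carry ``nodule_id`` and ``mean_entropy`` columns
    (the frame produced by :func:`uqtriage.scoring.score_records`).
    Returns a frame with columns ``nodule_id, threshold_percentile,
    group``; a nodule is uncertain iff ``mean_entropy > cutoff``.
    """
    cutoff = thresholds.cutoff_for(percentile)
    entropy = scores["mean_entropy"].to_numpy(dtype=float)
    group = np.where(entropy > cutoff, "uncertain", "certain")
    return pd.DataFrame(
        {
            "nodule_id": scores["nodule_id"].to_numpy(),
            "threshold_percentile": float(percentile),
            "group": group,
        }
    )
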