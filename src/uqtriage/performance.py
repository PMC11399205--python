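"""Discrimination metrics and AUC comparison tests.

AUC is the Mann-Whitney statistic (probability a random malignant
nodule scores above a random benign one, ties counting one half),
computed via midranks. Confidence intervals are percentile bootstrap
over nodule-level resamples. AUC comparisons use DeLong's structural
components: for disjoint groups the variance of the AUC difference is
the sum of the two group variances and the z statistic is referred to
the standard normal. The full-vs-certain comparison involves
overlapping groups whose covariance is not estimable from group-level
inputs; such comparisons carry ``overlapping=True`` as a documented
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateGroupError, DomainError

__all__ = [
    "auc",
    "bootstrap_auc_ci",
    "sensitivity_at_specificity",
    "delong_variance",
    "compare_auc",
    "AucComparison",
    "PerformanceReport",
    "evaluate_group",
]


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("labels must be 0 (benign) or 1 (malignant)")
    y = y.astype(int)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise DegenerateGroupError(
            f"need both classes to assess discrimination (got {n_pos} of {y.size} positive)"
        )
    return s, y


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    s, y = _check_binary(scores, labels)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_auc_ci(
    scores,
    labels,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over nodule-level resamples.

    Resamples that lose a class are redrawn. Deterministic given seed.
    """
    s, y = _check_binary(scores, labels)
    if reps < 1:
        raise DomainError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = s.size
    values = np.empty(reps)
    for i in range(reps):
        while True:
            idx = rng.integers(0, n, n)
            resampled = y[idx]
            if 0 < resampled.sum() < n:
                break
        values[i] = auc(s[idx], resampled)
    low, high = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def sensitivity_at_specificity(scores, labels, target_spec: float = 0.95) -> float:
    """Highest sensitivity over thresholds with specificity >= target.

    A nodule is called positive iff its score strictly exceeds the
    threshold; thresholds sweep the observed scores plus +/- infinity,
    so the all-negative operating point (sens 0, spec 1) always
    qualifies and the maximum is well defined.
    """
    s, y = _check_binary(scores, labels)
    if not 0.0 <= target_spec <= 1.0:
        raise DomainError("target_spec must lie in [0, 1]")
    pos = s[y == 1]
    neg = s[y == 0]
    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    best = 0.0
    for t in thresholds:
        spec = np.mean(neg <= t)
        if spec >= target_spec:
            best = max(best, float(np.mean(pos > t)))
    return best


def _structural_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (per positive) and V01
    (per negative), with ties scored one half."""
    s, y = _check_binary(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimator.

    var = S10 / m + S01 / n with S10, S01 the sample variances of the
    structural components over the m positives and n negatives.
    """
    s, y = _check_binary(scores, labels)
    if y.sum() < 2 or (y.size - y.sum()) < 2:
        raise DomainError("DeLong variance requires at least 2 nodules per class")
    _, v10, v01 = _structural_components(s, y)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


@dataclass(frozen=True)
class AucComparison:
    """DeLong-style comparison of two groups' AUCs."""

    group_a: str
    group_b: str
    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    z_statistic: float
    p_value: float
    paired: bool = False
    overlapping: bool = False


def compare_auc(
    scores_a,
    labels_a,
    scores_b,
    labels_b,
    group_a: str = "a",
    group_b: str = "b",
    overlapping: bool = False,
) -> AucComparison:
    """Unpaired DeLong test: z = (AUC_a - AUC_b) / sqrt(V_a + V_b).

    Set ``overlapping=True`` when the groups share nodules (full vs
    certain): the statistic is computed identically but the report is
    flagged, because the covariance between the two AUCs is ignored.
    """
    auc_a = auc(scores_a, labels_a)
    auc_b = auc(scores_b, labels_b)
    var_a = delong_variance(scores_a, labels_a)
    var_b = delong_variance(scores_b, labels_b)
    denom = math.sqrt(var_a + var_b)
    diff = auc_a - auc_b
    if denom == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / denom
    p = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return AucComparison(
        group_a=group_a,
        group_b=group_b,
        auc_a=auc_a,
        auc_b=auc_b,
        variance_a=var_a,
        variance_b=var_b,
        z_statistic=z,
        p_value=p,
        paired=False,
        overlapping=overlapping,
    )


@dataclass(frozen=True)
class PerformanceReport:
    """Discrimination summary for one group of nodules."""

    group: str
    n_benign: int
    n_malignant: int
    auc: float
    ci_low: float
    ci_high: float
    sensitivity_at_spec95: float
    bootstrap_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_benign": self.n_benign,
            "n_malignant": self.n_malignant,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity_at_spec95": self.sensitivity_at_spec95,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
        }


def evaluate_group(
    scores,
    labels,
    group: str,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    target_spec: float = 0.95,
) -> PerformanceReport:
    """AUC, bootstrap CI and sensitivity at fixed specificity for one group."""
    s, y = _check_binary(scores, labels)
    value = auc(s, y)
    low, high = bootstrap_auc_ci(s, y, reps=bootstrap_reps, seed=seed)
    sens = sensitivity_at_specificity(s, y, target_spec=target_spec)
    return PerformanceReport(
        group=group,
        n_benign=int((y == 0).sum()),
        n_malignant=int((y == 1).sum()),
        auc=value,
        ci_low=min(low, value),
        ci_high=max(high, value),
        sensitivity_at_spec95=sens,
        bootstrap_reps=int(bootstrap_reps),
        seed=int(seed),
    )
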