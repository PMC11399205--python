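"""Size/type subgroup characterization of the certain and uncertain groups.

Size classes follow the Lung-RADS 2022 diameter categories: small
(< 6 mm), medium (>= 6 to < 8 mm) and large (>= 8 mm). Group-level
summaries report counts and percentages by nodule type and size class
and the mean +/- SD and median [IQR] of diameter, separately for benign
and malignant nodules in the certain and uncertain groups. Between-group
tests are the independent-samples t-test on diameter and the chi-square
test on solid-vs-subsolid composition (part-solid and non-solid are
pooled as "subsolid"); 2x2 chi-square tables default to the Yates
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError
from .triage import QUANTILE_METHOD

__all__ = [
    "SIZE_CLASSES",
    "size_class",
    "size_classes",
    "independent_t",
    "chi_square",
    "SubgroupTable",
    "build_subgroup_table",
]

SIZE_CLASSES = ("small", "medium", "large")


def size_class(diameter_mm: float) -> str:
    """Lung-RADS size class: small < 6 mm <= medium < 8 mm <= large."""
    if not diameter_mm > 0:
        raise DomainError(f"diameter must be positive (got {diameter_mm!r})")
    if diameter_mm < 6.0:
        return "small"
    if diameter_mm < 8.0:
        return "medium"
    return "large"


def size_classes(diameters) -> np.ndarray:
    """Vectorized :func:`size_class`."""
    arr = np.asarray(diameters, dtype=float)
    if arr.size and not (arr > 0).all():
        raise DomainError("diameters must be positive")
    out = np.full(arr.shape, "large", dtype=object)
    out[arr < 8.0] = "medium"
    out[arr < 6.0] = "small"
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def independent_t(sample_a, sample_b, variant: str = "pooled") -> TTestResult:
    """Two-sided independent-samples t-test on two samples.

    ``variant`` selects the classical pooled-variance Student test
    (default) or Welch's unequal-variance test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise DomainError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), variant=variant)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    yates: bool


def chi_square(table, yates: Optional[bool] = None) -> ChiSquareResult:
    """Pearson chi-square test on an r x c contingency table.

    ``yates=None`` applies the continuity correction automatically for
    2x2 tables and never otherwise; pass an explicit boolean to
    override. A structural zero margin (expected count 0) is a
    :class:`DomainError`.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DomainError("table must be at least 2x2")
    if np.any(arr < 0):
        raise DomainError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DomainError("table has a zero row/column margin (expected count 0)")
    if yates is None:
        yates = arr.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p), yates=bool(yates))


_LABEL_NAMES = {0: "benign", 1: "malignant"}


@dataclass
class SubgroupTable:
    """Certain/uncertain characterization split by label.

    ``table`` has one row per (label, group) with counts, percentages,
    and diameter summaries; ``tests`` holds, per label, the t-test on
    diameter and the solid-vs-subsolid chi-square between the certain
    and uncertain groups (absent when either group is empty).
    """

    table: pd.DataFrame
    tests: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")

    def to_dict(self) -> dict:
        return {
            "rows": self.table.to_dict(orient="records"),
            "tests": self.tests,
        }


def _quantiles(x: np.ndarray, qs=(0.25, 0.5, 0.75)) -> list[float]:
    return [float(np.quantile(x, q, method=QUANTILE_METHOD)) for q in qs]


def _summarize_cell(label: int, group: str, sub: pd.DataFrame) -> dict:
    row: dict = {
        "label": _LABEL_NAMES[label],
        "group": group,
        "n": int(len(sub)),
    }
    n = len(sub)
    for t in ("solid", "part_solid", "non_solid"):
        count = int((sub["nodule_type"] == t).sum())
        row[f"n_{t}"] = count
        row[f"pct_{t}"] = 100.0 * count / n if n else 0.0
    classes = size_classes(sub["diameter_mm"].to_numpy()) if n else np.array([], dtype=object)
    for c in SIZE_CLASSES:
        count = int((classes == c).sum())
        row[f"n_{c}"] = count
        row[f"pct_{c}"] = 100.0 * count / n if n else 0.0
    if n:
        d = sub["diameter_mm"].to_numpy(dtype=float)
        q1, med, q3 = _quantiles(d)
        row.update(
            {
                "diameter_mean": float(d.mean()),
                "diameter_sd": float(d.std(ddof=1)) if n > 1 else 0.0,
                "diameter_median": med,
                "diameter_q1": q1,
                "diameter_q3": q3,
            }
        )
    else:
        row.update(
            {
                "diameter_mean": np.nan,
                "diameter_sd": np.nan,
                "diameter_median": np.nan,
                "diameter_q1": np.nan,
                "diameter_q3": np.nan,
            }
        )
    return row


def build_subgroup_table(
    cohort: pd.DataFrame,
    assignments: pd.DataFrame,
    t_variant: str = "pooled",
) -> SubgroupTable:
    """Build the certain/uncertain characterization table.

    ``cohort`` needs columns ``nodule_id, label, diameter_mm,
    nodule_type`` (a scored frame works); ``assignments`` is the output
    of :func:`uqtriage.triage.assign_groups` at one percentile. Every
    cohort row must have an assignment. Empty cells are reported with
    zero counts; between-group tests are emitted only when both the
    certain and uncertain group of a label are non-empty (and large
    enough for the test).
    """
    merged = cohort.merge(assignments[["nodule_id", "group"]], on="nodule_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "nodule_id"].iloc[0]
        raise DomainError(f"no group assignment for nodule_id {missing!r}")
    if len(merged) != len(cohort):
        raise DomainError("assignments contain duplicate nodule_ids")

    rows = []
    tests: dict = {}
    for label in (0, 1):
        by_group = {}
        for group in ("certain", "uncertain"):
            sub = merged[(merged["label"] == label) & (merged["group"] == group)]
            by_group[group] = sub
            rows.append(_summarize_cell(label, group, sub))
        certain, uncertain = by_group["certain"], by_group["uncertain"]
        label_tests: dict = {}
        if len(certain) >= 2 and len(uncertain) >= 2:
            tt = independent_t(
                certain["diameter_mm"].to_numpy(),
                uncertain["diameter_mm"].to_numpy(),
                variant=t_variant,
            )
            label_tests["diameter_t"] = {
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "variant": tt.variant,
            }
            table = np.array(
                [
                    [
                        int((certain["nodule_type"] == "solid").sum()),
                        int((certain["nodule_type"] != "solid").sum()),
                    ],
                    [
                        int((uncertain["nodule_type"] == "solid").sum()),
                        int((uncertain["nodule_type"] != "solid").sum()),
                    ],
                ]
            )
            if not (np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)):
                cs = chi_square(table)
                label_tests["solid_vs_subsolid_chi2"] = {
                    "chi2": cs.chi2,
                    "df": cs.df,
                    "p": cs.p,
                    "yates": cs.yates,
                }
        if label_tests:
            tests[_LABEL_NAMES[label]] = label_tests

    return SubgroupTable(table=pd.DataFrame(rows), tests=tests)
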