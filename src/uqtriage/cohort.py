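"""Synthetic nodule cohorts with ensemble prediction vectors.

This module generates cohorts of pulmonary nodules, each carrying a
ground-truth label (benign/malignant), a diameter, a radiological type
(solid, part-solid, non-solid) and a vector of N probabilistic malignancy
predictions emulating the members of a deep-learning ensemble.

The generative model is built around a latent per-nodule *difficulty*
``d`` in [0, 1]:

* ``d`` rises for subsolid nodules and for nodules whose size is atypical
  for their class (large benign, small malignant) — the case mix that
  screening readers and risk models find hardest.
* The ensemble "leans" toward the correct class with probability
  ``sigmoid(accuracy * (1 - d)**accuracy_decay)``, so discrimination
  degrades smoothly with difficulty.
* The consensus probability is ``sigmoid(lean * magnitude)`` with
  magnitude ``separation * (1 - d)``: easy cases get confident (extreme)
  probabilities, hard cases hover near 0.5.
* Individual members are conditionally i.i.d. draws from a Beta
  distribution centred on the consensus, with concentration interpolating
  (geometrically) from ``concentration_confident`` at ``d = 0`` down to
  ``concentration_uncertain`` at ``d = 1``.

As a consequence the mean binary entropy of the members increases with
difficulty, uncertain cases are enriched for subsolid and atypically
sized nodules, and discrimination within the uncertain stratum collapses
toward chance — the structure the triage analysis is designed to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortParseError, ConfigurationError, SchemaError

__all__ = [
    "NODULE_TYPES",
    "LogNormalSize",
    "DifficultyModel",
    "MemberModel",
    "CohortConfig",
    "NoduleRecord",
    "generate_cohort",
    "records_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
    "validate_cohort_frame",
    "development_config",
    "external_config",
    "cohort_config_from_dict",
    "calibrate_accuracy",
]

NODULE_TYPES = ("solid", "part_solid", "non_solid")

_SIZE_FLOOR_MM = 2.0


@dataclass(frozen=True)
class LogNormalSize:
    """Log-normal diameter model, truncated below at 2 mm.

    ``median_mm`` is the median of the untruncated distribution and
    ``sigma`` the standard deviation of log-diameter.
    """

    median_mm: float
    sigma: float


@dataclass(frozen=True)
class DifficultyModel:
    """Covariate effects on the latent difficulty.

    ``base`` is the difficulty of a typical solid nodule;
    ``subsolid_shift`` is added for part-solid and non-solid nodules;
    ``atypical_benign_shift`` is added to benign nodules in proportion to
    ``sigmoid((diameter - size_midpoint_mm) / size_scale_mm)`` (large
    benign nodules are atypical), and ``atypical_malignant_shift``
    symmetrically to malignant nodules in proportion to the complement
    (small malignant nodules are atypical). Gaussian jitter with standard
    deviation ``noise_sd`` is added before clipping to [0, 1].
    """

    base: float = 0.06
    subsolid_shift: float = 0.32
    atypical_benign_shift: float = 0.65
    atypical_malignant_shift: float = 0.70
    size_midpoint_mm: float = 11.0
    size_scale_mm: float = 3.0
    noise_sd: float = 0.13


@dataclass(frozen=True)
class MemberModel:
    """How the ensemble responds to a nodule of difficulty ``d``.

    ``accuracy`` controls the probability that the ensemble consensus
    leans toward the correct class (the stratum-level AUC);
    ``accuracy_decay`` is the exponent with which that probability decays
    toward chance as difficulty rises. ``separation`` is the consensus
    logit magnitude at zero difficulty and ``magnitude_jitter`` its
    log-scale noise (suppressed at ``d = 0`` so zero-difficulty cohorts
    are uniformly confident). The two concentrations bound the Beta
    concentration of member draws at ``d = 0`` and ``d = 1``.
    """

    separation: float = 5.0
    accuracy: float = 6.0
    accuracy_decay: float = 3.0
    magnitude_jitter: float = 0.5
    concentration_confident: float = 4000.0
    concentration_uncertain: float = 12.0


def _default_type_mix() -> dict[int, tuple[float, float, float]]:
    # Screening-like composition: benign mostly solid with a non-solid
    # minority; malignant with a substantial part-solid share.
    return {0: (0.850, 0.033, 0.117), 1: (0.692, 0.185, 0.123)}


def _default_sizes() -> dict[int, LogNormalSize]:
    return {0: LogNormalSize(5.0, 0.41), 1: LogNormalSize(11.0, 0.56)}


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``type_mix`` and ``size_distribution`` are per-label (0 = benign,
    1 = malignant) mappings; a single mix applied to both labels may be
    given as a plain 3-tuple.
    """

    n_nodules: int
    malignant_fraction: float
    n_members: int = 20
    cohort: str = "development"
    type_mix: Mapping[int, tuple[float, float, float]] = field(
        default_factory=_default_type_mix
    )
    size_distribution: Mapping[int, LogNormalSize] = field(default_factory=_default_sizes)
    difficulty_model: DifficultyModel = field(default_factory=DifficultyModel)
    member_model: MemberModel = field(default_factory=MemberModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.type_mix, (tuple, list)):
            mix = tuple(float(x) for x in self.type_mix)
            object.__setattr__(self, "type_mix", {0: mix, 1: mix})
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_nodules, (int, np.integer)) or self.n_nodules < 1:
            raise ConfigurationError("n_nodules must be a positive integer")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ConfigurationError("malignant_fraction must lie in [0, 1]")
        if not isinstance(self.n_members, (int, np.integer)) or self.n_members < 2:
            raise ConfigurationError("n_members must be an integer >= 2")
        for label in (0, 1):
            if label not in self.type_mix:
                raise ConfigurationError(f"type_mix missing entry for label {label}")
            mix = self.type_mix[label]
            if len(mix) != len(NODULE_TYPES) or any(p < 0 for p in mix):
                raise ConfigurationError("type_mix entries must be 3 non-negative proportions")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"type_mix for label {label} must sum to 1 (got {sum(mix)!r})"
                )
            if label not in self.size_distribution:
                raise ConfigurationError(f"size_distribution missing entry for label {label}")
            size = self.size_distribution[label]
            if size.median_mm <= 0 or size.sigma <= 0:
                raise ConfigurationError("size_distribution parameters must be positive")
        dm = self.difficulty_model
        if dm.size_scale_mm <= 0:
            raise ConfigurationError("difficulty_model.size_scale_mm must be positive")
        if dm.noise_sd < 0:
            raise ConfigurationError("difficulty_model.noise_sd must be non-negative")
        mm = self.member_model
        for name in (
            "separation",
            "accuracy",
            "accuracy_decay",
            "concentration_confident",
            "concentration_uncertain",
        ):
            if getattr(mm, name) <= 0:
                raise ConfigurationError(f"member_model.{name} must be positive")
        if mm.magnitude_jitter < 0:
            raise ConfigurationError("member_model.magnitude_jitter must be non-negative")


@dataclass
class NoduleRecord:
    """One nodule: identity, metadata, and its N member predictions."""

    nodule_id: str
    cohort: str
    label: int
    diameter_mm: float
    nodule_type: str
    members: np.ndarray

    def validate(self) -> None:
        if self.label not in (0, 1):
            raise SchemaError(f"{self.nodule_id}: label must be 0 or 1")
        if not self.diameter_mm > 0:
            raise SchemaError(f"{self.nodule_id}: diameter_mm must be positive")
        if self.nodule_type not in NODULE_TYPES:
            raise SchemaError(f"{self.nodule_id}: unknown nodule_type {self.nodule_type!r}")
        members = np.asarray(self.members, dtype=float)
        if members.ndim != 1 or members.size == 0:
            raise SchemaError(f"{self.nodule_id}: members must be a non-empty vector")
        if np.any(members < 0) or np.any(members > 1):
            raise SchemaError(f"{self.nodule_id}: member probabilities must lie in [0, 1]")


def development_config(n_nodules: int = 883, seed: int = 0, **overrides) -> CohortConfig:
    """Screening-like development cohort (default 883 nodules, 65 malignant)."""
    params: dict = dict(
        n_nodules=n_nodules,
        malignant_fraction=65 / 883,
        cohort="development",
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def external_config(n_nodules: int = 374, seed: int = 1, **overrides) -> CohortConfig:
    """Clinical-like external cohort: malignant-rich, larger nodules,
    and a higher baseline difficulty reflecting the domain shift from
    screening to heterogeneous clinical acquisitions."""
    params: dict = dict(
        n_nodules=n_nodules,
        malignant_fraction=207 / 374,
        cohort="external",
        type_mix={0: (0.81, 0.05, 0.14), 1: (0.90, 0.072, 0.028)},
        size_distribution={0: LogNormalSize(6.8, 0.58), 1: LogNormalSize(22.4, 0.65)},
        difficulty_model=DifficultyModel(base=0.18),
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def _sample_truncated_lognormal(
    rng: np.random.Generator, size_model: LogNormalSize, n: int
) -> np.ndarray:
    """Draw log-normal diameters, resampling any below the 2 mm floor."""
    out = rng.lognormal(math.log(size_model.median_mm), size_model.sigma, size=n)
    for _ in range(100):
        low = out < _SIZE_FLOOR_MM
        if not low.any():
            return out
        out[low] = rng.lognormal(math.log(size_model.median_mm), size_model.sigma, low.sum())
    # Pathological parameters (mass almost entirely below the floor).
    out[out < _SIZE_FLOOR_MM] = _SIZE_FLOOR_MM
    return out


def _latent_difficulty(
    rng: np.random.Generator,
    dm: DifficultyModel,
    labels: np.ndarray,
    diameters: np.ndarray,
    subsolid: np.ndarray,
) -> np.ndarray:
    large = 1.0 / (1.0 + np.exp(-(diameters - dm.size_midpoint_mm) / dm.size_scale_mm))
    d = (
        dm.base
        + dm.subsolid_shift * subsolid
        + dm.atypical_benign_shift * (1 - labels) * large
        + dm.atypical_malignant_shift * labels * (1.0 - large)
    )
    d = d + rng.normal(0.0, dm.noise_sd, size=labels.shape) if dm.noise_sd > 0 else d + 0.0
    return np.clip(d, 0.0, 1.0)


def _member_matrix(
    rng: np.random.Generator,
    mm: MemberModel,
    labels: np.ndarray,
    difficulty: np.ndarray,
    n_members: int,
) -> np.ndarray:
    n = labels.shape[0]
    lean_correct_prob = 1.0 / (1.0 + np.exp(-mm.accuracy * (1.0 - difficulty) ** mm.accuracy_decay))
    correct = rng.random(n) < lean_correct_prob
    lean = np.where(correct, 2 * labels - 1, 1 - 2 * labels)
    magnitude = mm.separation * (1.0 - difficulty)
    if mm.magnitude_jitter > 0:
        magnitude = magnitude * np.exp(mm.magnitude_jitter * difficulty * rng.normal(0.0, 1.0, n))
    mu = 1.0 / (1.0 + np.exp(-lean * magnitude))
    log_k0 = math.log(mm.concentration_confident)
    log_k1 = math.log(mm.concentration_uncertain)
    kappa = np.exp((1.0 - difficulty) * log_k0 + difficulty * log_k1)
    a = mu * kappa
    b = (1.0 - mu) * kappa
    return rng.beta(a[:, None], b[:, None], size=(n, n_members))


def generate_cohort(config: CohortConfig) -> list[NoduleRecord]:
    """Generate a seeded, reproducible synthetic cohort.

    The number of malignant nodules is ``round(n * malignant_fraction)``;
    their positions in the cohort are a seeded permutation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_nodules)
    n_mal = int(round(n * config.malignant_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_mal] = 1
    labels = rng.permutation(labels)

    types = np.empty(n, dtype=object)
    diameters = np.empty(n, dtype=float)
    for label in (0, 1):
        idx = np.flatnonzero(labels == label)
        if idx.size == 0:
            continue
        mix = np.asarray(config.type_mix[label], dtype=float)
        mix = mix / mix.sum()
        types[idx] = rng.choice(NODULE_TYPES, size=idx.size, p=mix)
        diameters[idx] = _sample_truncated_lognormal(
            rng, config.size_distribution[label], idx.size
        )

    subsolid = (types != "solid").astype(float)
    difficulty = _latent_difficulty(rng, config.difficulty_model, labels, diameters, subsolid)
    members = _member_matrix(rng, config.member_model, labels, difficulty, config.n_members)

    width = max(5, len(str(n)))
    return [
        NoduleRecord(
            nodule_id=f"{config.cohort}-{i:0{width}d}",
            cohort=config.cohort,
            label=int(labels[i]),
            diameter_mm=float(diameters[i]),
            nodule_type=str(types[i]),
            members=members[i].copy(),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["nodule_id", "cohort", "label", "diameter_mm", "nodule_type"]


def _member_columns(n_members: int) -> list[str]:
    width = max(2, len(str(n_members)))
    return [f"member_{i + 1:0{width}d}" for i in range(n_members)]


def records_to_frame(records: Sequence[NoduleRecord]) -> pd.DataFrame:
    """Tabulate records; member columns are ``member_01 .. member_NN``."""
    if not records:
        raise SchemaError("cannot tabulate an empty record list")
    n_members = len(records[0].members)
    cols = _member_columns(n_members)
    rows = []
    for rec in records:
        if len(rec.members) != n_members:
            raise SchemaError(
                f"{rec.nodule_id}: member count {len(rec.members)} != {n_members}"
            )
        row = {
            "nodule_id": rec.nodule_id,
            "cohort": rec.cohort,
            "label": int(rec.label),
            "diameter_mm": float(rec.diameter_mm),
            "nodule_type": rec.nodule_type,
        }
        row.update({c: float(v) for c, v in zip(cols, rec.members)})
        rows.append(row)
    return pd.DataFrame(rows, columns=_BASE_COLUMNS + cols)


def frame_to_records(frame: pd.DataFrame) -> list[NoduleRecord]:
    member_cols = [c for c in frame.columns if c.startswith("member_")]
    records = []
    for _, row in frame.iterrows():
        rec = NoduleRecord(
            nodule_id=str(row["nodule_id"]),
            cohort=str(row["cohort"]),
            label=int(row["label"]),
            diameter_mm=float(row["diameter_mm"]),
            nodule_type=str(row["nodule_type"]),
            members=row[member_cols].to_numpy(dtype=float),
        )
        rec.validate()
        records.append(rec)
    return records


def write_cohort(records: Sequence[NoduleRecord], path) -> None:
    """Write records as UTF-8, LF-terminated CSV (lossless round-trip)."""
    frame = records_to_frame(records)
    # %.17g round-trips every IEEE double exactly
    frame.to_csv(
        path,
        index=False,
        lineterminator="\n",
        encoding="utf-8",
        float_format=lambda v: format(v, ".17g"),
    )


def validate_cohort_frame(frame: pd.DataFrame) -> list[dict]:
    """Per-row schema/range/enum diagnostics for a cohort table.

    Each diagnostic is ``{"row": <0-based data row>, "column": str,
    "message": str}``; ``row`` is None for table-level problems.
    Returns an empty list for a valid table.
    """
    diagnostics: list[dict] = []
    for col in _BASE_COLUMNS:
        if col not in frame.columns:
            diagnostics.append(
                {"row": None, "column": col, "message": f"missing required column {col!r}"}
            )
    member_cols = [c for c in frame.columns if c.startswith("member_")]
    if not member_cols:
        diagnostics.append(
            {"row": None, "column": "member_*", "message": "no member columns found"}
        )
    expected = _member_columns(len(member_cols))
    if member_cols and member_cols != expected:
        diagnostics.append(
            {
                "row": None,
                "column": "member_*",
                "message": (
                    f"member columns {member_cols} do not form the contiguous block "
                    f"{expected[0]}..{expected[-1]}"
                ),
            }
        )
    if diagnostics:
        return diagnostics

    ids = frame["nodule_id"].astype(str)
    for row_idx in ids.index[ids.duplicated()]:
        diagnostics.append(
            {
                "row": int(row_idx),
                "column": "nodule_id",
                "message": f"duplicated nodule_id {ids[row_idx]!r}",
            }
        )

    def _numeric(col: str) -> pd.Series:
        values = pd.to_numeric(frame[col], errors="coerce")
        for row_idx in values.index[values.isna() & frame[col].notna()]:
            diagnostics.append(
                {
                    "row": int(row_idx),
                    "column": col,
                    "message": f"non-numeric value {frame.loc[row_idx, col]!r}",
                }
            )
        for row_idx in values.index[frame[col].isna()]:
            diagnostics.append(
                {"row": int(row_idx), "column": col, "message": "missing value"}
            )
        return values

    labels = _numeric("label")
    for row_idx in labels.index[labels.notna() & ~labels.isin([0, 1])]:
        diagnostics.append(
            {
                "row": int(row_idx),
                "column": "label",
                "message": f"label must be 0 or 1 (got {labels[row_idx]!r})",
            }
        )
    diameters = _numeric("diameter_mm")
    for row_idx in diameters.index[diameters.notna() & (diameters <= 0)]:
        diagnostics.append(
            {
                "row": int(row_idx),
                "column": "diameter_mm",
                "message": f"diameter_mm must be positive (got {diameters[row_idx]!r})",
            }
        )
    types = frame["nodule_type"].astype(str)
    for row_idx in types.index[~types.isin(NODULE_TYPES)]:
        diagnostics.append(
            {
                "row": int(row_idx),
                "column": "nodule_type",
                "message": f"unknown nodule_type {types[row_idx]!r}",
            }
        )
    for col in member_cols:
        values = _numeric(col)
        bad = values.notna() & ((values < 0) | (values > 1))
        for row_idx in values.index[bad]:
            diagnostics.append(
                {
                    "row": int(row_idx),
                    "column": col,
                    "message": (
                        f"probability {values[row_idx]!r} outside [0, 1] for "
                        f"nodule_id {ids[row_idx]!r}"
                    ),
                }
            )
    return diagnostics


def read_cohort(path) -> list[NoduleRecord]:
    """Read a cohort CSV, validating schema and value ranges.

    Raises :class:`SchemaError` citing the first offending row/column.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    diagnostics = validate_cohort_frame(frame)
    if diagnostics:
        first = diagnostics[0]
        where = "table" if first["row"] is None else f"row {first['row'] + 2}"  # header = row 1
        raise SchemaError(f"{path}: {where}, column {first['column']}: {first['message']}")
    return frame_to_records(frame)


# ---------------------------------------------------------------------------
# AUC calibration
# ---------------------------------------------------------------------------


def _cohort_auc(config: CohortConfig) -> float:
    from .performance import auc
    from .scoring import score_records

    records = generate_cohort(config)
    scores = score_records(records)
    labels = np.array([r.label for r in records])
    return auc(scores["ensemble_risk"].to_numpy(), labels)


def calibrate_accuracy(
    config: CohortConfig,
    target_auc: float,
    n: int = 4000,
    seed: int = 12345,
    tol: float = 0.005,
    max_iter: int = 40,
) -> CohortConfig:
    """Return a copy of ``config`` whose ensemble accuracy is tuned so the
    full-cohort AUC hits ``target_auc``.

    The full-cohort AUC is monotone in ``member_model.accuracy``, so a
    bisection on a large (size ``n``) cohort generated with a fixed
    calibration seed converges quickly. The returned config keeps the
    original ``n_nodules`` and ``seed``.
    """
    if not 0.5 < target_auc < 1.0:
        raise ConfigurationError("target_auc must lie in (0.5, 1)")
    probe = replace(config, n_nodules=int(n), seed=int(seed))

    def auc_at(accuracy: float) -> float:
        cfg = replace(probe, member_model=replace(probe.member_model, accuracy=accuracy))
        return _cohort_auc(cfg)

    lo, hi = 0.05, 60.0
    auc_lo, auc_hi = auc_at(lo), auc_at(hi)
    if target_auc <= auc_lo:
        best = lo
    elif target_auc >= auc_hi:
        best = hi
    else:
        best = math.sqrt(lo * hi)
        for _ in range(max_iter):
            mid = math.sqrt(lo * hi)  # bisect in log space
            value = auc_at(mid)
            best = mid
            if abs(value - target_auc) <= tol:
                break
            if value < target_auc:
                lo = mid
            else:
                hi = mid
    return replace(config, member_model=replace(config.member_model, accuracy=best))


def cohort_config_from_dict(data: Mapping) -> CohortConfig:
    """Build a CohortConfig from a flat-key mapping (e.g. parsed YAML)."""
    data = dict(data)
    if "type_mix" in data and isinstance(data["type_mix"], Mapping):
        data["type_mix"] = {
            int(k): tuple(float(x) for x in v) for k, v in data["type_mix"].items()
        }
    if "size_distribution" in data:
        data["size_distribution"] = {
            int(k): LogNormalSize(**v) if isinstance(v, Mapping) else LogNormalSize(*v)
            for k, v in data["size_distribution"].items()
        }
    if isinstance(data.get("difficulty_model"), Mapping):
        data["difficulty_model"] = DifficultyModel(**data["difficulty_model"])
    if isinstance(data.get("member_model"), Mapping):
        data["member_model"] = MemberModel(**data["member_model"])
    try:
        return CohortConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
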