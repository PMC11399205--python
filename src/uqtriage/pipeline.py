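"""End-to-end orchestration: score, calibrate, triage, evaluate, summarize.

A run takes a development cohort (CSV path or synthetic config) and
optionally an external cohort, calibrates mean-entropy thresholds on
the development cohort, applies them to both cohorts, and writes a
machine-readable report bundle:

* ``<cohort>_scores.csv``     — per-nodule mean entropy and ensemble risk
* ``thresholds.json``         — calibrated cutoffs with provenance
* ``<cohort>_assignments.csv``— certain/uncertain per percentile
* ``performance.json``        — AUC, bootstrap CI, sensitivity at 95%
                                specificity, and DeLong comparisons for
                                full/certain/uncertain per percentile
* ``<cohort>_subgroups.csv`` / ``.json`` — size/type characterization
* ``manifest.json``           — seed, version, config hash, stage counts

One global seed fans out deterministically to per-stage substreams
(cohort generation, bootstrap per group) so the bundle is byte-identical
across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, cohort_config_from_dict, generate_cohort, read_cohort, validate_cohort_frame
from .exceptions import ConfigurationError, UQTriageError
from .performance import compare_auc, evaluate_group
from .scoring import score_records
from .subgroups import build_subgroup_table
from .triage import ThresholdSet, assign_groups, calibrate_thresholds

__all__ = ["RunConfig", "RunResult", "run_pipeline", "validate_inputs", "run_config_from_yaml"]

logger = logging.getLogger("uqtriage")

CohortInput = Union[str, Path, CohortConfig]


@dataclass(frozen=True)
class RunConfig:
    development_input: CohortInput
    external_input: Optional[CohortInput] = None
    percentiles: tuple[float, ...] = (90.0, 95.0)
    subgroup_percentile: float = 90.0
    bootstrap_reps: int = 1000
    seed: int = 0
    output_dir: Union[str, Path] = "uqtriage_run"

    def validate(self) -> None:
        for p in self.percentiles:
            if not 0.0 < p < 100.0:
                raise ConfigurationError(
                    f"percentiles must lie strictly between 0 and 100 (got {p!r})"
                )
        if self.subgroup_percentile not in self.percentiles:
            raise ConfigurationError("subgroup_percentile must be one of percentiles")
        if self.bootstrap_reps < 1:
            raise ConfigurationError("bootstrap_reps must be >= 1")


@dataclass
class RunResult:
    output_dir: Path
    thresholds: ThresholdSet
    performance: dict
    scores: dict
    assignments: dict
    subgroups: dict
    manifest: dict


def run_config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from YAML.

    The ``development`` and ``external`` sections are either
    ``{path: file.csv}`` or an inline cohort config mapping.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}

    def cohort_input(section) -> Optional[CohortInput]:
        if section is None:
            return None
        if isinstance(section, str):
            return section
        if "path" in section:
            return section["path"]
        return cohort_config_from_dict(section)

    dev = cohort_input(data.get("development"))
    if dev is None:
        raise ConfigurationError("config must define a development input")
    kwargs = dict(
        development_input=dev,
        external_input=cohort_input(data.get("external")),
        bootstrap_reps=int(data.get("bootstrap_reps", 1000)),
        seed=int(data.get("seed", 0)),
        output_dir=data.get("output_dir", "uqtriage_run"),
    )
    if "percentiles" in data:
        kwargs["percentiles"] = tuple(float(p) for p in data["percentiles"])
    if "subgroup_percentile" in data:
        kwargs["subgroup_percentile"] = float(data["subgroup_percentile"])
    config = RunConfig(**kwargs)
    config.validate()
    return config


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit stage seeds from the global seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _config_hash(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = encode(config)
    payload.pop("output_dir", None)  # bundle content must not depend on its location
    canonical = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _load_cohort(inp: CohortInput, generation_seed: int, tag: str):
    if isinstance(inp, CohortConfig):
        config = replace(inp, seed=generation_seed)
        records = generate_cohort(config)
        logger.info("stage=generate cohort=%s n=%d (synthetic)", tag, len(records))
    else:
        records = read_cohort(inp)
        logger.info("stage=load cohort=%s n=%d path=%s", tag, len(records), inp)
    return records


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _evaluate_cohort(
    tag: str,
    scores: pd.DataFrame,
    thresholds: ThresholdSet,
    percentiles,
    bootstrap_reps: int,
    boot_seeds: list[int],
) -> tuple[dict, pd.DataFrame]:
    """Table-2-style performance block for one cohort, plus assignments
    at every percentile stacked into one frame."""
    risk = scores["ensemble_risk"].to_numpy()
    labels = scores["label"].to_numpy()
    seed_iter = iter(boot_seeds)
    block: dict = {
        "full": evaluate_group(
            risk, labels, f"{tag}/full", bootstrap_reps, next(seed_iter)
        ).to_dict()
    }
    assignment_frames = []
    for p in percentiles:
        assignment = assign_groups(scores, thresholds, p)
        assignment_frames.append(assignment)
        mask_uncertain = (assignment["group"] == "uncertain").to_numpy()
        entry: dict = {
            "n_certain": int((~mask_uncertain).sum()),
            "n_uncertain": int(mask_uncertain.sum()),
            "certain_fraction": float((~mask_uncertain).mean()),
        }
        groups = {"certain": ~mask_uncertain, "uncertain": mask_uncertain}
        for name, mask in groups.items():
            try:
                entry[name] = evaluate_group(
                    risk[mask], labels[mask], f"{tag}/{name}@{p:g}", bootstrap_reps, next(seed_iter)
                ).to_dict()
            except UQTriageError as exc:
                entry[name] = {"error": str(exc), "n": int(mask.sum())}
        try:
            cmp_cu = compare_auc(
                risk[groups["certain"]],
                labels[groups["certain"]],
                risk[groups["uncertain"]],
                labels[groups["uncertain"]],
                group_a=f"{tag}/certain@{p:g}",
                group_b=f"{tag}/uncertain@{p:g}",
            )
            entry["certain_vs_uncertain"] = dataclasses.asdict(cmp_cu)
        except UQTriageError as exc:
            entry["certain_vs_uncertain"] = {"error": str(exc)}
        try:
            cmp_fc = compare_auc(
                risk,
                labels,
                risk[groups["certain"]],
                labels[groups["certain"]],
                group_a=f"{tag}/full",
                group_b=f"{tag}/certain@{p:g}",
                overlapping=True,
            )
            entry["full_vs_certain"] = dataclasses.asdict(cmp_fc)
        except UQTriageError as exc:
            entry["full_vs_certain"] = {"error": str(exc)}
        block[f"p{p:g}"] = entry
        logger.info(
            "stage=evaluate cohort=%s percentile=%g certain=%d uncertain=%d",
            tag, p, entry["n_certain"], entry["n_uncertain"],
        )
    assignments = pd.concat(assignment_frames, ignore_index=True)
    return block, assignments


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write the report bundle.

    Identical config + seed produce a byte-identical bundle.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 2 + 2 * (1 + 2 * len(config.percentiles)))
    gen_dev, gen_ext = seeds[0], seeds[1]
    n_boot_each = 1 + 2 * len(config.percentiles)
    boot_dev = seeds[2 : 2 + n_boot_each]
    boot_ext = seeds[2 + n_boot_each :]

    dev_records = _load_cohort(config.development_input, gen_dev, "development")
    dev_scores = score_records(dev_records)
    dev_scores.to_csv(out / "development_scores.csv", index=False, lineterminator="\n")
    logger.info("stage=score cohort=development n=%d", len(dev_scores))

    thresholds = calibrate_thresholds(
        dev_scores["mean_entropy"].to_numpy(),
        percentiles=config.percentiles,
        source_cohort="development",
    )
    (out / "thresholds.json").write_text(thresholds.to_json() + "\n", encoding="utf-8")
    logger.info("stage=calibrate cutoffs=%s", dict(zip(thresholds.percentiles, thresholds.cutoffs)))

    performance: dict = {}
    scores = {"development": dev_scores}
    assignments: dict = {}
    subgroups: dict = {}

    performance["development"], dev_assign = _evaluate_cohort(
        "development", dev_scores, thresholds, config.percentiles, config.bootstrap_reps, boot_dev
    )
    assignments["development"] = dev_assign
    dev_assign.to_csv(out / "development_assignments.csv", index=False, lineterminator="\n")

    sub_assign = dev_assign[dev_assign["threshold_percentile"] == config.subgroup_percentile]
    dev_subgroups = build_subgroup_table(dev_scores, sub_assign)
    subgroups["development"] = dev_subgroups
    dev_subgroups.to_csv(out / "development_subgroups.csv")
    _write_json(out / "development_subgroups.json", dev_subgroups.to_dict())

    if config.external_input is not None:
        ext_records = _load_cohort(config.external_input, gen_ext, "external")
        ext_scores = score_records(ext_records)
        ext_scores.to_csv(out / "external_scores.csv", index=False, lineterminator="\n")
        logger.info("stage=score cohort=external n=%d", len(ext_scores))
        scores["external"] = ext_scores
        performance["external"], ext_assign = _evaluate_cohort(
            "external", ext_scores, thresholds, config.percentiles, config.bootstrap_reps, boot_ext
        )
        assignments["external"] = ext_assign
        ext_assign.to_csv(out / "external_assignments.csv", index=False, lineterminator="\n")
        sub_assign = ext_assign[ext_assign["threshold_percentile"] == config.subgroup_percentile]
        ext_subgroups = build_subgroup_table(ext_scores, sub_assign)
        subgroups["external"] = ext_subgroups
        ext_subgroups.to_csv(out / "external_subgroups.csv")
        _write_json(out / "external_subgroups.json", ext_subgroups.to_dict())

    _write_json(out / "performance.json", performance)

    manifest = {
        "package": "uqtriage",
        "version": __version__,
        "seed": int(config.seed),
        "percentiles": list(config.percentiles),
        "bootstrap_reps": int(config.bootstrap_reps),
        "config_sha256": _config_hash(config),
        "n_records": {tag: int(len(df)) for tag, df in scores.items()},
    }
    _write_json(out / "manifest.json", manifest)
    logger.info("stage=report bundle=%s", out)

    return RunResult(
        output_dir=out,
        thresholds=thresholds,
        performance=performance,
        scores=scores,
        assignments=assignments,
        subgroups=subgroups,
        manifest=manifest,
    )


def validate_inputs(path) -> dict:
    """Validate a cohort CSV; returns diagnostics and summary counts."""
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        return {
            "path": str(path),
            "n_rows": 0,
            "diagnostics": [{"row": None, "column": None, "message": f"unparseable file: {exc}"}],
            "n_diagnostics": 1,
            "valid": False,
        }
    diagnostics = validate_cohort_frame(frame)
    return {
        "path": str(path),
        "n_rows": int(len(frame)),
        "diagnostics": diagnostics,
        "n_diagnostics": len(diagnostics),
        "valid": not diagnostics,
    }
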