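"""Full two-arm analysis orchestration.

``run_full_analysis`` executes, for each test arm: continuity correction,
per-study measures, pooled results for the five accuracy measures with
heterogeneity, the linear SROC fit with AUC and Q*, the threshold diagnostic,
the funnel-plot asymmetry regression, and a leave-one-out table.  With
exactly two arms the Q* (and, secondarily, AUC) indices are compared with a
Z test.  The result is a plain nested dict that serializes to JSON and
validates against the schema shipped in ``data/report.schema.json``.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .bias import deeks_test, spearman_threshold
from .errors import DtaMetaError, InsufficientStudiesError, ValidationError
from .pooling import MEASURES, leave_one_out, pool_measure
from .sroc import compare_tests, compute_ds, fit_moses, with_summaries
from .studies import (
    StudyRecord,
    apply_continuity_correction,
    per_study_measures,
    read_studies,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "write_report", "forest_frame", "validate_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable choices of the pipeline, with reproduction-oriented defaults."""

    model: str = "random"
    correction_mode: str = "affected_studies"
    correction_value: float = 0.5
    ci_level: float = 0.95
    moses_weighted: bool = False
    auc_range: str = "full"  # "full" or "observed"
    auc_grid_step: float = 1e-4
    spearman_scale: str = "logit"

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValidationError(f"model must be 'fixed' or 'random', got {self.model!r}")
        if self.auc_range not in ("full", "observed"):
            raise ValidationError(f"auc_range must be 'full' or 'observed', got {self.auc_range!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any] | None) -> "AnalysisConfig":
        if not mapping:
            return cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses/tuples and map NaN to None."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _per_study_rows(studies: Sequence[StudyRecord], config: AnalysisConfig) -> list[dict]:
    rows = []
    for s in studies:
        c = apply_continuity_correction(s, mode=config.correction_mode, value=config.correction_value)
        m = per_study_measures(c, ci_level=config.ci_level)
        rows.append(
            {
                "study_id": s.study_id,
                "year": s.year,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "tn": s.tn,
                "corrected": c.corrected,
                "sens": m.sens,
                "sens_ci": list(m.sens_ci),
                "spec": m.spec,
                "spec_ci": list(m.spec_ci),
                "plr": m.plr,
                "nlr": m.nlr,
                "dor": m.dor,
                "dor_ci": list(m.dor_ci),
            }
        )
    return rows


def _pool_kwargs(config: AnalysisConfig) -> dict:
    return dict(
        correction_mode=config.correction_mode,
        correction_value=config.correction_value,
        ci_level=config.ci_level,
    )


def _loo_table(studies: Sequence[StudyRecord], config: AnalysisConfig, warnings: list[str]) -> list[dict]:
    if len(studies) < 2:
        warnings.append("leave-one-out skipped: fewer than 2 studies")
        return []

    def pooled_all(subset: Sequence[StudyRecord]) -> dict[str, float]:
        return {
            m: pool_measure(subset, m, model=config.model, **_pool_kwargs(config)).estimate
            for m in MEASURES
        }

    return [
        {"excluded_study_id": sid, **vals}
        for sid, vals in leave_one_out(list(studies), pooled_all)
    ]


def _analyze_arm(studies: Sequence[StudyRecord], config: AnalysisConfig, warnings: list[str]) -> dict:
    label = studies[0].test_label
    arm: dict[str, Any] = {"test_label": label, "k": len(studies)}
    arm["studies"] = _per_study_rows(studies, config)

    pooled = {}
    for m in MEASURES:
        res = pool_measure(studies, m, model=config.model, **_pool_kwargs(config))
        if res.clamped:
            warnings.append(f"arm {label}: {m} confidence interval clamped to [0, 1]")
        pooled[m] = res
    arm["pooled"] = pooled

    corrected = [
        apply_continuity_correction(s, mode=config.correction_mode, value=config.correction_value)
        for s in studies
    ]
    n_corrected = sum(c.corrected for c in corrected)
    if n_corrected:
        warnings.append(f"arm {label}: continuity correction applied to {n_corrected} studies")

    try:
        points = [compute_ds(c, study_id=s.study_id) for s, c in zip(studies, corrected)]
        fit = fit_moses(points, weighted=config.moses_weighted)
        if config.auc_range == "observed":
            fprs = [c.fp / (c.fp + c.tn) for c in corrected]
            fpr_range: str | tuple[float, float] = (min(fprs), max(fprs))
        else:
            fpr_range = "full"
        fit = with_summaries(fit, grid_step=config.auc_grid_step, fpr_range=fpr_range)
        arm["sroc"] = fit
    except DtaMetaError as exc:
        warnings.append(f"arm {label}: SROC analysis unavailable ({exc})")
        arm["sroc"] = None

    try:
        arm["threshold"] = spearman_threshold(
            studies,
            scale=config.spearman_scale,
            correction_mode=config.correction_mode,
            correction_value=config.correction_value,
        )
    except DtaMetaError as exc:
        warnings.append(f"arm {label}: threshold diagnostic unavailable ({exc})")
        arm["threshold"] = None

    try:
        deeks = deeks_test(
            studies,
            correction_mode=config.correction_mode,
            correction_value=config.correction_value,
        )
        for sid in deeks.excluded:
            warnings.append(f"arm {label}: study {sid!r} excluded from funnel regression (empty group)")
        arm["deeks"] = deeks
    except DtaMetaError as exc:
        warnings.append(f"arm {label}: funnel-plot regression unavailable ({exc})")
        arm["deeks"] = None

    arm["leave_one_out"] = _loo_table(studies, config, warnings)
    return arm


def run_full_analysis(
    input_path: str | Path,
    config: AnalysisConfig | str | Path | None = None,
) -> dict:
    """Run the complete analysis on a one- or two-arm CSV dataset."""
    if config is None:
        cfg = AnalysisConfig()
    elif isinstance(config, AnalysisConfig):
        cfg = config
    else:
        cfg = AnalysisConfig.from_yaml(config)

    records = read_studies(input_path)
    if not records:
        raise ValidationError(f"no study rows in {input_path}")
    arms: dict[str, list[StudyRecord]] = {}
    for r in records:
        arms.setdefault(r.test_label, []).append(r)

    warnings: list[str] = []
    report: dict[str, Any] = {
        "metadata": {
            "package_version": __version__,
            "input_path": str(input_path),
            "input_sha256": hashlib.sha256(Path(input_path).read_bytes()).hexdigest(),
            "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "config": dataclasses.asdict(cfg),
        },
        "arms": {label: _analyze_arm(studies, cfg, warnings) for label, studies in arms.items()},
    }

    if len(arms) == 2:
        (l1, a1), (l2, a2) = report["arms"].items()
        comparison: dict[str, Any] = {"arm1": l1, "arm2": l2}
        for stat in ("q_star", "auc"):
            cmp_entry = None
            f1, f2 = a1.get("sroc"), a2.get("sroc")
            if f1 is not None and f2 is not None:
                v1, se1 = getattr(f1, stat), getattr(f1, f"se_{stat}")
                v2, se2 = getattr(f2, stat), getattr(f2, f"se_{stat}")
                if all(map(math.isfinite, (v1, se1, v2, se2))) and se1 > 0 and se2 > 0:
                    cmp_entry = compare_tests(v1, se1, v2, se2, statistic=stat)
            if cmp_entry is None:
                warnings.append(f"comparison on {stat} unavailable (missing fit or standard error)")
            comparison[stat] = cmp_entry
        report["comparison"] = comparison
    else:
        report["comparison"] = None
        if len(arms) == 1:
            warnings.append("single test arm: between-test comparison omitted")

    report["warnings"] = warnings
    return _jsonable(report)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False, allow_nan=False)
        fh.write("\n")


def forest_frame(
    studies: Sequence[StudyRecord],
    measure: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Forest-plot-ready table: one row per study plus the pooled row."""
    cfg = config or AnalysisConfig()
    rows = []
    for s in studies:
        c = apply_continuity_correction(s, mode=cfg.correction_mode, value=cfg.correction_value)
        m = per_study_measures(c, ci_level=cfg.ci_level)
        ci = {
            "sens": m.sens_ci,
            "spec": m.spec_ci,
            "plr": m.plr_ci,
            "nlr": m.nlr_ci,
            "dor": m.dor_ci,
        }[measure]
        rows.append(
            {
                "study_id": s.study_id,
                "kind": "study",
                "estimate": getattr(m, measure),
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    pooled = pool_measure(list(studies), measure, model=cfg.model, **_pool_kwargs(cfg))
    rows.append(
        {
            "study_id": f"pooled ({pooled.model})",
            "kind": "pooled",
            "estimate": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
        }
    )
    return pd.DataFrame(rows)


# --- lightweight schema validation (no external validator dependency) ------

def _schema() -> dict:
    with resources.as_file(resources.files("dta_meta") / "data" / "report.schema.json") as p:
        return json.loads(Path(p).read_text())


def _check(instance: Any, schema: dict, where: str, errors: list[str]) -> None:
    stype = schema.get("type")
    if stype:
        types = stype if isinstance(stype, list) else [stype]
        ok = False
        for t in types:
            if (
                (t == "object" and isinstance(instance, dict))
                or (t == "array" and isinstance(instance, list))
                or (t == "string" and isinstance(instance, str))
                or (t == "number" and isinstance(instance, (int, float)) and not isinstance(instance, bool))
                or (t == "integer" and isinstance(instance, int) and not isinstance(instance, bool))
                or (t == "boolean" and isinstance(instance, bool))
                or (t == "null" and instance is None)
            ):
                ok = True
        if not ok:
            errors.append(f"{where}: expected {stype}, got {type(instance).__name__}")
            return
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{where}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in instance:
                _check(instance[key], sub, f"{where}.{key}", errors)
        addl = schema.get("additionalProperties")
        if isinstance(addl, dict):
            for key, val in instance.items():
                if key not in props:
                    _check(val, addl, f"{where}.{key}", errors)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{where}[{i}]", errors)


def validate_report(report: dict) -> list[str]:
    """Validate a report dict against the shipped JSON schema.

    Returns a list of problems (empty when valid).
    """
    errors: list[str] = []
    _check(report, _schema(), "$", errors)
    return errors
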