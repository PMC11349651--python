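"""End-to-end orchestration: read a cohort, score every subject, evaluate
against the reference amyloid status, and emit a machine-readable report.

The report is a plain JSON-serializable dict validated against the shipped
schema (``report_schema.json``).  Runs are idempotent for a fixed input and
configuration; excluded subjects are logged to stderr with their reason.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .analysis import compare_groups, evaluate_score, fit_logistic
from .caps import DEFAULT_THRESHOLD, compute_caps, compute_caps_mt
from .errors import CapsError, ValidationError
from .io import read_cohort
from .scales import Subject

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: Variables compared between groups in the full report.
_REPORT_VARIABLES = (
    "age", "duration_of_illness", "baseline_mmse", "npiq_total",
    "npiq_symptom_count", "hachinski", "sex", "rapid_decline",
    "white_matter_disease",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; echoed verbatim into the report."""

    input_path: str | Path
    output_path: Optional[str | Path] = None
    threshold: int = DEFAULT_THRESHOLD
    npiq_mode: str = "total"
    decline_method: str = "first_last"
    use_mt: bool = False
    full_analysis: bool = True
    seed: Optional[int] = None
    log_level: str = "WARNING"

    def as_dict(self) -> dict:
        return {
            "input_path": str(self.input_path),
            "output_path": None if self.output_path is None else str(self.output_path),
            "threshold": self.threshold,
            "npiq_mode": self.npiq_mode,
            "decline_method": self.decline_method,
            "use_mt": self.use_mt,
            "full_analysis": self.full_analysis,
            "seed": self.seed,
        }


def load_report_schema() -> dict:
    text = importlib.resources.files("capscore").joinpath("report_schema.json").read_text()
    return json.loads(text)


def _check_type(value, type_spec) -> bool:
    mapping = {
        "object": dict, "array": list, "string": str, "integer": int,
        "number": (int, float), "boolean": bool, "null": type(None),
    }
    types = type_spec if isinstance(type_spec, list) else [type_spec]
    ok = False
    for t in types:
        py = mapping[t]
        if t == "integer":
            ok = ok or (isinstance(value, int) and not isinstance(value, bool))
        else:
            ok = ok or isinstance(value, py)
    return ok


def validate_report(report: dict, schema: Optional[dict] = None, _path: str = "$") -> None:
    """Validate a report against the shipped schema (type/required subset).

    Raises :class:`ValidationError` naming the offending path.
    """
    schema = schema if schema is not None else load_report_schema()
    if "type" in schema and not _check_type(report, schema["type"]):
        raise ValidationError(f"{_path}: expected type {schema['type']}, got {type(report).__name__}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise ValidationError(f"{_path}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in report and report[key] is not None:
                validate_report(report[key], subschema, f"{_path}.{key}")
            elif key in report and report[key] is None and "null" not in (
                subschema.get("type") if isinstance(subschema.get("type"), list) else [subschema.get("type")]
            ):
                if "type" in subschema:
                    raise ValidationError(f"{_path}.{key}: null not allowed")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{_path}[{i}]")


def _subject_report(subject: Subject, config: RunConfig) -> dict:
    entry: dict = {"subject_id": subject.id}
    scorer = compute_caps_mt if config.use_mt else compute_caps
    try:
        r = scorer(
            subject,
            threshold=config.threshold,
            npiq_mode=config.npiq_mode,
            decline_method=config.decline_method,
        )
    except CapsError as exc:
        entry.update({"error": str(exc)})
        return entry
    entry.update(
        {
            "npiq_points": r.npiq_points,
            "decline_points": r.decline_points,
            "fazekas_points": r.fazekas_points,
            "caps_total": r.caps_total,
            "mtla_points": r.mtla_points,
            "caps_mt_total": r.caps_mt_total,
            "decline_rate": None if r.decline is None else round(r.decline.rate, 4),
            "predicted_status": r.predicted_status,
        }
    )
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Execute validate -> convert -> decline -> score -> evaluate.

    Returns the report dict; also writes it to ``config.output_path`` when
    set.  Hard failure only on unreadable/empty input; per-subject problems
    are collected as exclusions.
    """
    logging.basicConfig(level=config.log_level)
    cohort = read_cohort(config.input_path)
    if not cohort:
        raise ValidationError(f"input {config.input_path} contains no subjects")
    logger.info("loaded %d subjects from %s", len(cohort), config.input_path)

    score_kind = "caps_mt" if config.use_mt else "caps"
    evaluation = evaluate_score(
        cohort,
        score=score_kind,
        threshold=config.threshold,
        npiq_mode=config.npiq_mode,
        decline_method=config.decline_method,
    )
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.as_dict(),
        "n_input": len(cohort),
        "n_scored": evaluation.n_scored,
        "n_excluded": evaluation.n_excluded,
        "exclusions": [
            {"subject_id": sid, "reason": reason} for sid, reason in evaluation.exclusions
        ],
        "subjects": [_subject_report(s, config) for s in cohort],
        "confusion": {
            "tp": evaluation.confusion.tp,
            "fp": evaluation.confusion.fp,
            "tn": evaluation.confusion.tn,
            "fn": evaluation.confusion.fn,
        },
        "metrics": evaluation.metrics.as_floats() | {
            "percent": evaluation.metrics.as_percentages()
        },
        "roc": None
        if evaluation.roc is None
        else {
            "auc": evaluation.roc.auc,
            "auc_ci_95": list(evaluation.roc.auc_ci_95),
            "method": evaluation.roc.method,
            "fpr": [float(x) for x in evaluation.roc.fpr],
            "tpr": [float(x) for x in evaluation.roc.tpr],
            "thresholds": [float(x) for x in evaluation.roc.thresholds],
        },
    }

    if config.full_analysis:
        comparisons = []
        for var in _REPORT_VARIABLES:
            try:
                c = compare_groups(cohort, var)
            except CapsError as exc:
                logger.info("group comparison for %r skipped: %s", var, exc)
                continue
            comparisons.append(
                {
                    "variable": c.variable,
                    "test": c.test,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                }
            )
        report["group_comparisons"] = comparisons
        report["logistic"] = _logistic_block(cohort)

    validate_report(report)
    if config.output_path is not None:
        Path(config.output_path).write_text(json.dumps(report, indent=1) + "\n")
        logger.info("report written to %s", config.output_path)
    return report


def _logistic_block(cohort: Sequence[Subject]) -> Optional[dict]:
    """Amyloid positivity ~ NPI-Q total + baseline MMSE, on complete cases."""
    rows = [
        (s.npiq.total_score, s.baseline_mmse, 1 if s.amyloid_status_reference == "positive" else 0)
        for s in cohort
        if s.npiq is not None
        and s.baseline_mmse is not None
        and s.amyloid_status_reference in ("positive", "negative")
    ]
    if len(rows) < 10:
        return None
    import numpy as np

    arr = np.asarray(rows, dtype=float)
    try:
        fit = fit_logistic(arr[:, :2], arr[:, 2], feature_names=["npiq_total", "baseline_mmse"])
    except ValidationError:
        return None
    return {
        "names": list(fit.names),
        "coefficients": [None if np.isnan(v) else float(v) for v in fit.params],
        "p_values": [None if np.isnan(v) else float(v) for v in fit.p_values],
        "log_likelihood": None if np.isnan(fit.log_likelihood) else fit.log_likelihood,
        "converged": fit.converged,
        "separation": fit.separation,
    }
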