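"""Cohort serialization: long-format CSV (one row per subject-visit) and
nested per-subject JSON.  Dates are ISO-8601 throughout.

CSV dialect
-----------
Subject-level columns are repeated on every visit row:

``subject_id, age, sex, duration_of_illness, hachinski, lawton_brody,
fazekas, scheltens_mtla, csf_abeta42, csf_ptau, csf_ttau, amyloid_status,
reference_modality, npiq_<domain> (x12), visit_date, instrument, score``

Empty cells are missing values.  JSON files hold a list of nested records
with a ``visits`` array and an ``npiq`` object.
"""

from __future__ import annotations

import json
import math
from datetime import date as Date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .scales import (
    NPIQ_DOMAINS,
    CognitiveScore,
    CSFPanel,
    ImagingRatings,
    NPIQProfile,
    Subject,
)

_SUBJECT_COLUMNS = [
    "subject_id", "age", "sex", "duration_of_illness", "hachinski", "lawton_brody",
    "fazekas", "scheltens_mtla", "csf_abeta42", "csf_ptau", "csf_ttau",
    "amyloid_status", "reference_modality",
]
_NPIQ_COLUMNS = [f"npiq_{d}" for d in NPIQ_DOMAINS]
_VISIT_COLUMNS = ["visit_date", "instrument", "score"]
CSV_COLUMNS = _SUBJECT_COLUMNS + _NPIQ_COLUMNS + _VISIT_COLUMNS


def subject_to_dict(subject: Subject) -> dict:
    """Nested JSON-ready representation of one subject."""
    return {
        "subject_id": subject.id,
        "age": subject.age,
        "sex": subject.sex,
        "duration_of_illness": subject.duration_of_illness,
        "hachinski": subject.hachinski,
        "lawton_brody": subject.lawton_brody,
        "imaging": (
            {"fazekas": subject.imaging.fazekas, "scheltens_mtla": subject.imaging.scheltens_mtla}
            if subject.imaging
            else None
        ),
        "csf": (
            {
                "abeta42": subject.csf.abeta42,
                "ptau": subject.csf.ptau,
                "ttau": subject.csf.ttau,
                "ptau_abeta42_ratio": subject.csf.ptau_abeta42_ratio,
                "ttau_abeta42_ratio": subject.csf.ttau_abeta42_ratio,
            }
            if subject.csf
            else None
        ),
        "npiq": dict(subject.npiq.severities) if subject.npiq else None,
        "visits": [
            {
                "date": s.date.isoformat() if s.date else None,
                "instrument": s.instrument,
                "score": s.raw,
            }
            for s in subject.cognitive_scores
        ],
        "amyloid_status": subject.amyloid_status_reference,
        "reference_modality": subject.reference_modality,
    }


def subject_from_dict(record: dict) -> Subject:
    imaging = record.get("imaging")
    csf = record.get("csf")
    npiq = record.get("npiq")
    return Subject(
        id=str(record["subject_id"]),
        age=float(record["age"]),
        sex=record["sex"],
        duration_of_illness=record.get("duration_of_illness"),
        hachinski=record.get("hachinski"),
        lawton_brody=record.get("lawton_brody"),
        imaging=ImagingRatings(**imaging) if imaging else None,
        csf=CSFPanel(**{k: v for k, v in csf.items() if v is not None}) if csf else None,
        npiq=NPIQProfile.from_partial(npiq) if npiq is not None else None,
        cognitive_scores=tuple(
            CognitiveScore(
                v["instrument"],
                int(v["score"]),
                Date.fromisoformat(v["date"]) if v.get("date") else None,
            )
            for v in record.get("visits", [])
        ),
        amyloid_status_reference=record.get("amyloid_status", "unknown"),
        reference_modality=record.get("reference_modality", "none"),
    )


def write_cohort_json(cohort: Sequence[Subject], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([subject_to_dict(s) for s in cohort], indent=1) + "\n"
    )


def read_cohort_json(path: str | Path) -> list[Subject]:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValidationError("cohort JSON must be a list of subject records")
    return [subject_from_dict(r) for r in records]


def cohort_to_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    """Long-format DataFrame, one row per subject-visit (or one row if no visits)."""
    rows = []
    for s in cohort:
        base = {
            "subject_id": s.id,
            "age": s.age,
            "sex": s.sex,
            "duration_of_illness": s.duration_of_illness,
            "hachinski": s.hachinski,
            "lawton_brody": s.lawton_brody,
            "fazekas": s.imaging.fazekas if s.imaging else None,
            "scheltens_mtla": s.imaging.scheltens_mtla if s.imaging else None,
            "csf_abeta42": s.csf.abeta42 if s.csf else None,
            "csf_ptau": s.csf.ptau if s.csf else None,
            "csf_ttau": s.csf.ttau if s.csf else None,
            "amyloid_status": s.amyloid_status_reference,
            "reference_modality": s.reference_modality,
        }
        for d in NPIQ_DOMAINS:
            base[f"npiq_{d}"] = s.npiq.severities[d] if s.npiq else None
        if s.cognitive_scores:
            for v in s.cognitive_scores:
                rows.append(
                    base
                    | {
                        "visit_date": v.date.isoformat() if v.date else None,
                        "instrument": v.instrument,
                        "score": v.raw,
                    }
                )
        else:
            rows.append(base | {"visit_date": None, "instrument": None, "score": None})
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(cohort: Sequence[Subject], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return cast(value)


def frame_to_cohort(frame: pd.DataFrame) -> list[Subject]:
    missing = set(_SUBJECT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    subjects = []
    for sid, g in frame.groupby("subject_id", sort=False):
        r = g.iloc[0]
        npiq = None
        if all(c in frame.columns for c in _NPIQ_COLUMNS) and not g[_NPIQ_COLUMNS].iloc[0].isna().all():
            npiq = NPIQProfile.from_partial(
                {d: int(r[f"npiq_{d}"]) for d in NPIQ_DOMAINS if pd.notna(r[f"npiq_{d}"])}
            )
        fazekas = _opt(r.get("fazekas"), int)
        imaging = (
            ImagingRatings(fazekas=fazekas, scheltens_mtla=_opt(r.get("scheltens_mtla"), int))
            if fazekas is not None
            else None
        )
        csf_fields = {
            "abeta42": _opt(r.get("csf_abeta42")),
            "ptau": _opt(r.get("csf_ptau")),
            "ttau": _opt(r.get("csf_ttau")),
        }
        csf = CSFPanel(**csf_fields) if any(v is not None for v in csf_fields.values()) else None
        visits = []
        for _, v in g.iterrows():
            if pd.isna(v.get("score")) or pd.isna(v.get("instrument")):
                continue
            date = v.get("visit_date")
            visits.append(
                CognitiveScore(
                    str(v["instrument"]),
                    int(v["score"]),
                    Date.fromisoformat(str(date)) if pd.notna(date) else None,
                )
            )
        status = r["amyloid_status"] if pd.notna(r["amyloid_status"]) else "unknown"
        modality = r["reference_modality"] if pd.notna(r["reference_modality"]) else "none"
        subjects.append(
            Subject(
                id=str(sid),
                age=float(r["age"]),
                sex=str(r["sex"]),
                duration_of_illness=_opt(r.get("duration_of_illness")),
                hachinski=_opt(r.get("hachinski"), int),
                lawton_brody=_opt(r.get("lawton_brody"), int),
                imaging=imaging,
                csf=csf,
                npiq=npiq,
                cognitive_scores=tuple(visits),
                amyloid_status_reference=str(status),
                reference_modality=str(modality),
            )
        )
    return subjects


def read_cohort_csv(path: str | Path) -> list[Subject]:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValidationError(f"cohort file {path} contains no subjects")
    return frame_to_cohort(frame)


def read_cohort(path: str | Path) -> list[Subject]:
    """Read a cohort from CSV or JSON, dispatching on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_cohort_json(path)
    return read_cohort_csv(path)
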