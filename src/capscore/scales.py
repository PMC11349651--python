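"""Clinical instruments: data model, validation, and scale-level derived quantities.

The package consumes visual MRI ratings (Fazekas, Scheltens) and bedside
instruments (MMSE/MoCA, NPI-Q, Hachinski, Lawton-Brody) as *inputs*; nothing
here touches images or assay chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Mapping, Optional, Sequence

from .errors import IndeterminateStatusError, ValidationError

#: The 12 NPI-Q symptom domains, in conventional order.
NPIQ_DOMAINS: tuple[str, ...] = (
    "delusions",
    "hallucinations",
    "agitation",
    "apathy",
    "anxiety",
    "depression",
    "euphoria",
    "disinhibition",
    "irritability",
    "aberrant_motor_behavior",
    "sleeping_disorder",
    "appetite_disturbance",
)

# CSF cutoffs (ng/L for absolute analytes; ratios dimensionless).  Values on
# the other side of each bound are abnormal, i.e. amyloid-positive side.
ABETA42_NORMAL_ABOVE = 1030.0
PTAU_ABETA42_NORMAL_BELOW = 0.024
TTAU_ABETA42_NORMAL_BELOW = 0.29

HACHINSKI_VASCULAR_ABOVE = 4
LAWTON_BRODY_MAX = 23


@dataclass(frozen=True)
class NPIQProfile:
    """Neuropsychiatric Inventory Questionnaire: 12 domain severities, each 0-3.

    Domains a caregiver reports as absent are recorded with severity 0.
    """

    severities: Mapping[str, int]

    def __post_init__(self):
        keys = set(self.severities)
        missing = set(NPIQ_DOMAINS) - keys
        extra = keys - set(NPIQ_DOMAINS)
        if missing or extra:
            raise ValidationError(
                f"NPI-Q profile must cover exactly the 12 domains; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        for domain, sev in self.severities.items():
            if not isinstance(sev, (int,)) or isinstance(sev, bool) or not 0 <= sev <= 3:
                raise ValidationError(
                    f"NPI-Q severity for domain {domain!r} must be an integer in 0..3, got {sev!r}"
                )
        object.__setattr__(self, "severities", dict(self.severities))

    @classmethod
    def from_partial(cls, severities: Mapping[str, int] | None = None, **kwargs: int) -> "NPIQProfile":
        """Build a profile from the reported domains only; the rest default to 0."""
        reported = dict(severities or {})
        reported.update(kwargs)
        unknown = set(reported) - set(NPIQ_DOMAINS)
        if unknown:
            raise ValidationError(f"unknown NPI-Q domains: {sorted(unknown)}")
        full = {d: int(reported.get(d, 0)) for d in NPIQ_DOMAINS}
        return cls(full)

    @property
    def total_score(self) -> int:
        return sum(self.severities.values())

    @property
    def symptom_count(self) -> int:
        return sum(1 for s in self.severities.values() if s > 0)


def npiq_summary(profile: NPIQProfile) -> tuple[int, int]:
    """Return (total severity score 0-36, number of present symptoms 0-12)."""
    return profile.total_score, profile.symptom_count


@dataclass(frozen=True)
class CognitiveScore:
    """One administration of a 30-point cognitive screen (MMSE or MoCA)."""

    instrument: str
    raw: int
    date: Optional[Date] = None

    def __post_init__(self):
        if self.instrument not in ("MMSE", "MoCA"):
            raise ValidationError(f"instrument must be 'MMSE' or 'MoCA', got {self.instrument!r}")
        if not isinstance(self.raw, int) or isinstance(self.raw, bool) or not 0 <= self.raw <= 30:
            raise ValidationError(f"{self.instrument} raw score must be an integer in 0..30, got {self.raw!r}")

    def as_mmse(self) -> "CognitiveScore":
        """Return this score on the MMSE scale, converting MoCA via the crosswalk."""
        if self.instrument == "MMSE":
            return self
        return CognitiveScore("MMSE", moca_to_mmse(self.raw), self.date)


# MoCA -> MMSE crosswalk anchors (weighted-mean equivalents), de-duplicated
# and sorted.  Between anchors the conversion is linear; below the lowest
# anchor it extends with the first segment's slope, floored at 0.
_MOCA_MMSE_ANCHORS: tuple[tuple[int, int], ...] = (
    (11, 18),
    (12, 19),
    (13, 20),
    (14, 20),
    (15, 21),
    (18, 24),
    (21, 26),
    (24, 28),
    (25, 28),
    (26, 29),
    (28, 29),
    (30, 30),
)


def moca_to_mmse(moca: int) -> int:
    """Convert a MoCA score (0-30) to its MMSE equivalent (0-30).

    Reproduces every anchor of the published weighted-mean crosswalk exactly,
    interpolates linearly between anchors, extrapolates below the lowest
    anchor with the adjacent segment's slope (floored at 0), and rounds
    half-up.  Monotone non-decreasing over the whole 0-30 range.
    """
    if not isinstance(moca, int) or isinstance(moca, bool) or not 0 <= moca <= 30:
        raise ValidationError(f"MoCA score must be an integer in 0..30, got {moca!r}")
    xs = [a for a, _ in _MOCA_MMSE_ANCHORS]
    ys = [b for _, b in _MOCA_MMSE_ANCHORS]
    if moca <= xs[0]:
        # first-segment slope is (19-18)/(12-11) = 1
        value = ys[0] - (xs[0] - moca) * (ys[1] - ys[0]) / (xs[1] - xs[0])
        value = max(0.0, value)
    else:
        i = max(k for k, x in enumerate(xs) if x <= moca)
        if xs[i] == moca:
            return ys[i]
        x0, y0, x1, y1 = xs[i], ys[i], xs[i + 1], ys[i + 1]
        value = y0 + (moca - x0) * (y1 - y0) / (x1 - x0)
    return min(30, int(math.floor(value + 0.5)))


def hachinski_class(score: int) -> str:
    """Classify a Hachinski Ischemic Score: 'vascular' iff score > 4."""
    if not isinstance(score, int) or isinstance(score, bool) or score < 0:
        raise ValidationError(f"Hachinski score must be a non-negative integer, got {score!r}")
    return "vascular" if score > HACHINSKI_VASCULAR_ABOVE else "non_vascular"


def adl_stage(lawton_total: int) -> str:
    """Stage by ADL independence: 23/23 = fully independent = 'prodromal'."""
    if (
        not isinstance(lawton_total, int)
        or isinstance(lawton_total, bool)
        or not 0 <= lawton_total <= LAWTON_BRODY_MAX
    ):
        raise ValidationError(f"Lawton-Brody total must be an integer in 0..23, got {lawton_total!r}")
    return "prodromal" if lawton_total == LAWTON_BRODY_MAX else "dementia"


@dataclass(frozen=True)
class ImagingRatings:
    """Visual MRI ratings: Fazekas 0-3 (white matter), Scheltens/MTLA 0-4."""

    fazekas: int
    scheltens_mtla: Optional[int] = None

    def __post_init__(self):
        if not isinstance(self.fazekas, int) or isinstance(self.fazekas, bool) or not 0 <= self.fazekas <= 3:
            raise ValidationError(f"Fazekas rating must be an integer in 0..3, got {self.fazekas!r}")
        s = self.scheltens_mtla
        if s is not None and (not isinstance(s, int) or isinstance(s, bool) or not 0 <= s <= 4):
            raise ValidationError(f"Scheltens/MTLA rating must be an integer in 0..4, got {s!r}")


@dataclass(frozen=True)
class CSFPanel:
    """CSF analytes in ng/L plus optional pre-computed tau/Abeta42 ratios."""

    abeta42: Optional[float] = None
    ptau: Optional[float] = None
    ttau: Optional[float] = None
    ptau_abeta42_ratio: Optional[float] = None
    ttau_abeta42_ratio: Optional[float] = None

    def __post_init__(self):
        for name in ("abeta42", "ptau", "ttau", "ptau_abeta42_ratio", "ttau_abeta42_ratio"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"CSF field {name} must be > 0 when present, got {v!r}")
        # Stored ratios must agree with element-wise division within 5%.
        for num, ratio_name in (("ptau", "ptau_abeta42_ratio"), ("ttau", "ttau_abeta42_ratio")):
            stored = getattr(self, ratio_name)
            n, d = getattr(self, num), self.abeta42
            if stored is not None and n is not None and d is not None:
                if not math.isclose(stored, n / d, rel_tol=0.05):
                    raise ValidationError(
                        f"{ratio_name}={stored} inconsistent with {num}/abeta42={n / d:.4g}"
                    )

    def effective_ratio(self, which: str) -> Optional[float]:
        """Stored ratio if present, else derived from the analytes."""
        stored = getattr(self, f"{which}_abeta42_ratio")
        if stored is not None:
            return stored
        num = getattr(self, which)
        if num is not None and self.abeta42 is not None:
            return num / self.abeta42
        return None


@dataclass(frozen=True)
class AmyloidStatus:
    """A dichotomized amyloid call plus the rule that produced it."""

    status: str
    basis: str

    def __post_init__(self):
        if self.status not in ("positive", "negative"):
            raise ValidationError(f"status must be 'positive' or 'negative', got {self.status!r}")
        if self.basis not in ("csf_ratio", "csf_absolute", "pet", "reference"):
            raise ValidationError(f"unknown basis {self.basis!r}")


def csf_amyloid_status(panel: CSFPanel) -> AmyloidStatus:
    """Dichotomize a CSF panel into amyloid positive/negative.

    Ratio rule first: positive iff p-tau/Abeta42 >= 0.024 or t-tau/Abeta42
    >= 0.29 (borderline equality counts as positive).  If no ratio is
    available, fall back to the absolute rule: positive iff Abeta42 <= 1030
    ng/L.  Deterministic; the basis records which rule decided.
    """
    ptau_r = panel.effective_ratio("ptau")
    ttau_r = panel.effective_ratio("ttau")
    if ptau_r is not None or ttau_r is not None:
        positive = (ptau_r is not None and ptau_r >= PTAU_ABETA42_NORMAL_BELOW) or (
            ttau_r is not None and ttau_r >= TTAU_ABETA42_NORMAL_BELOW
        )
        return AmyloidStatus("positive" if positive else "negative", "csf_ratio")
    if panel.abeta42 is not None:
        positive = panel.abeta42 <= ABETA42_NORMAL_ABOVE
        return AmyloidStatus("positive" if positive else "negative", "csf_absolute")
    raise IndeterminateStatusError("CSF panel has no usable analyte or ratio")


def reference_from_measurements(
    csf: Optional[CSFPanel] = None, pet_status: Optional[str] = None
) -> AmyloidStatus:
    """Combine available modalities into one reference call.

    PET takes precedence when both modalities are present, being the more
    direct measure of cerebral amyloid deposition.
    """
    if pet_status is not None:
        if pet_status not in ("positive", "negative"):
            raise ValidationError(f"PET status must be 'positive' or 'negative', got {pet_status!r}")
        return AmyloidStatus(pet_status, "pet")
    if csf is not None:
        return csf_amyloid_status(csf)
    raise IndeterminateStatusError("no amyloid measurement available")


@dataclass
class Subject:
    """One memory-clinic chart: demographics, scales, imaging, reference label.

    ``amyloid_status_reference`` is the ground truth used by every evaluation
    operation.  Optional instruments may be absent; analyses requiring them
    drop the subject for that operation only.
    """

    id: str
    age: float
    sex: str
    npiq: Optional[NPIQProfile] = None
    cognitive_scores: Sequence[CognitiveScore] = field(default_factory=tuple)
    duration_of_illness: Optional[float] = None
    hachinski: Optional[int] = None
    lawton_brody: Optional[int] = None
    imaging: Optional[ImagingRatings] = None
    csf: Optional[CSFPanel] = None
    amyloid_status_reference: str = "unknown"
    reference_modality: str = "none"

    def __post_init__(self):
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age!r}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.amyloid_status_reference not in ("positive", "negative", "unknown"):
            raise ValidationError(
                f"amyloid_status_reference must be positive/negative/unknown, "
                f"got {self.amyloid_status_reference!r}"
            )
        if self.reference_modality not in ("CSF", "PET", "both", "none"):
            raise ValidationError(f"unknown reference modality {self.reference_modality!r}")
        if self.hachinski is not None and not 0 <= self.hachinski <= 18:
            raise ValidationError(f"Hachinski score must be in 0..18, got {self.hachinski!r}")
        if self.lawton_brody is not None and not 0 <= self.lawton_brody <= LAWTON_BRODY_MAX:
            raise ValidationError(f"Lawton-Brody total must be in 0..23, got {self.lawton_brody!r}")
        scores = list(self.cognitive_scores)
        dated = [s for s in scores if s.date is not None]
        dated.sort(key=lambda s: s.date)
        undated = [s for s in scores if s.date is None]
        self.cognitive_scores = tuple(dated + undated)

    @property
    def mmse_scores(self) -> tuple[CognitiveScore, ...]:
        """All dated cognitive scores on the MMSE scale (MoCA converted)."""
        return tuple(s.as_mmse() for s in self.cognitive_scores if s.date is not None)

    @property
    def baseline_mmse(self) -> Optional[int]:
        """Earliest available score on the MMSE scale, if any."""
        scores = [s.as_mmse() for s in self.cognitive_scores]
        return scores[0].raw if scores else None

    @property
    def stage(self) -> Optional[str]:
        return adl_stage(self.lawton_brody) if self.lawton_brody is not None else None
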