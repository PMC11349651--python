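"""The CAPS and CAPS-MT additive point scores for amyloid positivity.

CAPS sums three components from routinely collected clinical data:

====================================  ======  ======
component                             status  points
====================================  ======  ======
NPI-Q total severity                  0       0
                                      1       1
                                      >= 2    2
rapid cognitive decline               no      0
(MMSE loss > 2 points/year)           yes     1
Fazekas white-matter rating           >= 2    0
                                      0 or 1  1
====================================  ======  ======

Total range 0-4; a score of 3 or 4 predicts amyloid positivity.  CAPS-MT
appends one point for marked medial temporal atrophy (Scheltens > 2),
extending the range to 0-5; the positivity threshold stays at 3 by default
(a documented assumption — no point table for the extended score has been
published).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .decline import DeclineResult, annualized_decline
from .errors import CapsError, IncompleteScoreError, InsufficientVisitsError, ValidationError, ZeroSpanError
from .scales import Subject

DEFAULT_THRESHOLD = 3
SCHELTENS_MTLA_ABOVE = 2  # Scheltens > 2 earns the CAPS-MT point


@dataclass(frozen=True)
class CAPSResult:
    """Per-subject component points, totals, and predicted amyloid class."""

    npiq_points: int
    decline_points: int
    fazekas_points: int
    caps_total: int
    predicted_status: str
    threshold_used: int
    mtla_points: Optional[int] = None
    caps_mt_total: Optional[int] = None
    decline: Optional[DeclineResult] = None

    @property
    def score(self) -> int:
        """The total actually used for prediction (CAPS-MT when computed)."""
        return self.caps_mt_total if self.caps_mt_total is not None else self.caps_total


def npiq_points(total_npiq_score: int) -> int:
    """Points for the NPI-Q total severity: 0 -> 0, 1 -> 1, >= 2 -> 2."""
    if not isinstance(total_npiq_score, int) or isinstance(total_npiq_score, bool) or total_npiq_score < 0:
        raise ValidationError(f"NPI-Q total must be a non-negative integer, got {total_npiq_score!r}")
    return min(total_npiq_score, 2)


def fazekas_points(fazekas: int) -> int:
    """One point for little white-matter disease (Fazekas 0 or 1), else 0."""
    if not isinstance(fazekas, int) or isinstance(fazekas, bool) or not 0 <= fazekas <= 3:
        raise ValidationError(f"Fazekas rating must be an integer in 0..3, got {fazekas!r}")
    return 1 if fazekas <= 1 else 0


def classify(score: int, threshold: int = DEFAULT_THRESHOLD) -> str:
    """Predicted amyloid class: 'positive' iff score >= threshold."""
    return "positive" if score >= threshold else "negative"


def compute_caps(
    subject: Subject,
    threshold: int = DEFAULT_THRESHOLD,
    npiq_mode: str = "total",
    decline_method: str = "first_last",
) -> CAPSResult:
    """Score one subject on CAPS.

    ``npiq_mode`` selects the NPI-Q input to the point table: ``"total"``
    (default, the total severity score) or ``"count"`` (number of present
    symptoms, for sensitivity analysis).

    Raises :class:`IncompleteScoreError` naming the missing component when
    the subject lacks an NPI-Q profile, two dated cognitive scores, or a
    Fazekas rating.
    """
    if npiq_mode not in ("total", "count"):
        raise ValidationError(f"npiq_mode must be 'total' or 'count', got {npiq_mode!r}")
    if subject.npiq is None:
        raise IncompleteScoreError("npiq")
    if subject.imaging is None:
        raise IncompleteScoreError("fazekas")
    try:
        decl = annualized_decline(subject.mmse_scores, method=decline_method)
    except (InsufficientVisitsError, ZeroSpanError) as exc:
        raise IncompleteScoreError("decline", f"cannot score subject {subject.id!r}: {exc}") from exc

    npiq_input = subject.npiq.total_score if npiq_mode == "total" else subject.npiq.symptom_count
    p_npiq = npiq_points(npiq_input)
    p_decl = 1 if decl.rapid else 0
    p_faz = fazekas_points(subject.imaging.fazekas)
    total = p_npiq + p_decl + p_faz
    return CAPSResult(
        npiq_points=p_npiq,
        decline_points=p_decl,
        fazekas_points=p_faz,
        caps_total=total,
        predicted_status=classify(total, threshold),
        threshold_used=threshold,
        decline=decl,
    )


def compute_caps_mt(
    subject: Subject,
    threshold: int = DEFAULT_THRESHOLD,
    npiq_mode: str = "total",
    decline_method: str = "first_last",
) -> CAPSResult:
    """Score one subject on CAPS-MT (CAPS plus a Scheltens > 2 point).

    Requires a Scheltens/MTLA rating; callers may fall back to plain CAPS
    when it is absent.
    """
    if subject.imaging is None or subject.imaging.scheltens_mtla is None:
        raise IncompleteScoreError("scheltens_mtla")
    base = compute_caps(subject, threshold=threshold, npiq_mode=npiq_mode, decline_method=decline_method)
    p_mtla = 1 if subject.imaging.scheltens_mtla > SCHELTENS_MTLA_ABOVE else 0
    mt_total = base.caps_total + p_mtla
    return CAPSResult(
        npiq_points=base.npiq_points,
        decline_points=base.decline_points,
        fazekas_points=base.fazekas_points,
        caps_total=base.caps_total,
        predicted_status=classify(mt_total, threshold),
        threshold_used=threshold,
        mtla_points=p_mtla,
        caps_mt_total=mt_total,
        decline=base.decline,
    )
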