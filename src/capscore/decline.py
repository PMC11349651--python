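"""Annualized cognitive decline from longitudinal MMSE scores.

Rate is expressed in MMSE points lost per year (positive = decline).  A loss
of strictly more than 2 points/year counts as rapid decline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientVisitsError, ValidationError, ZeroSpanError
from .scales import CognitiveScore

DAYS_PER_YEAR = 365.25
RAPID_DECLINE_POINTS_PER_YEAR = 2.0


@dataclass(frozen=True)
class DeclineResult:
    """Annualized MMSE slope summary. ``rate`` > 0 means decline."""

    rate: float
    rapid: bool
    n_timepoints: int
    span_years: float


def is_rapid(rate: float) -> bool:
    """True iff the annualized loss strictly exceeds 2 MMSE points/year."""
    if not np.isfinite(rate):
        raise ValidationError(f"decline rate must be finite, got {rate!r}")
    return rate > RAPID_DECLINE_POINTS_PER_YEAR


def annualized_decline(
    scores: Sequence[CognitiveScore], method: str = "first_last"
) -> DeclineResult:
    """Annualized MMSE decline from dated scores on the MMSE scale.

    Parameters
    ----------
    scores
        Dated cognitive scores; MoCA entries must be converted to MMSE
        equivalents beforehand (``CognitiveScore.as_mmse``).
    method
        ``"first_last"`` (default): (first - last) / span, matching the
        two-timepoint clinical definition.  ``"regression"``: negated
        least-squares slope over all visits.

    Raises
    ------
    InsufficientVisitsError
        Fewer than two dated scores — such subjects are excluded from any
        analysis that uses rapid decline.
    ZeroSpanError
        All scores on one date.
    """
    if method not in ("first_last", "regression"):
        raise ValidationError(f"unknown decline method {method!r}")
    dated = [s for s in scores if s.date is not None]
    for s in dated:
        if s.instrument != "MMSE":
            raise ValidationError(
                f"decline requires MMSE-scale scores; convert {s.instrument} first"
            )
    if len(dated) < 2:
        raise InsufficientVisitsError(
            f"decline needs >= 2 dated scores, got {len(dated)}"
        )
    dated.sort(key=lambda s: s.date)
    t0 = dated[0].date
    years = np.array([(s.date - t0).days / DAYS_PER_YEAR for s in dated])
    span = float(years[-1])
    if span <= 0:
        raise ZeroSpanError("cognitive scores span zero time")
    values = np.array([float(s.raw) for s in dated])
    if method == "first_last":
        rate = (values[0] - values[-1]) / span
    else:
        slope = np.polyfit(years, values, 1)[0]
        rate = -float(slope)
    rate = float(rate)
    return DeclineResult(rate=rate, rapid=is_rapid(rate), n_timepoints=len(dated), span_years=span)
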