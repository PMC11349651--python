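"""Synthetic memory-clinic cohorts with the statistical structure of the
published Abeta+/Abeta- comparison, plus a deterministic 48-subject fixture
reproducing the printed 2x2 classification counts.

Continuous scales are drawn from *moment-matched* truncated normals: the
location parameter is solved numerically so that the mean of the truncated
(and, for integer scales, discretized) distribution equals the configured
group mean.  A plain truncated normal centred on the target would be biased
upward near a scale floor (e.g. NPI-Q totals near 0), breaking parameter
recovery.  Variables are drawn independently within group except for the
deterministic link between the drawn rapid/slow status and the synthesized
second MMSE visit; the published table reports no correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .scales import (
    NPIQ_DOMAINS,
    CognitiveScore,
    ImagingRatings,
    NPIQProfile,
    Subject,
)

BASELINE_DATE = Date(2023, 1, 1)
FOLLOWUP_DAYS = 365

# Per-domain NPI-Q severity means.  Depression and irritability are the
# published per-domain means; the remaining 10 domains share the residual
# of the group's total NPI-Q mean equally (no further breakdown printed).
_POS_DOMAIN_MEANS = {"depression": 0.80, "irritability": 0.63}
_NEG_DOMAIN_MEANS = {"depression": 0.14, "irritability": 0.18}


def _domain_weights(total_mean: float, named: dict[str, float]) -> tuple[float, ...]:
    residual = max(total_mean - sum(named.values()), 0.0)
    per_other = residual / (len(NPIQ_DOMAINS) - len(named))
    w = np.array([named.get(d, per_other) for d in NPIQ_DOMAINS], dtype=float)
    return tuple(w / w.sum())


@dataclass(frozen=True)
class GroupParams:
    """Generating distributions for one amyloid group.

    Defaults are set per group by :func:`default_params`; SDs are the
    nominal (pre-truncation) normal scales.
    """

    n: int
    age_mean: float
    age_sd: float
    prop_female: float
    duration_mean: float
    duration_sd: float
    mmse_mean: float
    mmse_sd: float
    npi_mean: float
    npi_sd: float
    hachinski_mean: float
    hachinski_sd: float
    p_rapid: float
    fazekas_probs: tuple[float, ...]
    scheltens_probs: tuple[float, ...]
    npiq_domain_weights: tuple[float, ...]

    def __post_init__(self):
        if not isinstance(self.n, int) or isinstance(self.n, bool) or self.n < 0:
            raise ValidationError(f"n must be a non-negative integer, got {self.n!r}")
        for name in ("age_sd", "duration_sd", "mmse_sd", "npi_sd", "hachinski_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("prop_female", "p_rapid"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0,1]")
        for name, size in (("fazekas_probs", 4), ("scheltens_probs", 5), ("npiq_domain_weights", 12)):
            p = np.asarray(getattr(self, name), dtype=float)
            if len(p) != size or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValidationError(f"{name} must be {size} non-negative values summing to 1")


@dataclass(frozen=True)
class CohortParams:
    """Two-group generator configuration; defaults mirror the published table."""

    positive: GroupParams
    negative: GroupParams


def default_params(n_positive: int = 30, n_negative: int = 22) -> CohortParams:
    """The published two-group parameterization (Abeta+ n=30, Abeta- n=22).

    White-matter ("Fazekas >= 2") prevalence is 0.05 / 0.18 and the
    Scheltens 0-4 category probabilities place the unprinted remainder on
    grade 4; both are documented assumptions where the source table is
    internally inconsistent.
    """
    positive = GroupParams(
        n=n_positive,
        age_mean=69.40, age_sd=10.64,
        prop_female=0.63,
        duration_mean=2.87, duration_sd=1.78,
        mmse_mean=24.50, mmse_sd=2.52,
        npi_mean=2.73, npi_sd=1.66,
        hachinski_mean=2.37, hachinski_sd=0.85,
        p_rapid=0.61,
        fazekas_probs=(0.55, 0.40, 0.04, 0.01),  # P(>=2) = 0.05
        scheltens_probs=(0.10, 0.60, 0.12, 0.04, 0.14),
        npiq_domain_weights=_domain_weights(2.73, _POS_DOMAIN_MEANS),
    )
    negative = GroupParams(
        n=n_negative,
        age_mean=69.73, age_sd=10.76,
        prop_female=0.45,
        duration_mean=3.29, duration_sd=2.54,
        mmse_mean=26.85, mmse_sd=3.71,
        npi_mean=1.18, npi_sd=1.14,
        hachinski_mean=2.45, hachinski_sd=1.68,
        p_rapid=0.50,
        fazekas_probs=(0.45, 0.37, 0.14, 0.04),  # P(>=2) = 0.18
        scheltens_probs=(0.35, 0.40, 0.15, 0.00, 0.10),
        npiq_domain_weights=_domain_weights(1.18, _NEG_DOMAIN_MEANS),
    )
    return CohortParams(positive=positive, negative=negative)


# --------------------------------------------------------------------------
# Moment-matched truncated / discretized normals


def _discretized_normal_pmf(lo: int, hi: int, mean: float, sd: float) -> np.ndarray:
    """PMF on integers lo..hi from a normal rounded-and-clipped to the range,
    with the location solved so the discrete mean equals ``mean`` exactly."""
    if not lo < hi:
        raise ValidationError("lo must be < hi")
    if not lo < mean < hi:
        raise ValidationError(f"target mean {mean} outside ({lo}, {hi})")
    ks = np.arange(lo, hi + 1)
    # cell edges: k gets (k-1/2, k+1/2]; boundary cells absorb the tails
    edges = np.concatenate(([-np.inf], ks[:-1] + 0.5, [np.inf]))

    def discrete_mean(mu: float) -> float:
        cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
        p = np.diff(cdf)
        return float((ks * p).sum())

    span = hi - lo
    mu = optimize.brentq(
        lambda m: discrete_mean(m) - mean, lo - 4 * sd - span, hi + 4 * sd + span, xtol=1e-12
    )
    p = np.diff(stats.norm.cdf(edges, loc=mu, scale=sd))
    return p / p.sum()


def _matched_truncnorm(lo: float, hi: float, mean: float, sd: float):
    """Frozen truncnorm on (lo, hi) whose *truncated* mean equals ``mean``."""
    if not lo < mean < hi:
        raise ValidationError(f"target mean {mean} outside ({lo}, {hi})")

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    span = min(hi - lo, 50 * sd)
    mu = optimize.brentq(lambda m: trunc_mean(m) - mean, lo - 6 * sd - span, hi + 6 * sd + span, xtol=1e-10)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def _allocate_npiq(total: int, weights: np.ndarray, rng: np.random.Generator) -> dict[str, int]:
    """Split a total severity across the 12 domains (each capped at 3)."""
    counts = rng.multinomial(total, weights)
    while np.any(counts > 3):
        excess_idx = np.flatnonzero(counts > 3)
        excess = int((counts[excess_idx] - 3).sum())
        counts[excess_idx] = 3
        room = counts < 3
        w = weights * room
        if w.sum() == 0:  # totals <= 36 guarantee room somewhere
            break
        counts += rng.multinomial(excess, w / w.sum())
    return {d: int(c) for d, c in zip(NPIQ_DOMAINS, counts)}


# Annual MMSE drops conditional on decline status.  Slow losses of exactly
# 2 points/yr are avoided because a 365-day visit interval puts them
# marginally over the >2/yr boundary once annualized with 365.25 days/yr.
_SLOW_DROPS, _SLOW_P = np.array([0, 1]), np.array([0.45, 0.55])
_RAPID_DROPS, _RAPID_P = np.array([3, 4, 5, 6]), np.array([0.45, 0.30, 0.15, 0.10])


def _generate_group(
    params: GroupParams, status: str, id_prefix: str, rng: np.random.Generator
) -> list[Subject]:
    n = params.n
    if n == 0:
        return []
    age = _matched_truncnorm(40.0, 110.0, params.age_mean, params.age_sd).rvs(n, random_state=rng)
    duration = _matched_truncnorm(0.1, 30.0, params.duration_mean, params.duration_sd).rvs(
        n, random_state=rng
    )
    female = rng.random(n) < params.prop_female
    mmse_pmf = _discretized_normal_pmf(0, 30, params.mmse_mean, params.mmse_sd)
    mmse0 = rng.choice(31, size=n, p=mmse_pmf)
    npi_pmf = _discretized_normal_pmf(0, 36, params.npi_mean, params.npi_sd)
    npi_total = rng.choice(37, size=n, p=npi_pmf)
    hach_pmf = _discretized_normal_pmf(0, 18, params.hachinski_mean, params.hachinski_sd)
    hachinski = rng.choice(19, size=n, p=hach_pmf)
    fazekas = rng.choice(4, size=n, p=np.asarray(params.fazekas_probs))
    scheltens = rng.choice(5, size=n, p=np.asarray(params.scheltens_probs))
    rapid = rng.random(n) < params.p_rapid
    drops = np.where(
        rapid,
        rng.choice(_RAPID_DROPS, size=n, p=_RAPID_P),
        rng.choice(_SLOW_DROPS, size=n, p=_SLOW_P),
    )
    weights = np.asarray(params.npiq_domain_weights)
    followup = BASELINE_DATE + timedelta(days=FOLLOWUP_DAYS)

    subjects = []
    for i in range(n):
        mmse1 = int(max(0, mmse0[i] - drops[i]))
        subjects.append(
            Subject(
                id=f"{id_prefix}{i + 1:05d}",
                age=float(np.round(age[i], 1)),
                sex="female" if female[i] else "male",
                duration_of_illness=float(np.round(duration[i], 2)),
                npiq=NPIQProfile(_allocate_npiq(int(npi_total[i]), weights, rng)),
                cognitive_scores=(
                    CognitiveScore("MMSE", int(mmse0[i]), BASELINE_DATE),
                    CognitiveScore("MMSE", mmse1, followup),
                ),
                hachinski=int(hachinski[i]),
                lawton_brody=None,
                imaging=ImagingRatings(fazekas=int(fazekas[i]), scheltens_mtla=int(scheltens[i])),
                amyloid_status_reference=status,
                reference_modality="CSF",
            )
        )
    return subjects


def generate_cohort(params: Optional[CohortParams] = None, seed: int | None = 0) -> list[Subject]:
    """Generate a reproducible two-group synthetic cohort.

    The same ``(params, seed)`` pair always yields an identical cohort.
    Reference amyloid status is assigned by group membership; CSF analyte
    values themselves are not simulated.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    cohort = _generate_group(params.positive, "positive", "P", rng)
    cohort += _generate_group(params.negative, "negative", "N", rng)
    return cohort


# --------------------------------------------------------------------------
# Deterministic fixture reproducing the printed classification counts


def _profile(**sev: int) -> NPIQProfile:
    return NPIQProfile.from_partial(sev)


# Hand-constructed component table: 28 reference-positive subjects of whom
# 25 score >= 3 (13 fours, 12 threes) and 3 score <= 2, and 20 reference-
# negative subjects of whom 16 score <= 2 and 4 score >= 3.  Columns:
# (reference status, npiq severities, rapid?, fazekas, scheltens, age, modality)
_FIXTURE_ROWS: tuple = (
    # --- reference positive, CAPS 4 (NPI>=2, rapid, Fazekas<=1): 13 true positives
    *[
        ("positive", dict(depression=2, irritability=1), True, 0, 2, 71.0, "CSF"),
        ("positive", dict(depression=1, irritability=1, anxiety=1), True, 1, 1, 66.0, "CSF"),
        ("positive", dict(depression=2, agitation=1), True, 0, 3, 74.0, "CSF"),
        ("positive", dict(irritability=2), True, 1, 2, 69.0, "PET"),
        ("positive", dict(depression=1, apathy=1), True, 0, 1, 63.0, "CSF"),
        ("positive", dict(depression=3, irritability=2), True, 1, 2, 77.0, "CSF"),
        ("positive", dict(anxiety=1, sleeping_disorder=1), True, 0, 2, 72.0, "PET"),
        ("positive", dict(depression=2, irritability=2, apathy=1), True, 1, 3, 68.0, "CSF"),
        ("positive", dict(depression=1, irritability=1), True, 0, 1, 75.0, "CSF"),
        ("positive", dict(agitation=2, appetite_disturbance=1), True, 1, 2, 70.0, "PET"),
        ("positive", dict(depression=2), True, 0, 2, 65.0, "CSF"),
        ("positive", dict(irritability=1, depression=1, euphoria=1), True, 1, 1, 73.0, "CSF"),
        ("positive", dict(depression=2, anxiety=2), True, 0, 2, 67.0, "PET"),
    ],
    # --- reference positive, CAPS 3: 12 true positives
    # NPI>=2 + rapid + Fazekas>=2
    ("positive", dict(depression=2, irritability=1), True, 2, 2, 76.0, "CSF"),
    ("positive", dict(depression=1, anxiety=1), True, 3, 1, 71.0, "CSF"),
    ("positive", dict(irritability=2, apathy=1), True, 2, 3, 64.0, "PET"),
    ("positive", dict(depression=3), True, 2, 2, 70.0, "CSF"),
    # NPI>=2 + slow + Fazekas<=1
    ("positive", dict(depression=2, irritability=1), False, 0, 2, 72.0, "CSF"),
    ("positive", dict(depression=1, irritability=1), False, 1, 1, 69.0, "CSF"),
    ("positive", dict(anxiety=2, sleeping_disorder=1), False, 0, 2, 78.0, "PET"),
    ("positive", dict(depression=2, apathy=2), False, 1, 3, 66.0, "CSF"),
    # NPI=1 + rapid + Fazekas<=1
    ("positive", dict(depression=1), True, 0, 2, 73.0, "CSF"),
    ("positive", dict(irritability=1), True, 1, 1, 68.0, "CSF"),
    ("positive", dict(apathy=1), True, 0, 2, 75.0, "PET"),
    ("positive", dict(anxiety=1), True, 1, 2, 62.0, "CSF"),
    # --- reference positive, CAPS <= 2: 3 false negatives
    # two >80y with marked medial temporal atrophy (Scheltens 4)
    ("positive", dict(depression=1), False, 0, 4, 84.0, "CSF"),
    ("positive", dict(), True, 1, 4, 82.0, "CSF"),
    # one typical late-onset case, CAPS 2, no neuropsychiatric symptoms
    ("positive", dict(), True, 0, 1, 69.0, "CSF"),
    # --- reference negative, CAPS >= 3: 4 false positives
    # two < 60y with early neuropsychiatric symptoms
    ("negative", dict(depression=2, irritability=1), True, 2, 1, 56.0, "CSF"),
    ("negative", dict(anxiety=1, agitation=1), False, 1, 1, 58.0, "CSF"),
    # two typical presentations
    ("negative", dict(depression=1, apathy=1), True, 1, 1, 70.0, "PET"),
    ("negative", dict(irritability=2), False, 0, 2, 67.0, "CSF"),
    # --- reference negative, CAPS <= 2: 16 true negatives
    ("negative", dict(), False, 2, 1, 71.0, "CSF"),
    ("negative", dict(), False, 0, 0, 66.0, "CSF"),
    ("negative", dict(depression=1), False, 2, 1, 74.0, "PET"),
    ("negative", dict(), True, 2, 0, 69.0, "CSF"),
    ("negative", dict(irritability=1), False, 1, 1, 63.0, "CSF"),
    ("negative", dict(), False, 3, 2, 77.0, "CSF"),
    ("negative", dict(anxiety=1), True, 2, 1, 72.0, "PET"),
    ("negative", dict(), False, 1, 0, 68.0, "CSF"),
    ("negative", dict(sleeping_disorder=1), False, 2, 1, 75.0, "CSF"),
    ("negative", dict(), True, 3, 2, 64.0, "CSF"),
    ("negative", dict(depression=1, anxiety=1), False, 2, 1, 70.0, "PET"),
    ("negative", dict(), False, 2, 0, 62.0, "CSF"),
    ("negative", dict(apathy=1), False, 1, 2, 79.0, "CSF"),
    ("negative", dict(), True, 2, 1, 66.0, "CSF"),
    ("negative", dict(), False, 0, 1, 73.0, "PET"),
    ("negative", dict(irritability=1), False, 3, 0, 60.0, "CSF"),
)


def paper_fixture() -> list[Subject]:
    """The deterministic 48-subject evaluation fixture.

    Synthetic stand-in for the unavailable per-subject study data: component
    inputs are hand-constructed so that CAPS at threshold 3 against the
    reference labels yields exactly the printed 2x2 counts — 25/28
    reference-positive subjects scoring >= 3 and 16/20 reference-negative
    subjects scoring <= 2 (TP=25, FP=4, TN=16, FN=3).  The three false
    negatives and four false positives follow the published case
    descriptions (ages, atrophy grades).  Identical on every call.
    """
    followup = BASELINE_DATE + timedelta(days=FOLLOWUP_DAYS)
    subjects = []
    for i, (status, sev, rapid, fazekas, scheltens, age, modality) in enumerate(_FIXTURE_ROWS):
        baseline = 24 if status == "positive" else 27
        drop = 4 if rapid else 1
        subjects.append(
            Subject(
                id=f"F{i + 1:03d}",
                age=age,
                sex="female" if i % 2 == 0 else "male",
                duration_of_illness=3.0,
                npiq=_profile(**sev),
                cognitive_scores=(
                    CognitiveScore("MMSE", baseline, BASELINE_DATE),
                    CognitiveScore("MMSE", baseline - drop, followup),
                ),
                hachinski=2,
                lawton_brody=23 if i % 3 == 0 else 20,
                imaging=ImagingRatings(fazekas=fazekas, scheltens_mtla=scheltens),
                amyloid_status_reference=status,
                reference_modality=modality,
            )
        )
    return subjects
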