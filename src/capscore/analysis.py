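"""Cohort-level statistics: 2x2 operating characteristics, ROC/AUC with
DeLong confidence intervals, normality-gated two-group comparisons, and
binary logistic regression.

Operating characteristics are computed in exact rational arithmetic
(:class:`fractions.Fraction`) and only rounded for display, so printed
percentages are reproducible to the digit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .caps import DEFAULT_THRESHOLD, compute_caps, compute_caps_mt
from .errors import CapsError, DegenerateDataError, ValidationError
from .scales import Subject

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "OperatingCharacteristics",
    "ROCResult",
    "GroupComparison",
    "LogisticFit",
    "EvaluationResult",
    "confusion_metrics",
    "roc_analysis",
    "auc_mann_whitney",
    "compare_continuous",
    "compare_categorical",
    "compare_groups",
    "fit_logistic",
    "evaluate_score",
    "ppv_npv_at_prevalence",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 classification counts against the reference amyloid status."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValidationError("confusion table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Sensitivity/specificity/predictive values as exact fractions.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    Likelihood ratios follow the usual definitions and are ``None`` when
    their own denominator vanishes.
    """

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    lr_positive: Optional[Fraction]
    lr_negative: Optional[Fraction]

    def as_percentages(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """Proportion metrics as rounded percentages, for display."""
        out: dict[str, Optional[float]] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if v is None else round(float(v) * 100, ndigits)
        return out

    def as_floats(self) -> dict[str, Optional[float]]:
        return {
            name: (None if getattr(self, name) is None else float(getattr(self, name)))
            for name in ("sensitivity", "specificity", "ppv", "npv", "lr_positive", "lr_negative")
        }


def confusion_metrics(table: ConfusionTable) -> OperatingCharacteristics:
    """Exact operating characteristics of a 2x2 table."""

    def ratio(num: int, den: int) -> Optional[Fraction]:
        return Fraction(num, den) if den > 0 else None

    sens = ratio(table.tp, table.tp + table.fn)
    spec = ratio(table.tn, table.tn + table.fp)
    ppv = ratio(table.tp, table.tp + table.fp)
    npv = ratio(table.tn, table.tn + table.fn)
    lr_pos = None
    lr_neg = None
    if sens is not None and spec is not None:
        if spec != 1:
            lr_pos = sens / (1 - spec)
        if spec != 0:
            lr_neg = (1 - sens) / spec
    return OperatingCharacteristics(sens, spec, ppv, npv, lr_pos, lr_neg)


def ppv_npv_at_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Post-test probabilities at a given pre-test prevalence (Bayes)."""
    if not 0 < prevalence < 1:
        raise ValidationError(f"prevalence must be in (0,1), got {prevalence!r}")
    p, se, sp = prevalence, sensitivity, specificity
    ppv = se * p / (se * p + (1 - sp) * (1 - p))
    npv = sp * (1 - p) / (sp * (1 - p) + (1 - se) * p)
    return ppv, npv


# --------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with AUC and a 95% confidence interval."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    method: str


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2).

    Equals the probability that a random positive outscores a random
    negative, with ties split evenly; identical to the trapezoidal area
    under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ranks = stats.rankdata(scores)  # midranks handle ties exactly
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC requires both classes present")
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    m, n = len(pos), len(neg)
    # V10[i]: fraction of negatives below pos[i] (+ half the ties); V01 dual.
    v10 = (np.searchsorted(neg, pos, side="left") + np.searchsorted(neg, pos, side="right")) / (2 * n)
    v01 = 1 - (np.searchsorted(pos, neg, side="left") + np.searchsorted(pos, neg, side="right")) / (2 * m)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)


def roc_analysis(
    scores: Sequence[float], labels: Sequence[int], ci_method: str = "delong"
) -> ROCResult:
    """Empirical ROC curve, AUC, and a 95% CI for the AUC.

    ``labels`` are 1 for reference-positive, 0 for reference-negative;
    higher scores must indicate the positive class.  The CI uses DeLong's
    non-parametric variance by default (``ci_method="hanley_mcneil"``
    selects the binormal-free Hanley-McNeil approximation) and is clipped
    to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and the same length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValidationError("ROC analysis requires both classes present")
    if ci_method not in ("delong", "hanley_mcneil"):
        raise ValidationError(f"unknown CI method {ci_method!r}")

    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = auc_mann_whitney(scores, labels)
    if ci_method == "delong":
        var = _delong_variance(scores, labels)
    else:
        var = _hanley_mcneil_variance(auc, m, n)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, auc_ci_95=ci, method=ci_method
    )


# --------------------------------------------------------------------------
# Two-group comparisons


@dataclass(frozen=True)
class GroupComparison:
    """One variable compared between the amyloid-positive and -negative groups."""

    variable: str
    test: str  # 't', 'mann_whitney', or 'chi_square'
    statistic: float
    p_value: float
    group_summary: dict = field(default_factory=dict)


def _normal_enough(x: np.ndarray, alpha: float) -> bool:
    """Lilliefors-corrected Kolmogorov-Smirnov normality gate."""
    if len(np.unique(x)) == 1:
        return False  # constant sample: KS against a normal is meaningless
    _, p = lilliefors(x, dist="norm")
    return p >= alpha


def compare_continuous(
    a: Sequence[float], b: Sequence[float], alpha_normality: float = 0.05
) -> GroupComparison:
    """t-test when both groups pass the normality gate, else Mann-Whitney.

    The gate is a Lilliefors-corrected Kolmogorov-Smirnov test per group at
    ``alpha_normality`` (the composite-null correction matches how clinical
    software applies "the KS test" to data with estimated mean and SD).
    Equal variances are assumed on the t path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 4 or len(b) < 4:
        raise ValidationError("each group needs >= 4 observations for the normality gate")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateDataError("all values identical: two-sample tests undefined")
    if _normal_enough(a, alpha_normality) and _normal_enough(b, alpha_normality):
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return GroupComparison(
        variable="",
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_summary={
            "mean_a": float(a.mean()),
            "sd_a": float(a.std(ddof=1)),
            "n_a": len(a),
            "mean_b": float(b.mean()),
            "sd_b": float(b.std(ddof=1)),
            "n_b": len(b),
        },
    )


def compare_categorical(
    a: Sequence, b: Sequence, yates_correction: bool = False
) -> GroupComparison:
    """Chi-square test on the group x category contingency table.

    Yates continuity correction is off by default for 2x2 tables.
    """
    a, b = list(a), list(b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    table = pd.crosstab(
        pd.Series(["a"] * len(a) + ["b"] * len(b), name="group"),
        pd.Series(a + b, name="category"),
    )
    if table.shape[1] < 2:
        # a single observed category carries no association information
        return GroupComparison(
            variable="", test="chi_square", statistic=0.0, p_value=1.0,
            group_summary={"table": table.to_dict()},
        )
    stat, p, _, _ = stats.chi2_contingency(table.values, correction=yates_correction)
    return GroupComparison(
        variable="", test="chi_square", statistic=float(stat), p_value=float(p),
        group_summary={"table": table.to_dict()},
    )


def _rapid_or_none(s: Subject):
    from .decline import annualized_decline
    from .errors import InsufficientVisitsError, ZeroSpanError

    try:
        return annualized_decline(s.mmse_scores).rapid
    except (InsufficientVisitsError, ZeroSpanError):
        return None


#: Variable registry: name -> (kind, extractor).  Extractors return None
#: when the field is absent; such subjects are dropped for that variable.
COHORT_VARIABLES: dict[str, tuple[str, Callable[[Subject], object]]] = {
    "age": ("continuous", lambda s: s.age),
    "duration_of_illness": ("continuous", lambda s: s.duration_of_illness),
    "baseline_mmse": ("continuous", lambda s: s.baseline_mmse),
    "npiq_total": ("continuous", lambda s: s.npiq.total_score if s.npiq else None),
    "npiq_symptom_count": ("continuous", lambda s: s.npiq.symptom_count if s.npiq else None),
    "hachinski": ("continuous", lambda s: s.hachinski),
    "sex": ("categorical", lambda s: s.sex),
    "rapid_decline": ("categorical", _rapid_or_none),
    "white_matter_disease": (
        "categorical",
        lambda s: (s.imaging.fazekas >= 2) if s.imaging else None,
    ),
    "mtla": ("categorical", lambda s: s.imaging.scheltens_mtla if s.imaging else None),
    "stage": ("categorical", lambda s: s.stage),
}


def compare_groups(cohort: Sequence[Subject], variable: str, **kwargs) -> GroupComparison:
    """Compare one registered variable between reference Abeta+ and Abeta- groups.

    Continuous variables go through the normality-gated t / Mann-Whitney
    path; categorical variables through chi-square.  Subjects with unknown
    reference status or a missing field are dropped for this variable.
    """
    if variable not in COHORT_VARIABLES:
        raise ValidationError(
            f"unknown variable {variable!r}; known: {sorted(COHORT_VARIABLES)}"
        )
    kind, extract = COHORT_VARIABLES[variable]
    pos = [extract(s) for s in cohort if s.amyloid_status_reference == "positive"]
    neg = [extract(s) for s in cohort if s.amyloid_status_reference == "negative"]
    pos = [v for v in pos if v is not None]
    neg = [v for v in neg if v is not None]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"variable {variable!r}: need >= 2 subjects per group, "
            f"got {len(pos)} positive / {len(neg)} negative"
        )
    if kind == "continuous":
        result = compare_continuous(pos, neg, **kwargs)
    else:
        result = compare_categorical(pos, neg, **kwargs)
    return GroupComparison(
        variable=variable,
        test=result.test,
        statistic=result.statistic,
        p_value=result.p_value,
        group_summary=result.group_summary,
    )


# --------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool = False


def fit_logistic(
    features, outcome, feature_names: Optional[Sequence[str]] = None, add_intercept: bool = True
) -> LogisticFit:
    """Binary logistic regression by Newton/IRLS with Wald z p-values.

    ``features`` is (n, k); an intercept column is prepended by default.
    Perfect separation is flagged rather than raised: the returned fit has
    ``converged=False`` and ``separation=True``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    n, k = X.shape
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(k)]
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValidationError("features must not be constant")
    if n <= k + 1:
        raise ValidationError(f"need n > k+1 observations, got n={n}, k={k}")
    names = tuple((["intercept"] if add_intercept else []) + list(feature_names))
    design = sm.add_constant(X, prepend=True) if add_intercept else X

    import warnings

    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", disp=False, maxiter=100, tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
        return LogisticFit(
            names=names,
            params=np.asarray(res.params, dtype=float),
            bse=np.asarray(res.bse, dtype=float),
            z_values=np.asarray(res.tvalues, dtype=float),
            p_values=np.asarray(res.pvalues, dtype=float),
            log_likelihood=float(res.llf),
            converged=converged,
        )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        nan = np.full(len(names), np.nan)
        return LogisticFit(
            names=names, params=nan, bse=nan, z_values=nan, p_values=nan,
            log_likelihood=np.nan, converged=False, separation=True,
        )


# --------------------------------------------------------------------------
# End-to-end evaluation


@dataclass(frozen=True)
class EvaluationResult:
    """Cohort-level evaluation of a point score against the reference label."""

    confusion: ConfusionTable
    metrics: OperatingCharacteristics
    roc: Optional[ROCResult]
    n_scored: int
    n_excluded: int
    exclusions: tuple[tuple[str, str], ...]  # (subject id, reason)


def evaluate_score(
    cohort: Sequence[Subject],
    score: str | Callable[[Subject], object] = "caps",
    threshold: int = DEFAULT_THRESHOLD,
    **score_kwargs,
) -> EvaluationResult:
    """Score a cohort and evaluate against the reference amyloid status.

    ``score`` is ``"caps"``, ``"caps_mt"``, or any callable returning an
    object with ``score`` and ``predicted_status`` attributes.  Subjects
    without a binary reference label or with unscoreable inputs are dropped,
    with each exclusion logged and reported.
    """
    if score == "caps":
        score_fn = lambda s: compute_caps(s, threshold=threshold, **score_kwargs)
    elif score == "caps_mt":
        score_fn = lambda s: compute_caps_mt(s, threshold=threshold, **score_kwargs)
    elif callable(score):
        score_fn = score
    else:
        raise ValidationError(f"score must be 'caps', 'caps_mt', or a callable, got {score!r}")

    totals: list[float] = []
    labels: list[int] = []
    tp = fp = tn = fn = 0
    exclusions: list[tuple[str, str]] = []
    for s in cohort:
        if s.amyloid_status_reference not in ("positive", "negative"):
            exclusions.append((s.id, "no reference amyloid status"))
            continue
        try:
            result = score_fn(s)
        except CapsError as exc:
            exclusions.append((s.id, str(exc)))
            continue
        truth = s.amyloid_status_reference == "positive"
        predicted = result.predicted_status == "positive"
        tp += truth and predicted
        fn += truth and not predicted
        fp += (not truth) and predicted
        tn += (not truth) and not predicted
        totals.append(float(result.score))
        labels.append(int(truth))
    for sid, reason in exclusions:
        logger.warning("subject %s excluded from evaluation: %s", sid, reason)
    if not totals:
        raise ValidationError("no scoreable subjects with a reference label")
    table = ConfusionTable(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
    try:
        roc = roc_analysis(totals, labels)
    except ValidationError:
        roc = None  # single-class cohort: curve undefined, counts still valid
    return EvaluationResult(
        confusion=table,
        metrics=confusion_metrics(table),
        roc=roc,
        n_scored=len(totals),
        n_excluded=len(exclusions),
        exclusions=tuple(exclusions),
    )
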