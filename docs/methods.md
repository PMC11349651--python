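# Methods

## The score

CAPS is an additive clinical prediction rule for cerebral amyloid
positivity in people already carrying a clinical Alzheimer-syndrome
diagnosis. It is *not* a diagnostic test: it orders patients by the
likelihood that confirmatory CSF or PET testing will be positive. Three
binary-or-banded components contribute points:

- **Neuropsychiatric burden** — the NPI-Q total severity score (12 domains,
  each 0–3). 0 → 0 points, 1 → 1, ≥ 2 → 2. A configuration switch
  (`npiq_mode="count"`) substitutes the symptom count for sensitivity
  analysis; the total severity is the default and the recommended input.
- **Rapid decline** — 1 point when the annualized MMSE loss strictly
  exceeds 2 points/year. The rate uses the first and last dated MMSE
  (maximal span); this matches the two-timepoint clinical definition and
  the exclusion rule for subjects with fewer than two dated scores. A
  least-squares slope over all visits is available
  (`decline_method="regression"`) but off by default. Years are days/365.25.
- **Low white-matter burden** — 1 point for Fazekas 0–1. Prominent
  microangiopathy (Fazekas ≥ 2) suggests a vascular contribution and earns
  nothing.

Total 0–4; **positive prediction at ≥ 3** (ties at the threshold are
positive). CAPS-MT adds 1 point for Scheltens/MTLA > 2. No point table for
the extended score has been published; the simplest additive extension is
used here — range 0–5, threshold unchanged at ≥ 3 and exposed in every API
that scores subjects. This is the package's design choice and should be
treated as such when comparing against published CAPS-MT figures.

## MoCA → MMSE conversion

Only the 14 published crosswalk pairs are available, not the full table
they were drawn from. The conversion is therefore built from the
de-duplicated anchors (11→18, 12→19, 13→20, 14→20, 15→21, 18→24, 21→26,
24→28, 25→28, 26→29, 28→29, 30→30), linear interpolation between anchors,
extrapolation below MoCA 11 with the adjacent segment's slope (floored at
0), an identity cap at 30, and half-up rounding. This reproduces every
published pair exactly and is monotone non-decreasing over the whole 0–30
range; converted values for non-anchor inputs may differ from the original
external crosswalk by ±1 point.

## CSF positivity rule

Published cutoffs give normal ranges for five quantities but not the
Boolean combination used for classification. The implemented rule:
positive iff p-tau/Aβ42 ≥ 0.024 **or** t-tau/Aβ42 ≥ 0.29; when no ratio is
available (stored or derivable), positive iff Aβ42 ≤ 1030 ng/L; ratios take
precedence because ratios were the quantities calculated for
classification. Borderline equality counts as positive. When both CSF and
PET are available, PET decides (the more direct measure). Each call records
the deciding rule in its `basis` field.

## Statistical battery

- **Two-group comparisons.** Continuous variables pass through a
  per-group normality gate — a Lilliefors-corrected Kolmogorov–Smirnov
  test at α = 0.05, i.e. the composite-null version clinical software
  applies when mean and SD are estimated — then an equal-variance
  independent-samples t-test (both pass) or a two-sided Mann–Whitney U.
  Categorical variables use chi-square without Yates correction by default
  (a flag enables it). Samples that are entirely constant raise a
  degenerate-data error rather than returning a meaningless p.
- **Logistic regression** is maximum likelihood via Newton/IRLS
  (statsmodels backend) with Wald z p-values; perfect separation is
  flagged (`separation=True`, `converged=False`) instead of raising.
- **ROC/AUC.** The AUC is computed by midranks and equals the normalized
  Mann–Whitney U statistic (ties count ½), which is identical to the
  trapezoidal area under the empirical curve. The 95% CI uses DeLong's
  non-parametric variance by default, Hanley–McNeil on request, clipped to
  [0, 1].
- **2×2 operating characteristics** are kept as exact `Fraction`s;
  undefined metrics (zero denominator) are `None`, never 0. PPV/NPV at an
  arbitrary prevalence are available via Bayes
  (`ppv_npv_at_prevalence`) — predictive values are prevalence-dependent
  and the defaults only describe cohorts with ~58% amyloid prevalence.

## Synthetic cohort generator

The generator emulates a two-group memory-clinic cohort whose *marginal*
distributions match the published group description: per group it draws
age (truncated normal > 40), sex (Bernoulli), illness duration, baseline
MMSE (integers 0–30), NPI-Q total (integers 0–36), Hachinski (integers
0–18), Fazekas and Scheltens categories, and a rapid-decline indicator;
a second MMSE visit 365 days after baseline is synthesized consistent with
the drawn decline status.

Numerical choices that matter:

- **Moment matching.** For bounded scales, a normal truncated at the scale
  limits and centred on the target mean has a biased mean (e.g. NPI-Q
  2.73 (1.66) truncated at 0 would inflate the mean by ≈ 0.18, an order of
  magnitude more than the Monte-Carlo error at n = 20,000). Integer scales
  are therefore drawn from a discretized normal — cell k gets the normal
  mass of (k−½, k+½], boundary cells absorb the tails — whose location is
  solved by root-finding so the *discrete* mean equals the target exactly;
  continuous scales use the analogous truncated-normal moment match. The
  nominal SD is kept as the normal's scale, so the realized SD is slightly
  below nominal near a boundary; only means are calibrated.
- **NPI-Q domains.** The drawn total is allocated across the 12 domains by
  a weighted multinomial (severities capped at 3, excess re-allocated).
  Weights are proportional to per-domain means: the published depression
  and irritability means (0.80/0.63 in Aβ+, 0.14/0.18 in Aβ−) plus the
  residual of the group total split equally over the other ten domains.
- **Decline link.** Slow decliners lose 0–1 points over the 365-day
  interval, rapid decliners 3–6. A 2-point loss is excluded from the slow
  set because 2 points over 365 days annualizes to 2.0014 > 2 with the
  365.25-day year, which would silently flip the drawn status.
- **White matter and atrophy.** The published "white matter disease
  yes/no" row is internally inconsistent (columns don't sum to 100%);
  "yes" is interpreted as Fazekas ≥ 2 with prevalence 0.05 (Aβ+) and 0.18
  (Aβ−). The published Scheltens 0/1/2/3 percentages also leave 10–14%
  unaccounted; the remainder is assigned to grade 4.
- **Independence.** No within-group correlations are published, so all
  variables are drawn independently within group apart from the
  decline-to-second-visit link. Real cohorts correlate NPI-Q with decline
  and MMSE with atrophy; a green calibration test therefore establishes
  marginal fidelity, not joint realism, and pipeline results on generated
  cohorts should not be read as a validation of the score's accuracy.
- CSF analyte values and PET quantities are not simulated; reference
  status is assigned by group membership.

## The 48-subject fixture

`paper_fixture()` is a deterministic, hand-constructed synthetic cohort of
28 reference-positive and 20 reference-negative subjects whose component
inputs yield exactly the published classification counts (TP 25, FP 4,
TN 16, FN 3) at threshold ≥ 3. The misclassified subjects follow the
published case descriptions: two false negatives over 80 with Scheltens 4
(rescued by CAPS-MT), one aged 69 scoring 2 with no neuropsychiatric
symptoms, and four false positives including two under-60s with early
neuropsychiatric symptoms. All other fields (baseline MMSE values, sex
alternation, Hachinski, Lawton-Brody) are plausible filler and carry no
information; per-subject identities are an invention constrained only by
the printed counts and case notes. Confusion-table metrics computed from
the fixture are exact by construction; its AUC and CI depend on the
invented score distribution and are *not* reproductions of published
values.

## Degenerate inputs and tie-breaks

- `classify` ties at the threshold → positive.
- Decline with < 2 dated scores → exclusion error; zero span → error;
  improving scores give a negative rate and are never rapid.
- Evaluation drops unscoreable subjects one at a time, logs each reason,
  and reports the exclusion list; it fails only when nothing is scoreable.
- Single-class cohorts: the confusion table and defined metrics are
  returned, the ROC is `None`.

## Known limitations

- The CAPS-MT point table and threshold are this package's extension, not
  a published specification.
- The generator calibrates marginal means only (see above).
- The normality gate's α and the equal-variance t-test mirror common
  clinical-software defaults; Welch or different gates will change
  borderline p-values.
- Predictive values shown for the fixture inherit its ~58% prevalence;
  use `ppv_npv_at_prevalence` for other settings.
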