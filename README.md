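# capscore

Clinical β-amyloid positivity prediction for clinical Alzheimer syndrome.

A substantial fraction of people who meet clinical criteria for probable or
possible Alzheimer disease turn out to be amyloid-negative on CSF or PET
biomarker testing. With anti-amyloid therapies in clinical use, clinicians
need a cheap way to triage who is most likely to test positive before
spending a lumbar puncture or a PET scan. `capscore` implements **CAPS**
(Clinical β-Amyloid Positivity Prediction Score), an additive 0–4 point
score built from three bedside observations, together with everything
needed to evaluate it: cohort I/O, longitudinal decline computation, group
comparisons, logistic regression, ROC/AUC with DeLong confidence intervals,
2×2 operating characteristics, and a calibrated synthetic memory-clinic
cohort generator.

## The score

For a subject with clinical Alzheimer syndrome:

| component | status | points |
|---|---|---|
| NPI-Q total severity | 0 | 0 |
| | 1 | 1 |
| | ≥ 2 | 2 |
| rapid cognitive decline | MMSE loss ≤ 2 points/year | 0 |
| | MMSE loss > 2 points/year | 1 |
| Fazekas white-matter rating | ≥ 2 | 0 |
| | 0 or 1 | 1 |

CAPS = NPI-Q points + decline points + Fazekas points ∈ {0,…,4}; a total of
**3 or 4 predicts amyloid positivity**. The rationale: neuropsychiatric
symptoms and fast decline are more frequent with amyloid pathology, while
prominent white-matter microangiopathy suggests a vascular driver of the
decline instead. **CAPS-MT** appends one point for marked medial temporal
atrophy (Scheltens rating > 2), extending the range to 0–5 with the same
default threshold.

MoCA-only visits are converted to MMSE equivalents through a weighted-mean
crosswalk (anchor-exact, linearly interpolated, monotone). Decline is
annualized as (first − last MMSE) / years between first and last visit,
with a strict > 2 points/year rapid rule.

## Worked example

```python
from capscore import evaluate_score, paper_fixture

ev = evaluate_score(paper_fixture(), "caps", threshold=3)
print(ev.confusion.as_tuple(), ev.metrics.as_percentages())
```

Running `python examples/evaluate_fixture.py` prints:

```
scored subjects: 48 (excluded: 0)
confusion table: TP=25 FP=4 TN=16 FN=3
sensitivity 89.3%  specificity 80.0%  PPV 86.2%  NPV 84.2%
LR+ 4.46  LR- 0.13
AUC 0.903 (95% CI 0.812-0.994, delong)
```

The 48-subject fixture is a deterministic synthetic cohort whose component
inputs reproduce the published validation counts: 25 of 28
reference-positive subjects score ≥ 3 (true positives), 16 of 20
reference-negative subjects score ≤ 2 (true negatives). Sensitivity is the
exact fraction 25/28, specificity 16/20, PPV 25/29, NPV 16/19 — the package
keeps these as rationals and rounds only for display.

Other examples (each a short, self-contained script under `examples/`):

- `score_single_subject.py` — chart data in, CAPS/CAPS-MT out.
- `simulate_cohort.py` — generate a two-group synthetic cohort and run the
  normality-gated comparison battery.
- `logistic_predictors.py` — logistic regression of amyloid status on
  NPI-Q and baseline MMSE.
- `end_to_end_pipeline.py` — CSV in, schema-validated JSON report out via
  `run_pipeline`.

## Synthetic cohorts

`generate_cohort(default_params(), seed)` draws amyloid-positive and
-negative groups whose marginal distributions match the published
two-group description (e.g. Aβ+: baseline MMSE 24.50 (2.52), NPI-Q total
2.73 (1.66), 61% rapid decliners; Aβ−: 26.85 (3.71), 1.18 (1.14), 50%).
Integer scales are drawn from discretized normals whose location is solved
so the post-truncation mean equals the target exactly; see
`docs/methods.md` for what the generator does and does not emulate.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a large synthetic amyloid-positive cohort with the default
parameterization and writes the recomputed sample means of the NPI-Q total
score and baseline MMSE as JSON.
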