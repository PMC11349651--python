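"""Which clinical variables independently predict amyloid positivity?

Fits a binary logistic regression of the reference amyloid label on NPI-Q
total and baseline MMSE in a synthetic cohort, printing coefficients with
Wald p-values.
"""

import numpy as np

from capscore import default_params, fit_logistic, generate_cohort

cohort = generate_cohort(default_params(150, 110), seed=5)
rows = np.array(
    [
        (s.npiq.total_score, s.baseline_mmse, s.amyloid_status_reference == "positive")
        for s in cohort
    ],
    dtype=float,
)

fit = fit_logistic(rows[:, :2], rows[:, 2], feature_names=["npiq_total", "baseline_mmse"])
print(f"converged: {fit.converged}   log-likelihood: {fit.log_likelihood:.2f}")
for name, b, p in zip(fit.names, fit.params, fit.p_values):
    print(f"  {name:<14} coef {b:+.3f}   p = {p:.4g}")

# A positive NPI-Q coefficient means each extra severity point raises the
# odds of amyloid positivity; in cohorts built from the default group
# distributions it is the dominant independent predictor.
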