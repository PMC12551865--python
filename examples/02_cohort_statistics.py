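"""Firth-regression outcome analysis on a synthetic patient cohort.

Generates a cohort with known logistic effects of the contrast gradient on
short-term outcomes, then runs the full statistical chain: confounder scan,
penalized-likelihood-ratio forward selection per outcome, BH-FDR across the
selected predictors, and per-10-unit odds-ratio reporting.
"""

import tempfile
from pathlib import Path

import numpy as np

import aortagrad as ag

# 930 patients keep the Monte-Carlo noise low enough to see the known
# effects; the generating coefficients mirror the per-10-unit scale.
df, truth = ag.generate_cohort(ag.CohortSpec(n_patients=930, seed=3))
params = df[["patient_id", "mean_intensity", "proximal_intensity", "contrast_gradient"]]

with tempfile.TemporaryDirectory() as tmp:
    report = ag.run_stats(params, df, Path(tmp))

print("Confounders flagged as covariates:", ", ".join(report["covariates"]) or "none")
print()
mt = report["model_table"]
grad = mt[mt.term == "contrast_gradient"]
print("Outcomes where forward selection kept the contrast gradient")
print("(odds ratios per 10 HU/% decrease; true generating OR in brackets):")
for _, row in grad.iterrows():
    true_or = float(np.exp(10 * truth["gradient_effect_per_unit"][row.outcome]))
    print("  %-22s OR %.3f (95%% CI %.3f-%.3f), p=%.4g, q=%.4g  [true %.3f]"
          % (row.outcome, row["or"], row.or_ci_low, row.or_ci_high,
             row.p, row.p_adjusted, true_or))
print()
print("An OR below 1 means that a steeper intensity decline along the aorta")
print("(a more negative gradient) raises the odds of the adverse outcome.")
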