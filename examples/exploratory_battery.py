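"""The 27-model exploratory battery on a cohort with planted effects.

Generates a large cohort (n = 500 so the planted effects are visible),
runs the quasi-Poisson count models and the Huber residual-change models,
and prints the focal rows next to the generator's true values.
"""

import math

import modengage as me
from modengage.synth import planned_analysis_frame

config = me.CohortConfig(seed=2024, n_participants=500, dropout_probability=0.0)
frame = planned_analysis_frame(me.generate_cohort(config))
results = me.run_exploratory_battery(frame)

cols = ["model_id", "b", "robust_se", "statistic", "rate_ratio", "p_raw", "p_fdr"]
age_row = results[(results.outcome == "between_count") & (results.predictor == "age")]
cred_row = results[(results.outcome == "between_count") & (results.predictor == "ceq_credibility")]
change_row = results[(results.outcome == "phq9_week8") & (results.predictor == "between_count")]

print(f"battery: {len(results)} models, "
      f"{(results.p_raw < 0.05).sum()} with p_raw < .05, "
      f"{(results.p_fdr < 0.05).sum()} surviving BH-FDR\n")
print("age -> between-module revisits (true log rate ratio ln(1.07) = 0.0677):")
print(age_row[cols].to_string(index=False))
print("\ncredibility -> revisits (true ln(1.19) = 0.174):")
print(cred_row[cols].to_string(index=False))
print("\nrevisits -> week-8 PHQ-9 given baseline (true b = 0.23):")
print(change_row[["model_id", "b", "robust_se", "statistic", "p_raw", "p_fdr"]].to_string(index=False))
print(
    "\nrate_ratio = exp(b): each extra year of age multiplies the expected "
    "revisit count by that factor.  The residual-change coefficient is in "
    "PHQ-9 points per revisit after controlling for baseline severity."
)
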