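"""Cohort engagement descriptives from a simulated trial.

Runs the full pipeline (identify -> attribute -> summarize) on a simulated
26-participant cohort and prints the descriptive tables: per-participant
medians/IQRs, the per-module distribution, and the category breakdown.
"""

import pandas as pd

import modengage as me

spec = me.load_default_program()
config = me.CohortConfig(seed=1, n_participants=26)
participants = me.generate_cohort(config)
events, unlocks = me.generate_event_log(participants, spec, config)
enrollments = pd.Series(
    pd.to_datetime(participants["enrollment_date"]).dt.tz_localize("UTC").to_numpy(),
    index=participants["participant_id"],
)

attributed, anomalies, report = me.process_event_frames(events, unlocks, enrollments, spec)
summaries = me.summarize_cohort(attributed, spec.n_modules)

n_within = int(summaries["within_count"].sum())
n_between = int(summaries["between_count"].sum())
total = n_within + n_between
print(f"retained interactions: {total} "
      f"({n_within} within-module, {n_between} between-module revisits)")
print(f"participants who ever revisited: {(summaries['between_count'] > 0).sum()} of {len(summaries)}\n")

print("cohort summary (median / 25th / 75th percentiles):")
print(me.cohort_summary(summaries).to_string(index=False))

print("\ninteractions by module (declining use across the program):")
print(me.module_distribution(attributed, spec.n_modules).to_string(index=False))

print("\ninteractions by content category:")
print(me.category_breakdown(attributed).to_string())
print(
    "\nWithin-module counts above 62 mean participants did more than the "
    "program requires; the between-module column counts returns to content "
    "from earlier treatment stages ('revisits'), which are rare and skewed "
    "toward module 1."
)
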