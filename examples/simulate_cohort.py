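"""Generate a synthetic 26-participant cohort and write it as a fixture.

The generator emulates the data structure of an 8-week module-based CBT
app trial: item-level clinical scales with target reliabilities, raw event
logs with errant opens and logging bursts, and sequential module unlocks.
"""

import sys

import modengage as me

out = sys.argv[1] if len(sys.argv) > 1 else "scratch/example_fixture"

config = me.CohortConfig(seed=11, n_participants=26)
participants = me.generate_cohort(config)
spec = me.load_default_program()
events, unlocks = me.generate_event_log(participants, spec, config)
me.write_fixture(out, participants, events, unlocks, config)

print(f"fixture written to {out}")
print(f"participants: {len(participants)}, raw events: {len(events)}, unlocks: {len(unlocks)}")
print(
    participants[["participant_id", "age", "phq9_baseline", "hamd_baseline",
                  "planned_within", "planned_between", "completed_trial"]]
    .head(6)
    .to_string(index=False)
)
print(
    "\nplanned_within / planned_between are simulation ground truth: the "
    "interaction counts the participant's event log is built to produce "
    "after filtering (62 required completions plus optional extras, and "
    "revisits whose rate rises with age and treatment credibility)."
)
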