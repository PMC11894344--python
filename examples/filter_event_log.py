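"""Filtering rules on a hand-built event log.

Builds one participant's morning of app use — an errant 3-second tap, a
real 4-minute read, and a burst of 26 activity-scheduling logs — and shows
what the two a-priori rules retain.
"""

import pandas as pd

import modengage as me

spec = me.load_default_program()

rows = []
def ev(ts, action, cid):
    rows.append(
        {"participant_id": "P1", "timestamp": pd.Timestamp(ts, tz="UTC"),
         "element": cid or "app", "action": action, "content_id": cid, "platform": "ios"}
    )

# an errant open: closed after 3 seconds, below the 5-second threshold
ev("2023-01-09T09:00:00", "content_open", "m1_psychoeducation_reading")
ev("2023-01-09T09:00:03", "content_close", "m1_psychoeducation_reading")
# a meaningful read: 4 minutes of dwell
ev("2023-01-09T09:10:00", "content_open", "m1_psychoeducation_reading")
ev("2023-01-09T09:14:00", "content_close", "m1_psychoeducation_reading")
# a logging burst: 26 activities scheduled in one sitting
for m in range(26):
    ev(f"2023-01-09T10:{m:02d}:00", "log_submit", "m3_schedule_activity")
# returning to log again later the same day counts separately
ev("2023-01-09T19:00:00", "log_submit", "m3_schedule_activity")

events = pd.DataFrame(rows)
interactions, report = me.identify_interactions(events, spec)

print(f"raw events:            {len(events)}")
print(f"retained interactions: {len(interactions)}")
print(interactions[["timestamp", "content_id", "category", "source"]].to_string(index=False))
print(
    "\nThe 3-second tap is dropped (errant open), the 4-minute read counts, "
    "the 26-log burst collapses to one scheduling interaction, and the "
    "evening log (>30 min later) counts as a separate attempt to integrate "
    "the app into daily life."
)
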