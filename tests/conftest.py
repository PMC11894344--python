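import numpy as np
import pandas as pd
import pytest

from modengage import CohortConfig, load_default_program


@pytest.fixture(scope="session")
def spec():
    return load_default_program()


@pytest.fixture(scope="session")
def small_cohort_run(spec):
    """One generated 10-participant cohort pushed through the full pipeline."""
    from modengage import generate_cohort, generate_event_log, process_event_frames

    config = CohortConfig(seed=42, n_participants=10)
    participants = generate_cohort(config)
    events, unlocks = generate_event_log(participants, spec, config)
    enrollments = enrollment_series(participants)
    attributed, anomalies, report = process_event_frames(events, unlocks, enrollments, spec)
    return {
        "config": config,
        "participants": participants,
        "events": events,
        "unlocks": unlocks,
        "enrollments": enrollments,
        "attributed": attributed,
        "anomalies": anomalies,
        "report": report,
    }


def enrollment_series(participants: pd.DataFrame) -> pd.Series:
    return pd.Series(
        pd.to_datetime(participants["enrollment_date"]).dt.tz_localize("UTC").to_numpy(),
        index=participants["participant_id"],
    )


def make_events(rows):
    """Event DataFrame from (pid, iso-timestamp, action, content_id) tuples."""
    df = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "timestamp": pd.Timestamp(ts, tz="UTC"),
                "element": cid or "app",
                "action": action,
                "content_id": cid,
                "platform": "ios",
            }
            for pid, ts, action, cid in rows
        ]
    )
    return df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
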