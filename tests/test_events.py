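import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modengage import (
    compute_dwell,
    dedup_logging,
    filter_errant_opens,
    identify_interactions,
    interactions_to_events,
    read_event_log,
)
from .conftest import make_events


# --- dwell computation -----------------------------------------------------

def test_dwell_pairs_open_with_earliest_close_signal():
    events = make_events(
        [
            ("p1", "2023-01-02T10:00:00", "content_open", "m1_psychoeducation_reading"),
            ("p1", "2023-01-02T10:00:04", "content_close", "m1_psychoeducation_reading"),
            ("p1", "2023-01-02T11:00:00", "content_open", "m1_psychoeducation_video"),
            ("p1", "2023-01-02T11:00:07", "app_pause", None),
            ("p1", "2023-01-02T12:00:00", "content_open", "m1_evaluate_thoughts"),
        ]
    )
    spans = compute_dwell(events)
    assert list(spans["dwell_seconds"].round(1).fillna(-1)) == [4.0, 7.0, -1.0]


def test_dwell_close_must_precede_next_open():
    # the close after a second open belongs to that second open
    events = make_events(
        [
            ("p1", "2023-01-02T10:00:00", "content_open", "a"),
            ("p1", "2023-01-02T10:01:00", "content_open", "b"),
            ("p1", "2023-01-02T10:01:30", "content_close", "b"),
        ]
    )
    spans = compute_dwell(events)
    assert np.isnan(spans["dwell_seconds"].iloc[0])
    assert spans["dwell_seconds"].iloc[1] == 30.0


def test_errant_open_filter_boundary_semantics():
    spans = pd.DataFrame(
        {
            "participant_id": ["p"] * 3,
            "content_id": ["a", "b", "c"],
            "open_time": pd.to_datetime(["2023-01-02"] * 3, utc=True),
            "close_time": pd.NaT,
            "dwell_seconds": [4.9, 5.0, np.nan],
        }
    )
    kept = filter_errant_opens(spans, threshold_seconds=5.0)
    # 4.9 s removed; exactly 5 s retained ("fewer than 5" is strict);
    # undefined dwell (app killed) retained
    assert list(kept["content_id"]) == ["b", "c"]
    with pytest.raises(ValueError):
        filter_errant_opens(spans, threshold_seconds=-1)


@given(st.lists(st.floats(min_value=0, max_value=60), min_size=0, max_size=30))
@settings(deadline=None, max_examples=50)
def test_raising_dwell_threshold_never_increases_retained(dwells):
    spans = pd.DataFrame(
        {
            "participant_id": "p",
            "content_id": [f"c{i}" for i in range(len(dwells))],
            "open_time": pd.Timestamp("2023-01-02", tz="UTC"),
            "close_time": pd.NaT,
            "dwell_seconds": dwells,
        }
    )
    n_low = len(filter_errant_opens(spans, 5.0))
    n_high = len(filter_errant_opens(spans, 10.0))
    assert n_high <= n_low


# --- logging deduplication -------------------------------------------------

def _log_events(times_by_cid):
    rows = []
    for cid, times in times_by_cid.items():
        for t in times:
            rows.append(("p1", t, "log_submit", cid))
    return make_events(rows)


def test_burst_of_26_logs_within_30_minutes_counts_once(spec):
    times = [f"2023-01-02T10:{m:02d}:00" for m in range(26)]
    events = _log_events({"m3_schedule_activity": times})
    assert len(dedup_logging(events, spec)) == 1


def test_dedup_anchor_is_most_recently_retained(spec):
    # t = 0, 29, 58 min: the 29-min log is suppressed and does NOT reset the
    # window, so the 58-min log (>= 30 min after t=0) is retained
    events = _log_events(
        {"m3_schedule_activity": ["2023-01-02T10:00:00", "2023-01-02T10:29:00", "2023-01-02T10:58:00"]}
    )
    kept = dedup_logging(events, spec)
    assert list(kept["timestamp"].dt.strftime("%H:%M")) == ["10:00", "10:58"]


def test_dedup_is_per_logging_type(spec):
    events = _log_events(
        {
            "m3_schedule_activity": ["2023-01-02T10:00:00"],
            "m3_record_activity_mood": ["2023-01-02T10:01:00"],
        }
    )
    assert len(dedup_logging(events, spec)) == 2


def _brute_force_dedup(times, window_minutes=30.0, anchor="retained"):
    """Independent reference: test each submission against prior ones."""
    retained = []
    window = pd.Timedelta(minutes=window_minutes)
    for i, t in enumerate(times):
        pool = retained if anchor == "retained" else times[:i]
        if all(t - s >= window for s in pool):
            retained.append(t)
    return retained


@pytest.mark.parametrize("anchor", ["retained", "any"])
def test_dedup_matches_bruteforce_on_random_sequences(spec, anchor):
    rng = np.random.default_rng(2024)
    base = pd.Timestamp("2023-01-02T08:00:00", tz="UTC")
    for _ in range(200):
        n = int(rng.integers(1, 50))
        offsets = np.sort(rng.uniform(0, 600, n))
        times = [base + pd.Timedelta(minutes=float(m)) for m in offsets]
        events = _log_events({"m3_schedule_activity": [t.isoformat() for t in times]})
        kept = dedup_logging(events, spec, anchor=anchor)
        expected = _brute_force_dedup(times, anchor=anchor)
        assert list(kept["timestamp"]) == expected


@given(st.lists(st.floats(min_value=0, max_value=600), min_size=1, max_size=40))
@settings(deadline=None, max_examples=50)
def test_enlarging_dedup_window_never_increases_retained(spec, minutes):
    base = pd.Timestamp("2023-01-02T08:00:00", tz="UTC")
    times = [base + pd.Timedelta(minutes=m) for m in sorted(minutes)]
    events = _log_events({"m3_schedule_activity": [t.isoformat() for t in times]})
    n30 = len(dedup_logging(events, spec, window_minutes=30))
    n10 = len(dedup_logging(events, spec, window_minutes=10))
    assert n30 <= n10


# --- identify_interactions orchestration -----------------------------------

def test_empty_log_yields_empty_interactions(spec):
    empty = pd.DataFrame(
        columns=["participant_id", "timestamp", "element", "action", "content_id", "platform"]
    )
    empty["timestamp"] = pd.to_datetime(empty["timestamp"], utc=True)
    interactions, report = identify_interactions(empty, spec)
    assert interactions.empty and report.n_unknown == 0


def test_only_errant_opens_yield_zero_interactions(spec):
    events = make_events(
        [
            ("p1", "2023-01-02T10:00:00", "content_open", "m1_psychoeducation_reading"),
            ("p1", "2023-01-02T10:00:03", "content_close", "m1_psychoeducation_reading"),
            ("p1", "2023-01-02T11:00:00", "content_open", "m1_evaluate_thoughts"),
            ("p1", "2023-01-02T11:00:02", "app_close", None),
        ]
    )
    interactions, _ = identify_interactions(events, spec)
    assert interactions.empty


def test_unknown_content_ids_are_reported_not_fatal(spec):
    events = make_events(
        [
            ("p1", "2023-01-02T10:00:00", "content_open", "mystery_item"),
            ("p1", "2023-01-02T10:05:00", "content_close", "mystery_item"),
            ("p1", "2023-01-02T11:00:00", "content_open", "m1_psychoeducation_reading"),
            ("p1", "2023-01-02T11:05:00", "content_close", "m1_psychoeducation_reading"),
        ]
    )
    interactions, report = identify_interactions(events, spec)
    assert len(interactions) == 1
    assert report.unknown_content_ids == {"mystery_item": 2}  # open + close events


def test_identify_interactions_is_idempotent(spec, small_cohort_run):
    first, _ = identify_interactions(small_cohort_run["events"], spec)
    again, _ = identify_interactions(interactions_to_events(first), spec)
    pd.testing.assert_frame_equal(
        first[["participant_id", "timestamp", "content_id", "module_index", "category", "source"]],
        again[["participant_id", "timestamp", "content_id", "module_index", "category", "source"]],
    )


# --- reader ---------------------------------------------------------------

def test_reader_roundtrip_and_malformed_lines(tmp_path, spec):
    path = tmp_path / "events.jsonl"
    path.write_text(
        '{"participant_id": "p1", "timestamp": "2023-01-02T10:00:00Z", "action": "content_open", "content_id": "a", "element": "a", "platform": "ios"}\n'
        '{"participant_id": "p1", "timestamp": "not-a-time", "action": "content_open", "content_id": "b", "element": "b", "platform": "ios"}\n'
        '{"participant_id": "p1", "timestamp": "2023-01-02T09:00:00Z", "action": "warp", "content_id": "c", "element": "c", "platform": "ios"}\n'
        '{"participant_id": "p1", "timestamp": "2023-01-02T08:00:00Z", "action": "app_open", "content_id": null, "element": "home", "platform": "ios"}\n'
    )
    df = read_event_log(path)
    assert len(df) == 2  # two bad lines dropped
    assert df["timestamp"].is_monotonic_increasing  # sorted despite input order
    assert len(df.attrs["parse_errors"]) == 2
    assert "line 2" in df.attrs["parse_errors"][0]
    with pytest.raises(ValueError):
        read_event_log(path, errors="raise")
    with pytest.raises(FileNotFoundError):
        read_event_log(tmp_path / "missing.jsonl")


def test_reader_empty_file(tmp_path):
    path = tmp_path / "events.jsonl"
    path.write_text("")
    assert read_event_log(path).empty
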