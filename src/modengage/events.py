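"""Raw event-log processing: from logged taps to retained "interactions".

Two a-priori filtering rules turn a passively collected event stream into
meaningful content engagements:

1. **Errant-open rule** — a content open only counts if the content (or the
   app) was not closed again in fewer than ``dwell_threshold`` seconds
   (default 5 s).  Dwell exactly at the threshold is retained; an open with
   no subsequent close signal (e.g. the OS killed the app) is retained.
   Completion is not required for an open to count.
2. **Logging deduplication** — logging submissions (scheduling an activity,
   recording an activity and mood) only count when not submitted within
   ``window_minutes`` (default 30) of another retained submission of the
   same logging type, so a burst of 26 back-to-back logs counts once.

Actions retained after both rules are called *interactions*.  Event logs are
plain pandas DataFrames with columns ``participant_id, timestamp, element,
action, content_id, platform``; interactions add ``module_index, category,
source``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .program import ProgramSpec, ContentLookupError

logger = logging.getLogger(__name__)

ACTIONS = (
    "app_open",
    "app_pause",
    "app_close",
    "content_open",
    "content_close",
    "exercise_complete",
    "log_submit",
)
#: actions that end a dwell span for the 5-second rule
CLOSE_ACTIONS = ("content_close", "app_close", "app_pause")

EVENT_COLUMNS = ["participant_id", "timestamp", "element", "action", "content_id", "platform"]

__all__ = [
    "ACTIONS",
    "CLOSE_ACTIONS",
    "EVENT_COLUMNS",
    "AnomalyReport",
    "read_event_log",
    "compute_dwell",
    "filter_errant_opens",
    "dedup_logging",
    "identify_interactions",
    "interactions_to_events",
]


@dataclass
class AnomalyReport:
    """Non-fatal irregularities found while identifying interactions."""

    unknown_content_ids: dict[str, int] = field(default_factory=dict)
    duplicate_events: int = 0
    parse_errors: list[str] = field(default_factory=list)

    @property
    def n_unknown(self) -> int:
        return sum(self.unknown_content_ids.values())


def _empty_events() -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def read_event_log(path: str | Path, errors: str = "warn") -> pd.DataFrame:
    """Read an event log from JSONL (one object per line) or CSV.

    Events are returned sorted by (participant_id, timestamp, stable input
    order).  Malformed lines (unparseable timestamp, unknown action) are
    dropped and reported with their line numbers; ``errors='raise'`` turns
    them into a ValueError.  The list of messages is attached as
    ``df.attrs['parse_errors']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".jsonl":
        records, messages = _read_jsonl(path)
    else:
        records, messages = _read_csv(path)
    if errors == "raise" and messages:
        raise ValueError("; ".join(messages))
    for msg in messages:
        logger.warning("%s: %s", path.name, msg)
    if not records:
        df = _empty_events()
        df.attrs["parse_errors"] = messages
        return df
    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS + ["_line"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values(
        ["participant_id", "timestamp", "_line"], kind="stable"
    ).drop(columns="_line").reset_index(drop=True)
    df.attrs["parse_errors"] = messages
    return df


def _parse_record(rec: dict, lineno: int) -> tuple[dict | None, str | None]:
    action = rec.get("action")
    if action not in ACTIONS:
        return None, f"line {lineno}: unknown action {action!r}"
    ts = pd.to_datetime(rec.get("timestamp"), utc=True, errors="coerce")
    if pd.isna(ts):
        return None, f"line {lineno}: unparseable timestamp {rec.get('timestamp')!r}"
    cid = rec.get("content_id")
    if cid is not None and (isinstance(cid, float) and np.isnan(cid)):
        cid = None
    return {
        "participant_id": str(rec.get("participant_id")),
        "timestamp": ts,
        "element": rec.get("element", ""),
        "action": action,
        "content_id": cid,
        "platform": rec.get("platform", ""),
        "_line": lineno,
    }, None


def _read_jsonl(path: Path) -> tuple[list[dict], list[str]]:
    records, messages = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError:
                messages.append(f"line {lineno}: invalid JSON")
                continue
            parsed, msg = _parse_record(rec, lineno)
            if parsed is None:
                messages.append(msg)
            else:
                records.append(parsed)
    return records, messages


def _read_csv(path: Path) -> tuple[list[dict], list[str]]:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    records, messages = [], []
    for lineno, rec in enumerate(raw.to_dict("records"), start=2):
        rec = {k: (None if v == "" else v) for k, v in rec.items()}
        parsed, msg = _parse_record(rec, lineno)
        if parsed is None:
            messages.append(msg)
        else:
            records.append(parsed)
    return records, messages


def compute_dwell(events: pd.DataFrame) -> pd.DataFrame:
    """Pair each content_open with the earliest subsequent close signal.

    The close signal is the first ``content_close``/``app_close``/``app_pause``
    by the same participant before the next ``content_open`` (or the end of
    the log); if none occurs the dwell is undefined (NaN).  Returns one row
    per open: participant_id, content_id, open_time, close_time,
    dwell_seconds.
    """
    spans = []
    for pid, grp in events.groupby("participant_id", sort=False):
        actions = grp["action"].to_numpy()
        times = grp["timestamp"].to_numpy()
        cids = grp["content_id"].to_numpy(dtype=object)
        open_idx = np.flatnonzero(actions == "content_open")
        is_close = np.isin(actions, CLOSE_ACTIONS)
        for j, i in enumerate(open_idx):
            stop = open_idx[j + 1] if j + 1 < len(open_idx) else len(actions)
            close_pos = np.flatnonzero(is_close[i + 1 : stop])
            if close_pos.size:
                close_time = times[i + 1 + close_pos[0]]
                dwell = (close_time - times[i]) / np.timedelta64(1, "s")
            else:
                close_time, dwell = pd.NaT, np.nan
            spans.append((pid, cids[i], times[i], close_time, dwell))
    return pd.DataFrame(
        spans,
        columns=["participant_id", "content_id", "open_time", "close_time", "dwell_seconds"],
    )


def filter_errant_opens(spans: pd.DataFrame, threshold_seconds: float = 5.0) -> pd.DataFrame:
    """Drop spans closed in fewer than ``threshold_seconds`` seconds.

    Dwell exactly equal to the threshold is retained ("fewer than" excludes
    only strictly-below), and undefined dwell (no close signal) is retained.
    """
    if threshold_seconds < 0:
        raise ValueError("threshold_seconds must be non-negative")
    dwell = spans["dwell_seconds"]
    keep = dwell.isna() | (dwell >= threshold_seconds)
    return spans[keep].reset_index(drop=True)


def dedup_logging(
    events: pd.DataFrame,
    spec: ProgramSpec,
    window_minutes: float = 30.0,
    anchor: str = "retained",
) -> pd.DataFrame:
    """Deduplicate ``log_submit`` events per (participant, logging type).

    Greedy earliest-first scan: a submission is retained iff it occurs at
    least ``window_minutes`` after the reference submission of the same
    logging type; the first submission of each type is always retained.

    ``anchor`` selects the reference: ``"retained"`` (default) compares
    against the most recently *retained* submission, guaranteeing one credit
    per burst and progress for arbitrarily long slow streams; ``"any"``
    compares against every prior raw submission (sensitivity-analysis
    variant, which can suppress an entire slow stream after its first log).
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    if anchor not in {"retained", "any"}:
        raise ValueError(f"unknown anchor mode {anchor!r}")
    logs = events[events["action"] == "log_submit"]
    if logs.empty:
        return logs.reset_index(drop=True)
    logs = logs.copy()
    logs["_ltype"] = [
        spec.item(cid).logging_type if cid in spec._index else None
        for cid in logs["content_id"]
    ]
    window = pd.Timedelta(minutes=window_minutes)
    keep_idx: list = []
    for (_, _), grp in logs.groupby(["participant_id", "_ltype"], sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        times = grp["timestamp"].to_numpy()
        if anchor == "retained":
            last = None
            for idx, t in zip(grp.index, times):
                if last is None or t - last >= window:
                    keep_idx.append(idx)
                    last = t
        else:  # any prior raw submission
            for j, (idx, t) in enumerate(zip(grp.index, times)):
                if j == 0 or t - times[j - 1] >= window:
                    keep_idx.append(idx)
    retained = logs.loc[sorted(keep_idx)].drop(columns="_ltype")
    return retained.reset_index(drop=True)


def identify_interactions(
    events: pd.DataFrame,
    spec: ProgramSpec,
    dwell_threshold: float = 5.0,
    dedup_window_minutes: float = 30.0,
    dedup_anchor: str = "retained",
) -> tuple[pd.DataFrame, AnomalyReport]:
    """Apply both filtering rules and annotate retained interactions.

    Content/exercise opens pass through the dwell filter; logging
    submissions pass through the same-type deduplication.  Opens of
    logging-category content are navigational and not counted (the
    submission is the interaction).  Events referencing unknown content ids
    are excluded and tallied in the anomaly report; exact duplicate events
    are collapsed first.

    Returns ``(interactions, report)`` with interactions sorted by
    participant then timestamp, columns: participant_id, timestamp,
    content_id, module_index, category, source.
    """
    report = AnomalyReport(parse_errors=list(events.attrs.get("parse_errors", [])))
    if events.empty:
        return _empty_interactions(), report

    n0 = len(events)
    events = events.drop_duplicates(subset=EVENT_COLUMNS, keep="first")
    report.duplicate_events = n0 - len(events)

    known = events["content_id"].map(lambda c: c is None or c in spec._index)
    unknown = events.loc[~known, "content_id"]
    if len(unknown):
        report.unknown_content_ids = unknown.value_counts().to_dict()
        events = events[known]

    rows = []
    # content/exercise interactions via the dwell rule
    spans = compute_dwell(events)
    spans = filter_errant_opens(spans, threshold_seconds=dwell_threshold)
    for pid, cid, t in zip(
        spans["participant_id"], spans["content_id"], spans["open_time"]
    ):
        if cid is None:
            continue  # app/home-screen open, not a content unit
        item = spec.item(cid)
        if item.category == "logging":
            continue
        source = "exercise" if item.category == "practice" else "content_view"
        rows.append((pid, t, cid, item.module_index, item.category, source))

    # logging interactions via same-type deduplication
    retained_logs = dedup_logging(
        events, spec, window_minutes=dedup_window_minutes, anchor=dedup_anchor
    )
    for pid, cid, t in zip(
        retained_logs["participant_id"],
        retained_logs["content_id"],
        retained_logs["timestamp"],
    ):
        if cid is None:
            continue
        item = spec.item(cid)
        rows.append((pid, t, cid, item.module_index, item.category, "log"))

    out = pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp", "content_id", "module_index", "category", "source"],
    )
    if out.empty:
        return _empty_interactions(), report
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    out = out.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    return out, report


def _empty_interactions() -> pd.DataFrame:
    df = pd.DataFrame(
        columns=["participant_id", "timestamp", "content_id", "module_index", "category", "source"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def interactions_to_events(interactions: pd.DataFrame) -> pd.DataFrame:
    """Re-express retained interactions as a raw event log.

    Content views and exercises become ``content_open`` events with no close
    signal (undefined dwell, hence retained); logging interactions become
    ``log_submit`` events.  Running :func:`identify_interactions` on the
    result is a no-op, which makes the pipeline idempotent.
    """
    rows = []
    for rec in interactions.itertuples(index=False):
        action = "log_submit" if rec.source == "log" else "content_open"
        rows.append(
            (rec.participant_id, rec.timestamp, rec.content_id, action, rec.content_id, "synthetic")
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if df.empty:
        return _empty_events()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
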