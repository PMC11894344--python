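"""Module-stage timelines and within/between-module attribution.

A participant's *stage* at any instant is the latest module they have
unlocked.  Stage 1 begins at enrollment; each later stage begins at 00:00
UTC of its recorded unlock date, and stage intervals are half-open
``[start_i, start_{i+1})``.  The final reached stage extends to the end of
the treatment window (the last module has no successor and cannot be
revisited).

An interaction is *within-module* when its content belongs to the current
stage, and *between-module* (a "revisit") when its content belongs to an
earlier module.  Content from a module above the current stage is locked;
such interactions are anomalies — excluded from both counts and reported.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageTimeline",
    "TimelineError",
    "build_stage_timeline",
    "classify_interactions",
    "restrict_to_treatment_window",
]


class TimelineError(ValueError):
    """Unlock records inconsistent with sequential unlocking."""


@dataclass(frozen=True)
class StageTimeline:
    participant_id: str
    #: ordered (module_index, stage_start) pairs; starts strictly increase
    stages: tuple[tuple[int, pd.Timestamp], ...]

    def stage_at(self, when: pd.Timestamp) -> int:
        """Stage whose half-open interval contains ``when``.

        Raises ``TimelineError`` for instants before enrollment.
        """
        starts = [s for _, s in self.stages]
        pos = bisect_right(starts, when)
        if pos == 0:
            raise TimelineError(
                f"{self.participant_id}: instant {when} precedes enrollment"
            )
        return self.stages[pos - 1][0]

    @property
    def final_stage(self) -> int:
        return self.stages[-1][0]


def build_stage_timeline(
    unlocks: pd.DataFrame, enrollment: pd.Timestamp, participant_id: str | None = None
) -> StageTimeline:
    """Build a stage timeline from unlock records for one participant.

    ``unlocks`` needs columns ``module_index`` and ``unlock_date`` (dates;
    boundaries are set at 00:00 UTC).  Stage 1 starts at enrollment even
    with no records (the first module must be enterable on day 0).  Missing
    intermediate unlocks truncate the timeline at the last consecutive
    stage.  An unlock date before the enrollment date, or unlock dates that
    decrease with module index, raise :class:`TimelineError`.
    """
    enrollment = pd.Timestamp(enrollment)
    if enrollment.tzinfo is None:
        enrollment = enrollment.tz_localize("UTC")
    if participant_id is None:
        if len(unlocks) and "participant_id" in unlocks:
            participant_id = str(unlocks["participant_id"].iloc[0])
        else:
            participant_id = ""
    stages: list[tuple[int, pd.Timestamp]] = [(1, enrollment)]
    if unlocks.empty:
        return StageTimeline(participant_id, tuple(stages))

    recs = unlocks.sort_values("module_index")
    if recs["module_index"].duplicated().any():
        raise TimelineError(f"{participant_id}: duplicate unlock record for a module")
    dates = pd.to_datetime(recs["unlock_date"]).dt.tz_localize("UTC")
    if not dates.is_monotonic_increasing:
        raise TimelineError(f"{participant_id}: unlock dates decrease with module index")
    prev = 1
    for midx, date in zip(recs["module_index"], dates):
        midx = int(midx)
        if midx == 1:
            continue  # module 1 is open at enrollment
        if date < enrollment.normalize():
            raise TimelineError(
                f"{participant_id}: module {midx} unlock {date.date()} precedes enrollment"
            )
        if midx != prev + 1:
            break  # missing intermediate unlock: timeline stops at last stage
        start = max(date, enrollment)  # same-date unlock cannot precede enrollment
        stages.append((midx, start))
        prev = midx
    return StageTimeline(participant_id, tuple(stages))


def classify_interactions(
    interactions: pd.DataFrame,
    unlocks: pd.DataFrame,
    enrollments: pd.Series | dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute every interaction as within- or between-module.

    ``enrollments`` maps participant_id to enrollment instant.  Returns
    ``(attributed, anomalies)``: attributed interactions gain
    ``stage_at_time`` and ``attribution`` ('within'/'between') columns;
    interactions referencing locked content (module above the current
    stage) land in ``anomalies`` with an ``anomaly`` column.
    """
    if isinstance(enrollments, dict):
        enrollments = pd.Series(enrollments)
    att_frames, anom_frames = [], []
    for pid, grp in interactions.groupby("participant_id", sort=False):
        if pid not in enrollments.index:
            raise KeyError(f"no enrollment instant for participant {pid!r}")
        pun = unlocks[unlocks["participant_id"] == pid] if len(unlocks) else unlocks
        timeline = build_stage_timeline(pun, enrollments[pid], participant_id=str(pid))
        starts = np.array(
            [s.tz_convert("UTC").tz_localize(None).to_datetime64() for _, s in timeline.stages]
        )
        mods = np.array([m for m, _ in timeline.stages])
        times = grp["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
        pos = np.searchsorted(starts, times, side="right")
        if (pos == 0).any():
            raise TimelineError(f"{pid}: interaction precedes enrollment")
        stage = mods[pos - 1]
        grp = grp.copy()
        grp["stage_at_time"] = stage
        locked = grp["module_index"].to_numpy() > stage
        within = grp["module_index"].to_numpy() == stage
        grp["attribution"] = np.where(within, "within", "between")
        anom = grp[locked].copy()
        if len(anom):
            anom["attribution"] = "anomaly"
            anom["anomaly"] = "locked_content"
            anom_frames.append(anom)
        att_frames.append(grp[~locked])
    cols = list(interactions.columns) + ["stage_at_time", "attribution"]
    attributed = (
        pd.concat(att_frames, ignore_index=True) if att_frames else pd.DataFrame(columns=cols)
    )
    anomalies = (
        pd.concat(anom_frames, ignore_index=True)
        if anom_frames
        else pd.DataFrame(columns=cols + ["anomaly"])
    )
    return attributed, anomalies


def restrict_to_treatment_window(
    interactions: pd.DataFrame,
    enrollments: pd.Series | dict,
    window_days: int = 56,
) -> pd.DataFrame:
    """Keep interactions inside the half-open active-treatment window.

    The window is ``[enrollment, enrollment + window_days)`` in UTC: an
    interaction on day 55 is kept, one on day 56 is dropped.
    """
    if interactions.empty:
        return interactions
    if isinstance(enrollments, dict):
        enrollments = pd.Series(enrollments)
    enrollments = pd.to_datetime(enrollments)
    if enrollments.dt.tz is None:
        enrollments = enrollments.dt.tz_localize("UTC")
    start = interactions["participant_id"].map(enrollments)
    end = start + pd.Timedelta(days=window_days)
    keep = (interactions["timestamp"] >= start) & (interactions["timestamp"] < end)
    return interactions[keep].reset_index(drop=True)
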