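"""End-to-end orchestration: files in, report directory out.

``run_pipeline`` executes read -> identify -> attribute -> summarize ->
model battery and writes every tabular output plus a run manifest (config
snapshot, package version, anomaly counts, content hashes).  All thresholds
default to the analysis' a-priori values (5-second dwell, 30-minute
same-type deduplication, 56-day treatment window) and are surfaced so the
sensitivity comparisons are reproducible as a loop.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .attribution import classify_interactions, restrict_to_treatment_window
from .events import identify_interactions, read_event_log
from .metrics import (
    category_breakdown,
    cohort_summary,
    histogram_table,
    module_distribution,
    summarize_cohort,
)
from .program import ProgramSpec, load_default_program, load_program_spec
from .stats import run_exploratory_battery, spearman_matrix
from .synth import CohortConfig, generate_cohort, generate_event_log, write_fixture

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_fixture",
    "build_analysis_frame",
    "process_event_frames",
]

_ANALYSIS_VARS = [
    "age", "phq9_baseline", "hamd_baseline", "ceq_credibility", "ceq_expectancy",
    "csq_week8", "offapp_minutes", "phq9_week8", "hamd_week8",
]


class RunConfig(BaseModel):
    """Paths, thresholds and flags for one analysis run."""

    events: Path
    unlocks: Path
    participants: Path
    program_spec: Path | None = None  # packaged default when omitted
    out_dir: Path
    dwell_seconds: float = Field(default=5.0, gt=0)
    dedup_minutes: float = Field(default=30.0, gt=0)
    window_days: int = Field(default=56, gt=0)
    dedup_anchor_mode: str = "retained"
    percentile_method: str = "linear"
    sandwich_flavor: str = "HC0"
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_analysis_frame(summaries: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Join per-participant engagement counts to clinical scale totals."""
    counts = summaries[["participant_id", "total_interactions", "within_count", "between_count"]]
    cols = ["participant_id"] + [c for c in _ANALYSIS_VARS if c in participants.columns]
    merged = participants[cols].merge(counts, on="participant_id", how="left")
    for c in ("total_interactions", "within_count", "between_count"):
        merged[c] = merged[c].fillna(0).astype(int)  # enrolled but never interacted
    return merged


def process_event_frames(
    events: pd.DataFrame,
    unlocks: pd.DataFrame,
    enrollments: pd.Series | dict,
    spec: ProgramSpec | None = None,
    dwell_seconds: float = 5.0,
    dedup_minutes: float = 30.0,
    window_days: int | None = None,
    dedup_anchor: str = "retained",
):
    """In-memory pipeline: events -> attributed interactions.

    Returns ``(attributed, anomalies, report)``; the convenience used by
    scripts and tests that already hold the frames.
    """
    spec = spec or load_default_program()
    window = window_days if window_days is not None else spec.treatment_window_days
    interactions, report = identify_interactions(
        events, spec,
        dwell_threshold=dwell_seconds,
        dedup_window_minutes=dedup_minutes,
        dedup_anchor=dedup_anchor,
    )
    interactions = restrict_to_treatment_window(interactions, enrollments, window_days=window)
    attributed, anomalies = classify_interactions(interactions, unlocks, enrollments)
    return attributed, anomalies, report


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all outputs; returns the report dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = (
        load_program_spec(config.program_spec)
        if config.program_spec
        else load_default_program()
    )
    for path in (config.events, config.unlocks, config.participants):
        if not Path(path).exists():
            raise FileNotFoundError(f"required input missing: {path}")

    events = read_event_log(config.events)
    participants = pd.read_csv(config.participants)
    unlocks = pd.read_csv(config.unlocks)
    enrollments = pd.Series(
        pd.to_datetime(participants["enrollment_date"]).dt.tz_localize("UTC").to_numpy(),
        index=participants["participant_id"],
    )

    interactions, report = identify_interactions(
        events, spec,
        dwell_threshold=config.dwell_seconds,
        dedup_window_minutes=config.dedup_minutes,
        dedup_anchor=config.dedup_anchor_mode,
    )
    interactions = restrict_to_treatment_window(
        interactions, enrollments, window_days=config.window_days
    )
    attributed, anomalies = classify_interactions(interactions, unlocks, enrollments)

    n_modules = spec.n_modules
    summaries = summarize_cohort(attributed, n_modules)
    outputs: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        outputs[name] = path

    save("interactions.csv", interactions)
    save("attributed_interactions.csv", attributed)
    save("anomalies.csv", anomalies)
    save("engagement_summary.csv", summaries)
    if len(summaries):
        save("cohort_summary.csv", cohort_summary(summaries, method=config.percentile_method))
        save("total_interactions_hist.csv", histogram_table(summaries["total_interactions"], 10))
        save("between_count_hist.csv", histogram_table(summaries["between_count"], 2))
    save("module_distribution.csv", module_distribution(attributed, n_modules))
    save("category_breakdown.csv", category_breakdown(attributed).rename_axis("category").reset_index())

    analysis = build_analysis_frame(summaries, participants)
    save("analysis_frame.csv", analysis)
    have_scales = all(v in analysis.columns for v in _ANALYSIS_VARS)
    if have_scales and len(analysis) >= 8:
        save("model_results.csv", run_exploratory_battery(analysis, sandwich=config.sandwich_flavor))
        corr_vars = [
            "total_interactions", "between_count", "within_count",
            "hamd_baseline", "phq9_baseline", "ceq_credibility", "ceq_expectancy",
            "hamd_week8", "phq9_week8", "csq_week8", "offapp_minutes",
        ]
        save("correlation_matrix.csv", spearman_matrix(analysis, corr_vars), index=True)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config.model_dump_json()),
        "program_id": spec.program_id,
        "n_participants": int(len(participants)),
        "n_events": int(len(events)),
        "n_interactions": int(len(interactions)),
        "anomalies": {
            "locked_content": int(len(anomalies)),
            "unknown_content_events": report.n_unknown,
            "duplicate_events": report.duplicate_events,
            "parse_errors": len(report.parse_errors),
        },
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def simulate_fixture(
    out_dir: str | Path,
    config: CohortConfig | None = None,
    spec: ProgramSpec | None = None,
) -> Path:
    """Generate a synthetic cohort fixture directory (events/unlocks/participants)."""
    config = config or CohortConfig()
    spec = spec or load_default_program()
    participants = generate_cohort(config)
    events, unlocks = generate_event_log(participants, spec, config)
    out_dir = Path(out_dir)
    paths = write_fixture(out_dir, participants, events, unlocks, config)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_participants": config.n_participants,
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
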