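"""Descriptive engagement quantities.

Per-participant totals (overall, within-module, between-module), per-module
and per-category breakdowns, and cohort-level medians/IQRs.  The IQR is
reported as the 25th and 75th percentiles computed by linear interpolation
between order statistics (the mainstream statistical-software default);
other numpy percentile conventions can be selected because IQR endpoints on
small cohorts are sensitive to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .program import CATEGORIES

__all__ = [
    "EngagementSummary",
    "summarize_participant",
    "summarize_cohort",
    "module_distribution",
    "cohort_summary",
    "category_breakdown",
    "histogram_table",
]


@dataclass
class EngagementSummary:
    """Interaction counts for one participant (anomalies excluded)."""

    participant_id: str
    total_interactions: int
    within_count: int
    between_count: int
    per_module_within: np.ndarray  # length M, index m-1
    per_module_between: np.ndarray  # last entry structurally 0
    per_category: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "total_interactions": self.total_interactions,
            "within_count": self.within_count,
            "between_count": self.between_count,
        }
        for m, c in enumerate(self.per_module_within, start=1):
            row[f"within_m{m}"] = int(c)
        for m, c in enumerate(self.per_module_between, start=1):
            row[f"between_m{m}"] = int(c)
        for cat in CATEGORIES:
            row[f"n_{cat}"] = self.per_category.get(cat, 0)
        return row


def summarize_participant(attributed: pd.DataFrame, n_modules: int) -> EngagementSummary:
    """Count one participant's interactions by attribution, module, category."""
    pids = attributed["participant_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"expected a single participant, got {list(pids)}")
    pid = str(pids[0]) if len(pids) else ""
    within = attributed[attributed["attribution"] == "within"]
    between = attributed[attributed["attribution"] == "between"]
    pm_within = np.zeros(n_modules, dtype=int)
    pm_between = np.zeros(n_modules, dtype=int)
    for df, vec in ((within, pm_within), (between, pm_between)):
        counts = df["module_index"].value_counts()
        for m, c in counts.items():
            vec[int(m) - 1] = int(c)
    per_cat = {cat: 0 for cat in CATEGORIES}
    per_cat.update(attributed["category"].value_counts().to_dict())
    return EngagementSummary(
        participant_id=pid,
        total_interactions=len(attributed),
        within_count=len(within),
        between_count=len(between),
        per_module_within=pm_within,
        per_module_between=pm_between,
        per_category=per_cat,
    )


def summarize_cohort(attributed: pd.DataFrame, n_modules: int) -> pd.DataFrame:
    """Per-participant engagement summaries as one row per participant."""
    rows = [
        summarize_participant(grp, n_modules).as_row()
        for _, grp in attributed.groupby("participant_id", sort=True)
    ]
    cols = EngagementSummary("", 0, 0, 0, np.zeros(n_modules, int), np.zeros(n_modules, int)).as_row()
    return pd.DataFrame(rows, columns=list(cols))


def module_distribution(attributed: pd.DataFrame, n_modules: int) -> pd.DataFrame:
    """Interaction counts by content module with cohort-level percentages.

    Percentages are reported rounded to one decimal; the unrounded
    fraction is kept in the ``fraction`` column.
    """
    counts = np.zeros(n_modules, dtype=int)
    vc = attributed["module_index"].value_counts()
    for m, c in vc.items():
        counts[int(m) - 1] = int(c)
    total = counts.sum()
    frac = counts / total if total else np.zeros(n_modules)
    return pd.DataFrame(
        {
            "module_index": np.arange(1, n_modules + 1),
            "n_interactions": counts,
            "fraction": frac,
            "percent": np.round(100 * frac, 1),
        }
    )


def percentile(values, q, method: str = "linear") -> float:
    """Percentile with an explicit, configurable convention."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method=method))


def cohort_summary(summaries: pd.DataFrame, method: str = "linear") -> pd.DataFrame:
    """Cohort medians, IQRs (25th/75th percentiles), ranges and modes.

    One row per count variable (total, within, between).  The mode is
    most informative for the between-module count, whose distribution is
    zero-heavy ("median, mode, IQR" is the natural summary there).
    """
    if summaries.empty:
        raise ValueError("cohort_summary requires at least one participant summary")
    rows = []
    for var in ("total_interactions", "within_count", "between_count"):
        x = summaries[var].to_numpy(dtype=float)
        counts = pd.Series(x).value_counts()
        mode = counts.index[counts.to_numpy() == counts.max()].min()
        rows.append(
            {
                "variable": var,
                "n": len(x),
                "median": percentile(x, 50, method),
                "iqr_25": percentile(x, 25, method),
                "iqr_75": percentile(x, 75, method),
                "min": float(x.min()),
                "max": float(x.max()),
                "mode": float(mode),
            }
        )
    return pd.DataFrame(rows)


def category_breakdown(attributed: pd.DataFrame) -> pd.Series:
    """Interaction counts per content category; sums to the total."""
    counts = attributed["category"].value_counts()
    return pd.Series({cat: int(counts.get(cat, 0)) for cat in CATEGORIES}, name="n_interactions")


def histogram_table(values, bin_width: int = 10, start: int = 0) -> pd.DataFrame:
    """Plain tabular histogram (bin_low, bin_high, count) for report files."""
    x = np.asarray(values, dtype=float)
    hi = start + bin_width * max(1, int(np.ceil((x.max() - start + 1) / bin_width))) if len(x) else start + bin_width
    edges = np.arange(start, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
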