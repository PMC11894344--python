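# modengage

Engagement analytics for module-structured smartphone mental-health
interventions.

Trials of app-delivered CBT passively log every tap a participant makes,
but raw event counts are a poor measure of engagement: a 2-second errant
tap is not a skills review, and 26 activity logs entered in one sitting
are one practice session, not 26. `modengage` turns raw event logs from a
sequential-module program (modules unlock one at a time as completion
requirements are met) into *retained interactions*, attributes each one to
the participant's treatment stage, and asks the question frequency counts
cannot answer: is the participant working **within** their current module,
or **revisiting** content from an earlier stage — and does either pattern
relate to clinical outcomes?

It is a library for methodologists and trialists analysing digital
mental-health usage data, with a synthetic-data generator so every stage
runs, end to end, without access to any trial's raw logs.

## What it computes

**Interaction identification** (two a-priori rules):

* *errant-open rule* — a content open counts only if the content or app
  was not closed again in under 5 seconds (dwell exactly 5 s counts; an
  open with no close signal counts; completion is not required);
* *logging deduplication* — a logging submission counts only if it is at
  least 30 minutes after the most recently retained submission of the same
  logging type, so a burst of 26 logs yields 1 interaction.

**Module attribution.** A participant's *stage* at time *t* is the latest
unlocked module (stage boundaries at 00:00 UTC of the unlock date,
intervals half-open).  An interaction with content of module *m* at stage
*s* is *within-module* if *m = s*, a *between-module revisit* if *m < s*,
and a reported anomaly if *m > s* (locked content).

**Engagement descriptives.** Per-participant totals, per-module and
per-category partitions (which always conserve: within + between +
anomalies = total), cohort medians and 25th/75th-percentile IQRs.

**Exploratory battery.** 27 univariate models with a shared
Benjamini–Hochberg FDR correction:

* 21 quasi-Poisson regressions `count ~ predictor` with HC0 sandwich
  robust SEs — log link, dispersion φ = Pearson χ²/(n−p), rate ratio
  exp(b) — for 7 grand-mean-centered predictors (age, baseline PHQ-9 and
  HAM-D, CEQ credibility and expectancy, week-8 CSQ, ln(1+minutes) of
  off-app practice) × 3 outcomes (total, within, between counts);
* 6 residual-change models `week8 ~ baseline + count` by Huber robust
  regression (c = 1.345, MAD scale), the count coefficient estimating the
  association with symptom change.

Also included: Spearman correlations with t-approximation p-values and
McDonald's ω_t from a single-factor maximum-likelihood fit.

## Worked example

```bash
python examples/filter_event_log.py
```

builds one participant's morning — an errant 3-second tap, a 4-minute
read, a burst of 26 scheduling logs, and one more log that evening — and
prints:

```
raw events:            31
retained interactions: 3
                timestamp                 content_id category       source
2023-01-09 09:10:00+00:00 m1_psychoeducation_reading learning content_view
2023-01-09 10:00:00+00:00       m3_schedule_activity  logging          log
2023-01-09 19:00:00+00:00       m3_schedule_activity  logging          log
```

The errant tap is dropped, the burst collapses to a single scheduling
interaction, and the evening log — more than 30 minutes later — counts as
a separate attempt to integrate the app into daily life.

Running the full pipeline on a simulated 26-participant cohort
(`python examples/engagement_summaries.py`) prints cohort descriptives
such as

```
          variable  n  median  iqr_25  iqr_75  min  max  mode
total_interactions 26    70.0   65.00    81.5  5.0 95.0  65.0
      within_count 26    65.5   62.25    76.0  5.0 94.0  62.0
     between_count 26     3.0    2.00     4.0  0.0  9.0   2.0
```

— within-module medians just above the 62 interactions the program
requires, and rare, right-skewed revisit counts.  See
`examples/simulate_cohort.py` and `examples/exploratory_battery.py` for
the generator and the model battery (the latter prints the fitted
log-rate-ratios next to the generator's planted values).

A thin CLI wraps the same pipeline for shell use:

```bash
modengage simulate --out fixture --seed 1
modengage analyze --events fixture/events.jsonl --unlocks fixture/unlocks.csv \
    --participants fixture/participants.csv --out report
modengage demo --out demo_run --seed 1     # both steps at once
```

All thresholds (`--dwell-seconds`, `--dedup-minutes`, `--window-days`,
`--dedup-anchor`) are exposed so sensitivity analyses are a loop.

## Layout

```
src/modengage/
  program.py      program structure, default spec, minimum completion path
  events.py       event-log reading, dwell spans, the two filtering rules
  attribution.py  stage timelines, within/between classification
  metrics.py      engagement summaries and cohort descriptives
  stats.py        quasi-Poisson + sandwich, Huber residual change, BH, omega
  synth.py        seeded synthetic cohorts, event logs, fixtures
  pipeline.py     end-to-end orchestration and report writing
  cli.py          thin click wrapper (simulate / analyze / demo)
docs/methods.md   model and generator documentation
examples/         one narrative script per capability
```
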