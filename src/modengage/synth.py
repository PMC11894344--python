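"""Synthetic cohorts with the statistical structure the analysis assumes.

Nothing from the trial's raw logs is deposited publicly, so this module
generates stand-in data end to end: participant clinical scales at item
level, raw app event logs (including sub-5-second errant opens and logging
bursts), and module-unlock trajectories.  Every quantity the pipeline or
the model battery consumes can be produced at any cohort size from a single
seed.

Item scores come from a single-factor normal model discretized by
thresholds.  Because omega_t is defined under a factor model, the factor
structure is the natural generating assumption; the latent loading is
calibrated so that the *discretized* items hit the target omega, using the
exact Hermite (Mehler) series for the covariance of thresholded bivariate
normals.  Week-8 scores are driven by a target total — baseline carry-over
plus a configurable engagement effect (default 0.23 PHQ-9 points per
between-module revisit) — mapped onto the factor through the exact inverse
of E[scale sum | factor], so planted regression slopes are unattenuated.

Between-module revisit counts are Poisson with a log-linear rate in age and
treatment credibility (default log rate ratios ln(1.07) per year and
ln(1.19) per credibility unit); mixing over participants makes the marginal
counts overdispersed, as the analysis assumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats as sps
from scipy.optimize import brentq

from .program import ProgramSpec, load_default_program
from .stats import omega_from_corr

__all__ = [
    "CohortConfig",
    "SCALES",
    "ScaleDef",
    "generate_cohort",
    "generate_event_log",
    "sample_scale",
    "minimal_player_log",
    "planned_analysis_frame",
    "write_fixture",
    "read_fixture",
]

# ---------------------------------------------------------------------------
# configuration


class CohortConfig(BaseModel):
    """Generator settings; defaults are the study conditions being emulated.

    Scale reliability targets, the cohort size of 26, the 8-week window,
    and the planted engagement effects (ln 1.07 per year of age and
    ln 1.19 per credibility unit on the revisit rate; 0.23 week-8 PHQ-9
    points per revisit) correspond to the trial-level quantities the
    analysis reports; remaining rates describe realistic app-usage texture
    (errant-open frequency, logging-burst sizes, early-heavy session decay)
    that the trial does not publish.
    """

    n_participants: int = Field(default=26, ge=2)
    seed: int = 0
    enrollment_span_days: int = Field(default=14, ge=0)
    mean_sessions_per_week: float = Field(default=4.0, gt=0)
    errant_open_rate: float = Field(default=0.08, ge=0.0, le=1.0)
    burst_size_distribution: dict[int, float] = Field(
        default_factory=lambda: {1: 0.85, 2: 0.06, 3: 0.04, 5: 0.03, 10: 0.02}
    )
    revisit_rate_base: float = Field(default=2.0, ge=0.0)
    effect_age_on_revisits: float = math.log(1.07)
    effect_credibility_on_revisits: float = math.log(1.19)
    effect_revisits_on_week8_phq9: float = 0.23
    scale_reliabilities: dict[str, float] = Field(
        default_factory=lambda: {
            "hamd_baseline": 0.77,
            "phq9_baseline": 0.83,
            "ceq_credibility": 0.68,
            "ceq_expectancy": 0.84,
            "hamd_week8": 0.87,
            "phq9_week8": 0.93,
            "csq_week8": 0.93,
        }
    )
    dropout_probability: float = Field(default=2.0 / 26.0, ge=0.0, le=1.0)
    mean_extra_within: float = Field(default=10.0, ge=0.0)
    session_decay_per_day: float = Field(default=0.02, ge=0.0)
    baseline_effect_phq9: float = 0.35
    baseline_effect_hamd: float = 0.40
    factor_correlations: dict[str, float] = Field(
        default_factory=lambda: {
            "phq9_baseline:hamd_baseline": 0.5,
            "ceq_credibility:ceq_expectancy": 0.34,
        }
    )

    @field_validator("burst_size_distribution")
    @classmethod
    def _check_burst(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("burst_size_distribution must be non-empty")
        if any(size < 1 for size in v):
            raise ValueError("burst sizes must be positive integers")
        if any(p < 0 for p in v.values()) or not math.isclose(sum(v.values()), 1.0, abs_tol=1e-6):
            raise ValueError("burst size probabilities must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _check_reliabilities(self) -> "CohortConfig":
        for name, omega in self.scale_reliabilities.items():
            if name not in SCALES:
                raise ValueError(f"unknown scale {name!r}")
            if not 0.0 < omega < 1.0:
                raise ValueError(f"reliability for {name!r} must lie in (0, 1)")
            _calibrated_loading(name, omega)  # raises if infeasible
        return self


# ---------------------------------------------------------------------------
# ordinal item machinery


@dataclass(frozen=True)
class ScaleDef:
    """Layout of one clinical scale: groups of (n_items, n_levels, offset)."""

    name: str
    groups: tuple[tuple[int, int, int], ...]
    mean_frac: float  # target item mean as a fraction of the item range
    n_score_items: int  # leading items summed into the reported total

    @property
    def n_items(self) -> int:
        return sum(g[0] for g in self.groups)

    def item_levels(self) -> list[tuple[int, int]]:
        """Per-item (n_levels, offset) in order."""
        out = []
        for n, levels, off in self.groups:
            out.extend([(levels, off)] * n)
        return out

    def score_range(self) -> tuple[int, int]:
        lo = hi = 0
        for levels, off in self.item_levels()[: self.n_score_items]:
            lo += off
            hi += off + levels - 1
        return lo, hi


# Trial scale layouts: PHQ-9 (9 items 0-3), HAM-D (21 items on mixed 5- and
# 3-point scales, first 17 summed, total range 0-52), CEQ subscales (3 items,
# subscale range 3-27), CSQ (8 items, range 8-32).  Mean fractions place the
# expected totals at the reported cohort means.
SCALES: dict[str, ScaleDef] = {
    "phq9_baseline": ScaleDef("phq9_baseline", ((9, 4, 0),), 15.35 / 27.0, 9),
    "phq9_week8": ScaleDef("phq9_week8", ((9, 4, 0),), 6.79 / 27.0, 9),
    "hamd_baseline": ScaleDef("hamd_baseline", ((9, 5, 0), (12, 3, 0)), 19.54 / 52.0, 17),
    "hamd_week8": ScaleDef("hamd_week8", ((9, 5, 0), (12, 3, 0)), 10.88 / 52.0, 17),
    "ceq_credibility": ScaleDef("ceq_credibility", ((3, 9, 1),), (18.88 / 3 - 1) / 8.0, 3),
    "ceq_expectancy": ScaleDef("ceq_expectancy", ((3, 9, 1),), (13.97 / 3 - 1) / 8.0, 3),
    "csq_week8": ScaleDef("csq_week8", ((8, 4, 1),), (27.58 / 8 - 1) / 3.0, 8),
}

_HERMITE_ORDER = 20


def _thresholds(levels: int, mean_frac: float) -> np.ndarray:
    """Latent N(0,1) cut points giving Binomial(levels-1, mean_frac) categories."""
    probs = sps.binom.pmf(np.arange(levels), levels - 1, mean_frac)
    cum = np.clip(np.cumsum(probs)[:-1], 1e-6, 1 - 1e-6)
    return sps.norm.ppf(cum)


def _hermite_at(t: np.ndarray, n_max: int) -> np.ndarray:
    """Probabilists' Hermite polynomials He_0..He_{n_max-1} at points t."""
    H = np.zeros((n_max, len(t)))
    H[0] = 1.0
    if n_max > 1:
        H[1] = t
    for n in range(1, n_max - 1):
        H[n + 1] = t * H[n] - n * H[n - 1]
    return H


def _disc_coeffs(thresholds: np.ndarray) -> tuple[np.ndarray, float]:
    """Hermite expansion coefficients and variance of the thresholded score.

    The integer score is offset + sum_k 1(X > t_k), whose n-th Hermite
    coefficient is ``c_n = sum_k He_{n-1}(t_k) phi(t_k)``; for two standard
    normals with correlation rho the score covariance is exactly
    ``sum_n rho^n c_n^2 / n!`` (Mehler expansion).
    """
    phi = sps.norm.pdf(thresholds)
    H = _hermite_at(thresholds, _HERMITE_ORDER)
    c = np.array([np.sum(H[n - 1] * phi) for n in range(1, _HERMITE_ORDER + 1)])
    upper = np.concatenate([sps.norm.cdf(thresholds), [1.0]])
    probs = np.diff(np.concatenate([[0.0], upper]))
    vals = np.arange(len(probs), dtype=float)
    var = float(probs @ vals**2 - (probs @ vals) ** 2)
    return c, var


_FACTORIALS = np.array([math.factorial(k) for k in range(1, _HERMITE_ORDER + 1)], dtype=float)


def _disc_corr(rho: float, ci: np.ndarray, vi: float, cj: np.ndarray, vj: float) -> float:
    n = np.arange(1, _HERMITE_ORDER + 1)
    cov = np.sum(rho**n * ci * cj / _FACTORIALS)
    return float(cov / math.sqrt(vi * vj))


_loading_cache: dict[tuple, float] = {}


def _calibrated_loading(scale_name: str, omega_target: float) -> float:
    """Latent loading such that the discretized items hit the omega target."""
    key = (scale_name, round(omega_target, 6))
    if key in _loading_cache:
        return _loading_cache[key]
    sdef = SCALES[scale_name]
    levels = sdef.item_levels()[: sdef.n_score_items]
    coeffs = [_disc_coeffs(_thresholds(lv, sdef.mean_frac)) for lv, _ in levels]

    def implied_omega(lam: float) -> float:
        rho = lam * lam
        k = len(levels)
        R = np.eye(k)
        for i in range(k):
            for j in range(i):
                r = _disc_corr(rho, coeffs[i][0], coeffs[i][1], coeffs[j][0], coeffs[j][1])
                R[i, j] = R[j, i] = r
        return omega_from_corr(R)

    lo, hi = 0.05, 0.995
    f_lo, f_hi = implied_omega(lo) - omega_target, implied_omega(hi) - omega_target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"infeasible reliability {omega_target} for scale {scale_name!r} "
            f"(attainable range ~[{f_lo + omega_target:.3f}, {f_hi + omega_target:.3f}])"
        )
    lam = float(brentq(lambda L: implied_omega(L) - omega_target, lo, hi, xtol=1e-6))
    _loading_cache[key] = lam
    return lam


def _discretize(x: np.ndarray, thresholds: np.ndarray, offset: int) -> np.ndarray:
    return offset + np.sum(x[..., None] > thresholds, axis=-1)


def _sample_items(
    rng: np.random.Generator, sdef: ScaleDef, lam: float, f: np.ndarray
) -> np.ndarray:
    """Item matrix given factor scores f (one per row)."""
    n = len(f)
    cols = []
    s1 = math.sqrt(max(1.0 - lam * lam, 1e-12))
    for levels, offset in sdef.item_levels():
        thr = _thresholds(levels, sdef.mean_frac)
        x = lam * f + s1 * rng.standard_normal(n)
        cols.append(_discretize(x, thr, offset))
    return np.column_stack(cols)


def sample_scale(
    name: str,
    n: int,
    rng: np.random.Generator,
    omega: float | None = None,
    f: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an n x k integer item matrix for a named scale.

    ``omega`` defaults to the scale's study-condition reliability target;
    ``f`` supplies factor scores (defaults to standard normal draws).
    """
    sdef = SCALES[name]
    if omega is None:
        omega = CohortConfig().scale_reliabilities[name]
    lam = _calibrated_loading(name, omega)
    if f is None:
        f = rng.standard_normal(n)
    return _sample_items(rng, sdef, lam, f)


def _sum_given_f_grid(sdef: ScaleDef, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact E[scale total | factor] on a grid, for inverting totals."""
    s1 = math.sqrt(max(1.0 - lam * lam, 1e-12))
    fgrid = np.linspace(-6.0, 6.0, 481)
    esum = np.zeros_like(fgrid)
    for levels, offset in sdef.item_levels()[: sdef.n_score_items]:
        thr = _thresholds(levels, sdef.mean_frac)
        esum += offset + np.sum(
            sps.norm.cdf((lam * fgrid[:, None] - thr[None, :]) / s1), axis=1
        )
    return fgrid, esum


def _factor_for_totals(sdef: ScaleDef, lam: float, totals: np.ndarray) -> np.ndarray:
    fgrid, esum = _sum_given_f_grid(sdef, lam)
    return np.interp(np.clip(totals, esum[0], esum[-1]), esum, fgrid)


def _sum_slope(sdef: ScaleDef, lam: float) -> float:
    """d E[scale total]/d factor at the center, via the same grid."""
    fgrid, esum = _sum_given_f_grid(sdef, lam)
    i = len(fgrid) // 2
    return float((esum[i + 1] - esum[i - 1]) / (fgrid[i + 1] - fgrid[i - 1]))


# ---------------------------------------------------------------------------
# cohort generation

_POP_MEAN_AGE = 33.69
_POP_SD_AGE = 11.22
_POP_MEAN_CRED = 18.88


def _score(items: np.ndarray, sdef: ScaleDef) -> np.ndarray:
    return items[:, : sdef.n_score_items].sum(axis=1)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """One row per participant: demographics, item-level scales, planned use.

    Deterministic given the config (all randomness flows from its seed).
    ``planned_between`` (revisit counts) follow the configured log-linear
    rate in age and credibility; week-8 PHQ-9 totals embed the configured
    per-revisit effect after baseline carry-over.  Columns ``planned_*``
    are simulation ground truth used when plotting or when running the
    model battery without simulating raw event logs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_participants
    rel = config.scale_reliabilities

    ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    age = np.clip(rng.normal(_POP_MEAN_AGE, _POP_SD_AGE, n), 18.0, 80.0).round(1)
    base_date = pd.Timestamp("2023-01-02", tz="UTC")
    enroll_offset = (
        rng.integers(0, config.enrollment_span_days + 1, n)
        if config.enrollment_span_days
        else np.zeros(n, dtype=int)
    )
    enrollment = np.array([base_date + pd.Timedelta(days=int(d)) for d in enroll_offset])

    # correlated baseline factors
    r_dep = config.factor_correlations.get("phq9_baseline:hamd_baseline", 0.0)
    r_ceq = config.factor_correlations.get("ceq_credibility:ceq_expectancy", 0.0)
    z = rng.standard_normal((n, 4))
    f_phq = z[:, 0]
    f_ham = r_dep * z[:, 0] + math.sqrt(1 - r_dep**2) * z[:, 1]
    f_cred = z[:, 2]
    f_exp = r_ceq * z[:, 2] + math.sqrt(1 - r_ceq**2) * z[:, 3]

    items: dict[str, np.ndarray] = {}
    for name, f in (
        ("phq9_baseline", f_phq),
        ("hamd_baseline", f_ham),
        ("ceq_credibility", f_cred),
        ("ceq_expectancy", f_exp),
    ):
        items[name] = _sample_items(rng, SCALES[name], _calibrated_loading(name, rel[name]), f)

    phq_b = _score(items["phq9_baseline"], SCALES["phq9_baseline"])
    ham_b = _score(items["hamd_baseline"], SCALES["hamd_baseline"])
    cred = _score(items["ceq_credibility"], SCALES["ceq_credibility"])
    expt = _score(items["ceq_expectancy"], SCALES["ceq_expectancy"])

    # planned engagement counts
    log_rate = (
        np.log(max(config.revisit_rate_base, 1e-12))
        + config.effect_age_on_revisits * (age - _POP_MEAN_AGE)
        + config.effect_credibility_on_revisits * (cred - _POP_MEAN_CRED)
    )
    planned_between = (
        rng.poisson(np.exp(np.clip(log_rate, -30, 8)))
        if config.revisit_rate_base > 0
        else np.zeros(n, dtype=int)
    )
    dropped = rng.random(n) < config.dropout_probability
    dropout_day = np.where(dropped, rng.integers(3, 42, n), -1)
    if config.mean_extra_within > 0:
        # heavy-tailed gamma mixing so counts are overdispersed, as observed
        lam_extra = rng.gamma(0.8, config.mean_extra_within / 0.8, n)
        extras = rng.poisson(lam_extra)
    else:
        extras = np.zeros(n, dtype=int)
    planned_within = np.where(
        dropped, np.maximum((62 * dropout_day / 56.0).astype(int), 1), 62 + extras
    )
    planned_extra = np.where(dropped, 0, extras)

    # week-8 scales: target totals with baseline carry-over and planted effect
    def week8_totals(name: str, mu: float, b_base, baseline, effect, usage):
        sdef = SCALES[name]
        lam = _calibrated_loading(name, rel[name])
        slope = _sum_slope(sdef, lam)
        explained = b_base**2 * np.var(baseline) + effect**2 * np.var(usage)
        sd_eps = math.sqrt(max(slope**2 - explained, 1.0))
        T = (
            mu
            + b_base * (baseline - baseline.mean())
            + effect * usage
            + rng.normal(0.0, sd_eps, n)
        )
        f = _factor_for_totals(sdef, lam, T)
        return _sample_items(rng, sdef, lam, f)

    items["phq9_week8"] = week8_totals(
        "phq9_week8", 6.79, config.baseline_effect_phq9, phq_b,
        config.effect_revisits_on_week8_phq9, planned_between,
    )
    items["hamd_week8"] = week8_totals(
        "hamd_week8", 10.88, config.baseline_effect_hamd, ham_b, 0.0, planned_between
    )
    items["csq_week8"] = _sample_items(
        rng, SCALES["csq_week8"], _calibrated_loading("csq_week8", rel["csq_week8"]),
        rng.standard_normal(n),
    )

    offapp = np.round(rng.lognormal(math.log(35.0), 0.6, n)).astype(int)

    data: dict[str, object] = {
        "participant_id": ids,
        "age": age,
        "enrollment_date": [ts.date().isoformat() for ts in enrollment],
        "completed_trial": ~dropped,
        "dropout_day": dropout_day,
        "planned_within": planned_within,
        "planned_between": planned_between,
        "planned_extra": planned_extra,
        "platform": rng.choice(["ios", "android"], n),
    }
    prefixes = {
        "phq9_baseline": "phq9_b", "phq9_week8": "phq9_w8",
        "hamd_baseline": "hamd_b", "hamd_week8": "hamd_w8",
        "ceq_credibility": "ceq_cred", "ceq_expectancy": "ceq_exp",
        "csq_week8": "csq_w8",
    }
    for name, pref in prefixes.items():
        mat = items[name].astype(float)
        if name in ("phq9_week8", "hamd_week8", "csq_week8"):
            mat[dropped] = np.nan  # lost to follow-up: no week-8 assessment
        for j in range(mat.shape[1]):
            data[f"{pref}_i{j + 1}"] = mat[:, j]
    df = pd.DataFrame(data)
    for name, pref in prefixes.items():
        sdef = SCALES[name]
        cols = [f"{pref}_i{j + 1}" for j in range(sdef.n_score_items)]
        df[name] = df[cols].sum(axis=1, skipna=False)
    df["offapp_minutes"] = np.where(dropped, np.nan, offapp.astype(float))
    return df


def planned_analysis_frame(participants: pd.DataFrame) -> pd.DataFrame:
    """Model-battery input built from planned (ground-truth) usage counts."""
    out = participants[
        [
            "participant_id", "age", "phq9_baseline", "hamd_baseline",
            "ceq_credibility", "ceq_expectancy", "csq_week8",
            "offapp_minutes", "phq9_week8", "hamd_week8",
        ]
    ].copy()
    out["within_count"] = participants["planned_within"]
    out["between_count"] = participants["planned_between"]
    out["total_interactions"] = out["within_count"] + out["between_count"]
    return out


# ---------------------------------------------------------------------------
# event-log generation

_SECONDS = pd.Timedelta(seconds=1)


def _required_sequence(spec: ProgramSpec) -> list[list]:
    """Per module, the expanded list of required item completions."""
    seq = []
    for mod in spec.modules:
        reqs = []
        for item in mod.items:
            reqs.extend([item] * item.required_completions)
        seq.append(reqs)
    return seq


def generate_event_log(
    participants: pd.DataFrame, spec: ProgramSpec, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw events and unlock records for a generated cohort.

    Each participant works through the required completions module by
    module (module m during week m), unlocking the next module the day
    after requirements are met; optional extra within-module interactions
    and between-module revisits are laid on an early-heavy session-day
    process; errant opens (< 5 s dwell) and logging bursts are injected at
    the configured rates.  Deterministic given the config seed.
    """
    window = spec.treatment_window_days
    required = _required_sequence(spec)
    week_len = window / len(spec.modules)
    children = np.random.SeedSequence([int(config.seed), 1]).spawn(len(participants))
    all_events: list[tuple] = []
    all_unlocks: list[tuple] = []

    for (row, ss) in zip(participants.itertuples(index=False), children):
        rng = np.random.default_rng(ss)
        pid = row.participant_id
        platform = getattr(row, "platform", "ios")
        enroll = pd.Timestamp(row.enrollment_date, tz="UTC")
        end_day = float(row.dropout_day) if row.dropout_day and row.dropout_day > 0 else float(window)
        events: list[tuple] = []

        def emit(day: float, action: str, content_id: str | None, element: str | None = None):
            ts = enroll + pd.Timedelta(days=day)
            events.append((pid, ts, element or (content_id or "app"), action, content_id, platform))

        def emit_content(day: float, item) -> None:
            if rng.random() < config.errant_open_rate:
                # an errant tap shortly before the real engagement
                e0 = day - 120.0 / 86400.0
                emit(e0, "content_open", item.content_id)
                emit(e0 + rng.uniform(0.5, 4.5) / 86400.0, "content_close", item.content_id)
            if rng.random() < 0.10:
                emit(day - 60.0 / 86400.0, "app_open", None)
            dwell = rng.uniform(20.0, 300.0) / 86400.0
            emit(day, "content_open", item.content_id)
            if item.category == "practice" and rng.random() < 0.7:
                emit(day + dwell * 0.9, "exercise_complete", item.content_id)
            u = rng.random()
            if u < 0.03:
                pass  # no close signal: app killed, dwell undefined
            elif u < 0.08:
                emit(day + dwell, "app_pause", None)
            elif u < 0.13:
                emit(day + dwell, "app_close", None)
            else:
                emit(day + dwell, "content_close", item.content_id)

        def emit_logging(day: float, item) -> None:
            emit(day, "log_submit", item.content_id)
            sizes = np.array(sorted(config.burst_size_distribution))
            probs = np.array([config.burst_size_distribution[s] for s in sizes])
            burst = int(rng.choice(sizes, p=probs))
            for off in np.sort(rng.uniform(1.0, 25.0, burst - 1)):
                emit(day + off / 1440.0, "log_submit", item.content_id)

        # required progression, module m during week m
        unlock_days: list[float] = [0.0]  # module 1 open at enrollment
        truncated = False
        for m, reqs in enumerate(required, start=1):
            if truncated or not reqs:
                if not truncated and m < len(required):
                    unlock_days.append(unlock_days[-1])  # empty module: next opens same day
                    all_unlocks.append((pid, m + 1, (enroll + pd.Timedelta(days=unlock_days[-1])).date()))
                continue
            base = week_len * (m - 1)
            slots = base + week_len * (np.arange(1, len(reqs) + 1)) / (len(reqs) + 1)
            last_day = None
            for day, item in zip(slots, reqs):
                if day >= end_day:
                    truncated = True
                    break
                if item.category == "logging":
                    emit_logging(day, item)
                else:
                    emit_content(day, item)
                last_day = day
            if truncated or last_day is None:
                truncated = True
                continue
            if m < len(required):
                unlock = math.floor(last_day) + 1.0
                if unlock >= end_day:
                    truncated = True
                    continue
                unlock_days.append(unlock)
                all_unlocks.append((pid, m + 1, (enroll + pd.Timedelta(days=unlock)).date()))

        unlock_arr = np.array(unlock_days)

        def stage_at(day: float) -> int:
            return int(np.searchsorted(unlock_arr, day, side="right"))

        # early-heavy session days for optional use
        day_grid = np.arange(0, int(math.ceil(end_day)))
        p_active = np.minimum(
            1.0,
            (config.mean_sessions_per_week / 7.0)
            * np.exp(-config.session_decay_per_day * day_grid),
        )
        active_days = day_grid[rng.random(len(day_grid)) < p_active]
        if active_days.size == 0:
            active_days = np.array([max(0, int(end_day) // 2)])

        def pick_day(min_day: float) -> float:
            pool = active_days[active_days >= min_day]
            base_day = float(rng.choice(pool)) if pool.size else min_day
            return base_day + rng.uniform(8.0, 22.0) / 24.0

        # extra within-module interactions (non-logging, current stage)
        for _ in range(int(getattr(row, "planned_extra", 0))):
            day = pick_day(0.0)
            if day >= end_day:
                continue
            mod = spec.module(stage_at(day))
            pool = [it for it in mod.items if it.category != "logging"]
            if not pool:
                continue
            emit_content(day, pool[int(rng.integers(len(pool)))])

        # between-module revisits, skewed toward module 1 content
        if len(unlock_arr) > 1:
            for _ in range(int(row.planned_between)):
                day = pick_day(unlock_arr[1])
                if day >= end_day:
                    day = unlock_arr[1] + rng.uniform(0.3, max(end_day - unlock_arr[1] - 0.05, 0.4))
                    if day >= end_day:
                        continue
                s = stage_at(day)
                if s < 2:
                    continue
                prior = np.arange(1, s)
                if prior.size == 1:
                    target = 1
                else:
                    w = np.full(prior.size, 0.25 / (prior.size - 1))
                    w[0] = 0.75
                    target = int(rng.choice(prior, p=w))
                pool = [it for it in spec.module(target).items if it.category != "logging"]
                if not pool:
                    continue
                emit_content(day, pool[int(rng.integers(len(pool)))])

        all_events.extend(events)

    events_df = pd.DataFrame(
        all_events,
        columns=["participant_id", "timestamp", "element", "action", "content_id", "platform"],
    )
    if len(events_df):
        events_df = events_df.sort_values(
            ["participant_id", "timestamp"], kind="stable"
        ).reset_index(drop=True)
    unlocks_df = pd.DataFrame(
        all_unlocks, columns=["participant_id", "module_index", "unlock_date"]
    )
    return events_df, unlocks_df


def minimal_player_log(
    spec: ProgramSpec | None = None,
    enrollment: str = "2023-01-02",
    participant_id: str = "MINIMAL",
    missing_close_every: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic event log of a player doing exactly the required work.

    Performs each required completion once, in module order, with 60-second
    dwells and no errant opens, bursts, or revisits; the retained
    interaction count therefore equals the program's minimum completion
    path.  ``missing_close_every`` drops the close signal of every k-th
    content open (dwell undefined), which must not change the count.
    Returns (events, unlocks, enrollments-map).
    """
    spec = spec or load_default_program()
    enroll = pd.Timestamp(enrollment, tz="UTC")
    window = spec.treatment_window_days
    week_len = window / len(spec.modules)
    events: list[tuple] = []
    unlocks: list[tuple] = []
    n_opens = 0
    for m, reqs in enumerate(_required_sequence(spec), start=1):
        base = week_len * (m - 1)
        slots = base + week_len * np.arange(1, len(reqs) + 1) / (len(reqs) + 1)
        for day, item in zip(slots, reqs):
            ts = enroll + pd.Timedelta(days=float(day))
            if item.category == "logging":
                events.append((participant_id, ts, item.content_id, "log_submit", item.content_id, "ios"))
            else:
                n_opens += 1
                events.append((participant_id, ts, item.content_id, "content_open", item.content_id, "ios"))
                if not (missing_close_every and n_opens % missing_close_every == 0):
                    events.append(
                        (participant_id, ts + 60 * _SECONDS, item.content_id,
                         "content_close", item.content_id, "ios")
                    )
        if m < len(spec.modules):
            last = float(slots[-1]) if len(slots) else week_len * m - 1
            unlocks.append((participant_id, m + 1, (enroll + pd.Timedelta(days=math.floor(last) + 1)).date()))
    events_df = pd.DataFrame(
        events, columns=["participant_id", "timestamp", "element", "action", "content_id", "platform"]
    ).sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    unlocks_df = pd.DataFrame(unlocks, columns=["participant_id", "module_index", "unlock_date"])
    return events_df, unlocks_df, {participant_id: enroll}


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    directory: str | Path,
    participants: pd.DataFrame,
    events: pd.DataFrame,
    unlocks: pd.DataFrame,
    config: CohortConfig,
) -> dict[str, Path]:
    """Write events.jsonl, unlocks.csv, participants.csv and a config snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": directory / "events.jsonl",
        "unlocks": directory / "unlocks.csv",
        "participants": directory / "participants.csv",
        "config": directory / "cohort_config.json",
    }
    with open(paths["events"], "w") as fh:
        for rec in events.itertuples(index=False):
            fh.write(
                json.dumps(
                    {
                        "participant_id": rec.participant_id,
                        "timestamp": pd.Timestamp(rec.timestamp).isoformat(),
                        "element": rec.element,
                        "action": rec.action,
                        "content_id": rec.content_id,
                        "platform": rec.platform,
                    }
                )
                + "\n"
            )
    unlocks.to_csv(paths["unlocks"], index=False)
    participants.to_csv(paths["participants"], index=False)
    paths["config"].write_text(config.model_dump_json(indent=2))
    return paths


def read_fixture(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortConfig]:
    """Read a fixture directory back; inverse of :func:`write_fixture`."""
    from .events import read_event_log

    directory = Path(directory)
    events = read_event_log(directory / "events.jsonl")
    unlocks = pd.read_csv(directory / "unlocks.csv")
    if len(unlocks):
        unlocks["unlock_date"] = pd.to_datetime(unlocks["unlock_date"]).dt.date
    participants = pd.read_csv(directory / "participants.csv")
    config = CohortConfig.model_validate_json((directory / "cohort_config.json").read_text())
    return participants, events, unlocks, config
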