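"""Exploratory statistical battery.

The engagement counts produced by the pipeline are linked to clinical
measures with a fixed family of univariate models:

* 21 quasi-Poisson regressions with sandwich robust standard errors — seven
  predictors (age, baseline PHQ-9, baseline HAM-D, CEQ credibility, CEQ
  expectancy, week-8 CSQ, log-transformed off-app practice minutes), each
  fitted against three count outcomes (overall, within-module, and
  between-module interactions).  Predictors are grand-mean centered;
  off-app minutes are transformed as ln(x + 1) before centering.
* 6 residual-change models with Huber robust linear regression — week-8
  PHQ-9 and week-8 HAM-D regressed on their grand-mean-centered baselines
  plus each of the three usage counts.
* Benjamini–Hochberg step-up FDR adjustment across the 27 focal p-values.

Also here: Spearman rank correlation with the t-approximation p-value and
McDonald's omega total, the factor-model internal-consistency reliability
of a scale's summed score, from a single-factor maximum-likelihood fit.

The count and robust linear fits are direct IRLS implementations (log-link
Poisson scoring; Huber M-estimation with MAD scale, tuning constant 1.345).
Point estimates coincide with the standard GLM/RLM routines — those serve
as independent cross-checks in the test suite — while keeping a fit cheap
enough for the simulation-based calibration suites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize

__all__ = [
    "ModelResult",
    "spearman_with_p",
    "mcdonald_omega_total",
    "omega_from_corr",
    "fit_quasipoisson_robust",
    "fit_residual_change_robust",
    "bh_adjust",
    "run_exploratory_battery",
    "spearman_matrix",
    "BATTERY_COUNT_OUTCOMES",
    "BATTERY_PREDICTORS",
    "BATTERY_CHANGE_OUTCOMES",
]

_Z975 = float(sps.norm.ppf(0.975))


@dataclass
class ModelResult:
    """One fitted univariate model from the exploratory battery."""

    model_id: str
    outcome: str
    predictor: str
    b: float
    robust_se: float
    statistic: float  # z for count models, t for robust linear models
    ci_low: float
    ci_high: float
    p_raw: float
    rate_ratio: float | None = None  # exp(b), count models only
    dispersion: float | None = None  # Pearson phi, count models only
    df_resid: int | None = None  # robust linear models only
    n: int = 0
    p_fdr: float | None = None

    def as_row(self) -> dict:
        return asdict(self)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the two-sided t-approximation p-value.

    Ties get average ranks; rho is the Pearson correlation of the ranks and
    p comes from ``t = rho*sqrt((n-2)/(1-rho^2))`` on n-2 df.  A constant
    vector leaves rho undefined (returns nan, nan with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _single_factor_ml(R: np.ndarray, floor: float = 0.005) -> tuple[np.ndarray, bool]:
    """ML single-factor loadings for a correlation matrix.

    Minimises the concentrated discrepancy F(psi) = sum_{j>=2}(theta_j -
    log theta_j - 1) over uniquenesses, where theta are the eigenvalues of
    Psi^{-1/2} R Psi^{-1/2}.  Returns (standardized loadings,
    heywood_flag); uniquenesses are floored at ``floor`` when the optimum
    runs into the boundary (Heywood case).
    """
    p = R.shape[0]

    def objective(log_psi: np.ndarray) -> float:
        psi = np.exp(log_psi)
        s = 1.0 / np.sqrt(psi)
        theta = np.linalg.eigvalsh(R * np.outer(s, s))[::-1]
        tail = np.clip(theta[1:], 1e-12, None)
        return float(np.sum(tail - np.log(tail) - 1.0))

    start = np.log(np.clip(1.0 - np.square(R - np.eye(p)).sum(0) / (p - 1), 0.05, 0.95))
    res = minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=[(np.log(floor), 0.0)] * p,
        options={"maxiter": 500},
    )
    psi = np.exp(res.x)
    heywood = bool(np.any(psi <= floor * 1.0001))
    s = 1.0 / np.sqrt(psi)
    theta, vecs = np.linalg.eigh(R * np.outer(s, s))
    theta1, w1 = theta[-1], vecs[:, -1]
    lam = np.sqrt(np.clip(theta1 - 1.0, 0.0, None)) * w1 * np.sqrt(psi)
    if lam.sum() < 0:
        lam = -lam
    return np.clip(lam, -0.999, 0.9999), heywood


def omega_from_corr(R: np.ndarray, floor: float = 0.005) -> float:
    """Omega total computed from an item correlation matrix."""
    lam, heywood = _single_factor_ml(np.asarray(R, dtype=float), floor=floor)
    if heywood:
        warnings.warn("Heywood case: uniqueness floored at 0.005", stacklevel=2)
    num = lam.sum() ** 2
    return float(num / (num + np.sum(1.0 - lam**2)))


def mcdonald_omega_total(items: np.ndarray | pd.DataFrame, floor: float = 0.005) -> float:
    """McDonald's omega total for an n x k matrix of item scores.

    Fits a single-factor model to the Pearson correlation matrix of the raw
    item scores by maximum likelihood; with standardized loadings lambda,
    ``omega_t = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2))``.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need an n x k matrix with k >= 3 items")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than items")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("constant item: correlation matrix undefined")
    return omega_from_corr(R, floor=floor)


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def fit_quasipoisson_robust(
    y,
    x,
    outcome: str = "y",
    predictor: str = "x",
    sandwich: str = "HC0",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ModelResult:
    """Quasi-Poisson regression with a sandwich robust standard error.

    Log-link Poisson scoring (IRLS) gives the point estimates — identical
    to the Poisson MLE, since the quasi-Poisson dispersion rescales only
    model-based standard errors.  Dispersion is the Pearson chi-square over
    residual df.  The robust covariance is the HC0 score sandwich
    ``B M B`` with bread ``B = (X' W X)^{-1}``, ``W = diag(mu)``, and meat
    ``M = sum_i x_i x_i' (y_i - mu_i)^2``; ``sandwich="HC1"`` applies the
    n/(n-p) small-sample scale.  Inference for the slope: z = b/se, normal
    two-sided p, 95 percent Wald CI.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    # x=None fits the intercept-only model; the reported coefficient is then
    # the intercept (log of the fitted mean)
    X = np.ones((len(y), 1)) if x is None else _design(x)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(y == 0):
        raise ValueError("degenerate fit: all counts are zero")
    beta = np.zeros(p)
    beta[0] = np.log(y.mean())
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        XtW = X.T * mu
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(X @ beta, -30, 30))
    resid = y - mu
    phi = float(np.sum(resid**2 / mu) / (n - p))
    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    meat = (X * (resid**2)[:, None]).T @ X
    cov = bread @ meat @ bread
    if sandwich == "HC1":
        cov = cov * n / (n - p)
    elif sandwich != "HC0":
        raise ValueError(f"unknown sandwich flavor {sandwich!r}")
    slot = 1 if X.shape[1] > 1 else 0
    b = float(beta[slot])
    se = float(np.sqrt(cov[slot, slot]))
    zstat = b / se if se > 0 else np.inf * np.sign(b)
    p_raw = float(2 * sps.norm.sf(abs(zstat)))
    return ModelResult(
        model_id=f"qp:{outcome}~{predictor}",
        outcome=outcome,
        predictor=predictor,
        b=b,
        robust_se=se,
        statistic=float(zstat),
        ci_low=b - _Z975 * se,
        ci_high=b + _Z975 * se,
        p_raw=p_raw,
        rate_ratio=float(np.exp(b)),
        dispersion=phi,
        n=n,
    )


def _huber_psi_weight(u: np.ndarray, c: float) -> np.ndarray:
    """Huber weights psi(u)/u = min(1, c/|u|)."""
    au = np.abs(u)
    w = np.ones_like(u)
    mask = au > c
    w[mask] = c / au[mask]
    return w


def fit_residual_change_robust(
    y_week8,
    baseline,
    usage,
    outcome: str = "week8",
    predictor: str = "usage",
    c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ModelResult:
    """Residual change score model via Huber robust linear regression.

    The end-of-treatment score is regressed on its grand-mean-centered
    baseline and the focal usage count; the usage coefficient estimates the
    association with symptom *change*.  Huber M-estimation (tuning constant
    1.345 for 95 percent Gaussian efficiency) with scale re-estimated each
    iteration as the re-scaled median absolute deviation; on noiseless data
    it reduces to ordinary least squares.  The robust standard error is the
    M-estimator sandwich ``sigma^2 A^{-1} B A^{-1}`` with ``A = X'
    diag(psi') X`` and ``B = X' diag(psi^2) X``; inference uses Wald t on
    n - p degrees of freedom.
    """
    y = np.asarray(y_week8, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(baseline, float), np.asarray(usage, float)])
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > 3 observations")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        corr = np.corrcoef(X[:, 1], X[:, 2])[0, 1] if np.ptp(X[:, 1]) and np.ptp(X[:, 2]) else np.nan
        raise ValueError(
            f"rank-deficient design (rank {rank} < {p}); baseline/usage correlation {corr:.3f}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(mad / 0.6744897501960817, 1e-12)
        w = _huber_psi_weight(resid / scale, c)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * max(1.0, np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    resid = y - X @ beta
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = max(mad / 0.6744897501960817, 1e-12)
    u = resid / scale
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    A = X.T @ (X * dpsi[:, None])
    B = X.T @ (X * (psi**2)[:, None])
    Ainv = np.linalg.pinv(A)
    cov = scale**2 * (Ainv @ B @ Ainv) * n / (n - p)
    b = float(beta[2])
    se = float(np.sqrt(max(cov[2, 2], 0.0)))
    df = n - p
    tstat = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
    p_raw = float(2 * sps.t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
    tcrit = float(sps.t.ppf(0.975, df))
    return ModelResult(
        model_id=f"rlm:{outcome}~{predictor}",
        outcome=outcome,
        predictor=predictor,
        b=b,
        robust_se=se,
        statistic=float(tstat),
        ci_low=b - tcrit * se,
        ci_high=b + tcrit * se,
        p_raw=p_raw,
        df_resid=df,
        n=n,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in original order.

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` on the ascending sort;
    monotone and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# battery layout -----------------------------------------------------------

BATTERY_COUNT_OUTCOMES = ("total_interactions", "within_count", "between_count")
BATTERY_PREDICTORS = (
    "age",
    "phq9_baseline",
    "hamd_baseline",
    "ceq_credibility",
    "ceq_expectancy",
    "csq_week8",
    "offapp_minutes",  # entered as ln(x + 1), then centered
)
BATTERY_CHANGE_OUTCOMES = (("phq9_week8", "phq9_baseline"), ("hamd_week8", "hamd_baseline"))


def run_exploratory_battery(
    data: pd.DataFrame, sandwich: str = "HC0", verbose: bool = False
) -> pd.DataFrame:
    """Fit the full 27-model family and BH-adjust its focal p-values.

    ``data`` holds one row per participant with the engagement counts and
    scale totals named in :data:`BATTERY_COUNT_OUTCOMES`,
    :data:`BATTERY_PREDICTORS` and :data:`BATTERY_CHANGE_OUTCOMES`.
    Participants missing a variable are dropped from the affected models
    only.  Returns a 27-row DataFrame of :class:`ModelResult` fields with
    ``p_fdr`` filled in.
    """
    results: list[ModelResult] = []
    for pred in BATTERY_PREDICTORS:
        raw = data[pred].astype(float)
        if pred == "offapp_minutes":
            raw = np.log(raw + 1.0)
        for out in BATTERY_COUNT_OUTCOMES:
            sub = pd.DataFrame({"y": data[out], "x": raw}).dropna()
            xc = sub["x"] - sub["x"].mean()  # grand-mean centered on contributors
            if verbose and len(sub) < len(data):
                warnings.warn(
                    f"{out}~{pred}: dropped {len(data) - len(sub)} participants with missing data"
                )
            results.append(
                fit_quasipoisson_robust(
                    sub["y"].to_numpy(), xc.to_numpy(), outcome=out, predictor=pred,
                    sandwich=sandwich,
                )
            )
    for out, base in BATTERY_CHANGE_OUTCOMES:
        for usage in BATTERY_COUNT_OUTCOMES:
            sub = data[[out, base, usage]].dropna()
            bc = sub[base] - sub[base].mean()
            results.append(
                fit_residual_change_robust(
                    sub[out].to_numpy(), bc.to_numpy(), sub[usage].to_numpy(),
                    outcome=out, predictor=usage,
                )
            )
    q = bh_adjust([r.p_raw for r in results])
    for r, qi in zip(results, q):
        r.p_fdr = float(qi)
    return pd.DataFrame([r.as_row() for r in results])


def spearman_matrix(data: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Lower-triangle Spearman correlation table with significance markers.

    Pairwise-complete observations; stars: * p<.05, ** p<.01, *** p<.001.
    """
    k = len(variables)
    out = pd.DataFrame("", index=variables, columns=variables, dtype=object)
    for i in range(k):
        for j in range(i):
            sub = data[[variables[i], variables[j]]].dropna()
            rho, p = spearman_with_p(sub.iloc[:, 0], sub.iloc[:, 1])
            stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            out.iloc[i, j] = f"{rho:.2f}{stars}"
    return out
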