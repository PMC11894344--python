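import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from modengage import (
    bh_adjust,
    fit_quasipoisson_robust,
    fit_residual_change_robust,
    mcdonald_omega_total,
    run_exploratory_battery,
    spearman_with_p,
)
from modengage.stats import omega_from_corr


# --- Spearman --------------------------------------------------------------

def _avg_ranks(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    ranks[order] = np.arange(1, len(x) + 1)
    for v in np.unique(x):
        mask = x == v
        ranks[mask] = ranks[mask].mean()
    return ranks


def _spearman_oracle(x, y):
    rx, ry = _avg_ranks(x), _avg_ranks(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * sps.t.sf(abs(t), n - 2)


def test_spearman_perfect_monotone():
    assert spearman_with_p([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
    assert spearman_with_p([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)


def test_spearman_matches_average_rank_oracle_with_ties():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = spearman_with_p(x, y)
        rho0, p0 = _spearman_oracle(x, y)
        assert rho == pytest.approx(rho0, abs=1e-12)
        if abs(rho0) < 0.9999:
            assert p == pytest.approx(p0, abs=1e-10)


def test_spearman_constant_vector_is_undefined():
    with pytest.warns(UserWarning):
        rho, p = spearman_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(rho)


# --- McDonald omega --------------------------------------------------------

def test_omega_parallel_items_closed_form():
    # k parallel items with loading L: omega = (kL)^2 / ((kL)^2 + k(1 - L^2))
    for k, lam in [(3, 0.8), (5, 0.6), (9, 0.77)]:
        R = np.full((k, k), lam * lam)
        np.fill_diagonal(R, 1.0)
        expected = (k * lam) ** 2 / ((k * lam) ** 2 + k * (1 - lam**2))
        assert omega_from_corr(R) == pytest.approx(expected, abs=1e-6)
    assert omega_from_corr(np.full((3, 3), 0.64) + np.eye(3) * 0.36) == pytest.approx(
        5.76 / 6.84, abs=1e-6
    )


def test_omega_of_uncorrelated_items_is_near_zero():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((4000, 6))
    assert mcdonald_omega_total(X) < 0.1


def test_omega_agrees_with_statsmodels_ml_factor():
    from statsmodels.multivariate.factor import Factor

    rng = np.random.default_rng(8)
    lam = np.array([0.7, 0.6, 0.8, 0.5, 0.65])
    f = rng.standard_normal(3000)
    X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((3000, 5))
    ours = mcdonald_omega_total(X)
    fit = Factor(X, n_factor=1, method="ml").fit()
    L = np.abs(np.asarray(fit.loadings).ravel())
    theirs = L.sum() ** 2 / (L.sum() ** 2 + np.sum(1 - L**2))
    assert ours == pytest.approx(theirs, abs=1e-3)


def test_omega_rejects_degenerate_input():
    with pytest.raises(ValueError):
        mcdonald_omega_total(np.ones((10, 2)))
    with pytest.raises(ValueError):
        mcdonald_omega_total(np.ones((4, 5)))


# --- quasi-Poisson with sandwich SE ----------------------------------------

def test_intercept_only_fit_recovers_log_mean():
    res = fit_quasipoisson_robust([1, 2, 3], None)
    assert res.b == pytest.approx(np.log(2.0), abs=1e-10)
    assert res.rate_ratio == pytest.approx(2.0, abs=1e-8)


def test_quasipoisson_rejects_invalid_counts():
    with pytest.raises(ValueError):
        fit_quasipoisson_robust([1.5, 2.0, 3.0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        fit_quasipoisson_robust([0, 0, 0], [0.0, 1.0, 2.0])


def _toy_counts():
    x = np.array([-2.0, -1.0, 0.0, 0.5, 1.0, 1.5])
    y = np.array([1, 3, 2, 4, 6, 9])
    return y, x


def test_coefficients_equal_poisson_mle():
    import statsmodels.api as sm

    y, x = _toy_counts()
    res = fit_quasipoisson_robust(y, x)
    X = sm.add_constant(x)
    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    assert res.b == pytest.approx(glm.params[1], abs=1e-8)
    assert res.dispersion == pytest.approx(glm.pearson_chi2 / glm.df_resid, rel=1e-6)


def test_sandwich_se_matches_hand_computed_matrix_oracle():
    y, x = _toy_counts()
    res = fit_quasipoisson_robust(y, x)
    # explicit matrix arithmetic, independent of the IRLS implementation
    X = np.column_stack([np.ones(6), x])
    beta = np.zeros(2)  # solve the MLE independently by Newton-Raphson
    for _ in range(200):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        beta = beta + np.linalg.solve(hess, grad)
    mu = np.exp(X @ beta)
    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    meat = X.T @ (X * ((y - mu) ** 2)[:, None])
    se = np.sqrt((bread @ meat @ bread)[1, 1])
    assert res.robust_se == pytest.approx(se, abs=1e-8)
    assert res.statistic == pytest.approx(res.b / se, abs=1e-8)
    assert res.ci_low < res.b < res.ci_high


def test_sandwich_se_matches_statsmodels_hc0():
    import statsmodels.api as sm

    y, x = _toy_counts()
    res = fit_quasipoisson_robust(y, x)
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit(cov_type="HC0")
    assert res.robust_se == pytest.approx(glm.bse[1], rel=1e-6)


def test_sandwich_approaches_model_se_without_overdispersion():
    # equidispersed Poisson data: robust and model-based SEs should agree
    rng = np.random.default_rng(12)
    n = 2000
    x = rng.standard_normal(n)
    y = rng.poisson(np.exp(1.0 + 0.3 * x))
    res = fit_quasipoisson_robust(y, x)
    X = np.column_stack([np.ones(n), x])
    mu = np.exp(X @ np.array([1.0, 0.3]))
    model_se = np.sqrt(np.linalg.inv(X.T @ (X * mu[:, None]))[1, 1])
    assert res.robust_se == pytest.approx(model_se, rel=0.1)
    assert res.dispersion == pytest.approx(1.0, abs=0.15)


# --- Huber residual-change model -------------------------------------------

def test_huber_fit_is_exact_on_noiseless_plane():
    rng = np.random.default_rng(4)
    baseline = rng.normal(0, 3, 40)
    usage = rng.poisson(3.0, 40).astype(float)
    y = 1.0 + 2.0 * baseline + 0.5 * usage
    res = fit_residual_change_robust(y, baseline, usage)
    assert res.b == pytest.approx(0.5, abs=1e-8)


def test_huber_matches_least_squares_on_clean_normal_data():
    rng = np.random.default_rng(21)
    n = 4000
    baseline = rng.normal(0, 5, n)
    usage = rng.poisson(2.0, n).astype(float)
    y = 3.0 + 0.6 * baseline + 0.23 * usage + rng.normal(0, 2.0, n)
    res = fit_residual_change_robust(y, baseline, usage)
    X = np.column_stack([np.ones(n), baseline, usage])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert res.b == pytest.approx(ols[2], abs=0.02)


def test_huber_matches_statsmodels_rlm():
    import statsmodels.api as sm

    rng = np.random.default_rng(17)
    n = 200
    baseline = rng.normal(0, 5, n)
    usage = rng.poisson(2.0, n).astype(float)
    y = 3.0 + 0.6 * baseline + 0.2 * usage + rng.standard_t(3, n) * 2
    res = fit_residual_change_robust(y, baseline, usage)
    X = sm.add_constant(np.column_stack([baseline, usage]))
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(1.345)).fit(scale_est="mad")
    assert res.b == pytest.approx(rlm.params[2], abs=5e-3)


def test_huber_rejects_rank_deficient_design():
    base = np.arange(10.0)
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_residual_change_robust(np.arange(10.0), base, 2 * base)


# --- Benjamini-Hochberg ----------------------------------------------------

def test_bh_step_up_enumeration():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_adjust([0.03]), [0.03])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    # hand-enumerated mixed case: sorted p (.005,.04,.04,.8) * 4/(1..4) ->
    # (.02,.08,.0533..,.8) -> running min from the right -> (.02,.0533..,.0533..,.8)
    out = bh_adjust([0.04, 0.005, 0.8, 0.04])
    assert np.allclose(out, [0.16 / 3, 0.02, 0.8, 0.16 / 3])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(50):
        p = rng.uniform(0, 1, rng.integers(1, 40))
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(deadline=None, max_examples=100)
def test_bh_is_monotone_and_never_decreases(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)  # adjustment never decreases p
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)  # order-preserving


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# --- battery ---------------------------------------------------------------

def test_battery_shape_and_fdr_contract():
    from modengage import CohortConfig, generate_cohort
    from modengage.synth import planned_analysis_frame

    df = planned_analysis_frame(generate_cohort(CohortConfig(seed=9, n_participants=60)))
    res = run_exploratory_battery(df)
    assert len(res) == 27
    assert res["model_id"].is_unique
    assert (res["p_fdr"] >= res["p_raw"] - 1e-12).all()
    assert (res.loc[res["rate_ratio"].notna(), "dispersion"] > 0).all()
    # missing week-8 data (dropouts) only shrinks the affected models
    assert res["n"].max() == 60
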