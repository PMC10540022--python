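"""Estimator core: normal-equation and sandwich oracles, design
construction, independent GEE cross-check, contrast algebra."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrtdose import (
    ModelSpec,
    WCLSRegressor,
    build_design,
    fit_wcls,
    wald_contrast,
)
from mrtdose.wcls import CollinearDesignError


def toy_clustered_data(n_clusters=3, n_per=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_clusters * n_per
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    groups = np.repeat(np.arange(n_clusters), n_per)
    y = X @ np.array([1.0, 0.5, -0.25]) + rng.normal(size=n_clusters)[groups] \
        + rng.normal(size=n) * 0.3
    return X, y, groups


def brute_force_sandwich(X, y, groups, w=None):
    """Independent oracle: explicit normal equations and bread/meat sums."""
    w = np.ones(len(y)) if w is None else w
    W = np.diag(w)
    bread = X.T @ W @ X
    coef = np.linalg.inv(bread) @ X.T @ W @ y
    r = y - X @ coef
    meat = np.zeros_like(bread)
    for g in np.unique(groups):
        i = groups == g
        s = X[i].T @ W[np.ix_(i, i)] @ r[i]
        meat += np.outer(s, s)
    V = np.linalg.inv(bread) @ meat @ np.linalg.inv(bread)
    return coef, V


def hc0_covariance(X, y):
    """Independently coded HC0 heteroskedasticity-consistent covariance."""
    bread_inv = np.linalg.inv(X.T @ X)
    coef = bread_inv @ X.T @ y
    r = y - X @ coef
    meat = (X * r[:, None] ** 2).T @ X
    return bread_inv @ meat @ bread_inv


def test_coefficients_match_explicit_normal_equations():
    X, y, groups = toy_clustered_data()
    est = WCLSRegressor().fit(X, y, groups=groups)
    coef, V = brute_force_sandwich(X, y, groups)
    assert np.allclose(est.coef_, coef, atol=1e-10, rtol=0)
    assert np.allclose(est.robust_covariance_, V, atol=1e-10, rtol=0)


def test_weighted_fit_matches_weighted_normal_equations():
    X, y, groups = toy_clustered_data(seed=3)
    w = np.linspace(0.5, 2.0, len(y))
    est = WCLSRegressor().fit(X, y, groups=groups, sample_weight=w)
    coef, V = brute_force_sandwich(X, y, groups, w)
    assert np.allclose(est.coef_, coef, atol=1e-10, rtol=0)
    assert np.allclose(est.robust_covariance_, V, atol=1e-10, rtol=0)


def test_singleton_clusters_reduce_to_hc0():
    X, y, _ = toy_clustered_data(seed=1)
    est = WCLSRegressor().fit(X, y)  # no groups: every row its own cluster
    assert np.allclose(est.robust_covariance_, hc0_covariance(X, y), atol=1e-12)
    assert est.n_clusters_ == len(y)


def test_constant_response_gives_pure_intercept_and_zero_variance():
    X, y, groups = toy_clustered_data(seed=2)
    y = np.full_like(y, 3.25)
    est = WCLSRegressor().fit(X, y, groups=groups)
    assert est.coef_[0] == pytest.approx(3.25, abs=1e-12)
    assert np.allclose(est.coef_[1:], 0, atol=1e-12)
    assert np.allclose(est.robust_covariance_, 0, atol=1e-20)


def test_sandwich_invariant_to_cluster_labels_and_row_order():
    X, y, groups = toy_clustered_data(seed=4)
    base = WCLSRegressor().fit(X, y, groups=groups)
    relabeled = WCLSRegressor().fit(X, y, groups=np.array([f"c{g}" for g in groups]))
    perm = np.random.default_rng(0).permutation(len(y))
    shuffled = WCLSRegressor().fit(X[perm], y[perm], groups=groups[perm])
    for other in (relabeled, shuffled):
        assert np.allclose(base.coef_, other.coef_, atol=1e-12)
        assert np.allclose(
            base.robust_covariance_, other.robust_covariance_, atol=1e-12
        )


def test_matches_statsmodels_gee_independence(weekly_table):
    spec = ModelSpec("anxiety")
    y, X, w, groups = build_design(spec, weekly_table)
    fit = fit_wcls(spec, weekly_table)
    gee = sm.GEE(
        y.to_numpy(), X.to_numpy(), groups=groups,
        family=sm.families.Gaussian(), cov_struct=sm.cov_struct.Independence(),
    ).fit()
    assert np.allclose(gee.params, fit.params.to_numpy(), atol=1e-10)
    assert np.allclose(gee.cov_params(), fit.vcov.to_numpy(), atol=1e-12)


def test_mancl_derouen_matches_statsmodels_bias_reduced(weekly_table):
    spec = ModelSpec("strain", small_sample_correction="mancl-derouen")
    y, X, w, groups = build_design(spec, weekly_table)
    fit = fit_wcls(spec, weekly_table)
    gee = sm.GEE(
        y.to_numpy(), X.to_numpy(), groups=groups,
        family=sm.families.Gaussian(), cov_struct=sm.cov_struct.Independence(),
    ).fit(cov_type="bias_reduced")
    assert np.allclose(gee.cov_params(), fit.vcov.to_numpy(), atol=1e-12)


def test_bell_mccaffrey_variance_and_satterthwaite_df(weekly_table):
    spec = ModelSpec("strain", small_sample_correction="bell-mccaffrey")
    fit = fit_wcls(spec, weekly_table)
    plain = fit_wcls(ModelSpec("strain"), weekly_table)
    # CR2 inflates the plain sandwich
    assert (fit.bse >= plain.bse - 1e-12).all()
    for lvl in ("low", "medium", "high"):
        c = wald_contrast(fit, {f"dose_{lvl}": 1.0})
        assert c.df is not None and 2 < c.df < fit.n_clusters
        # t CI is wider than the z CI at the same SE
        assert (c.ci_upper - c.ci_lower) > 2 * 1.96 * c.se * 0.999


def test_design_column_layout_and_log_response(weekly_table):
    spec = ModelSpec("strain")
    y, X, w, groups = build_design(spec, weekly_table)
    assert list(X.columns) == [
        "intercept", "week_index", "sex_male", "baseline_age",
        "dose_low", "dose_medium", "dose_high",
    ]
    row = weekly_table.loc[y.index[0]]
    assert y.iloc[0] == pytest.approx(np.log(row["score_strain"]))
    assert np.log(50.0) == pytest.approx(3.912, abs=5e-4)
    assert (w == 1).all()


def test_centered_treatment_subtracts_category_probabilities(weekly_table):
    spec = ModelSpec("strain", centering=True, p_rand=0.5)
    y, X, w, groups = build_design(spec, weekly_table)
    full = weekly_table.loc[y.index]
    hi = (full["eligible_days"] == 6) & (full["dose_category"] == "high")
    idx = X.index[hi.to_numpy()][0]
    assert X.loc[idx, "dose_low"] == pytest.approx(0 - 21 / 64)
    assert X.loc[idx, "dose_medium"] == pytest.approx(0 - 35 / 64)
    assert X.loc[idx, "dose_high"] == pytest.approx(1 - 7 / 64)
    # centered fits exclude weeks with no eligible days by default
    assert (full["eligible_days"] > 0).all()


def test_uncentered_equals_pooled_ols(weekly_table):
    spec = ModelSpec("depression")
    y, X, w, groups = build_design(spec, weekly_table)
    fit = fit_wcls(spec, weekly_table)
    ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    assert np.allclose(ols.params, fit.params.to_numpy(), atol=1e-10)


def test_subgroup_contrast_equals_refit_on_subgroup(weekly_table):
    # with group-saturated design (no shared controls) the SCI high-dose
    # contrast must equal the bare coefficient from an SCI-only refit
    spec = ModelSpec("strain", controls=(), moderators=("group",))
    fit = fit_wcls(spec, weekly_table)
    combined = wald_contrast(
        fit, {"dose_high": 1.0, "dose_high:group_SCI": 1.0}
    )
    sci = weekly_table[weekly_table["group"] == "SCI"]
    refit = fit_wcls(ModelSpec("strain", controls=()), sci)
    assert combined.estimate == pytest.approx(refit.params["dose_high"], abs=1e-10)
    assert combined.se == pytest.approx(refit.bse["dose_high"], abs=1e-10)


def test_wald_contrast_unit_and_zero_vectors(weekly_table):
    fit = fit_wcls(ModelSpec("strain"), weekly_table)
    unit = wald_contrast(fit, {"dose_medium": 1.0})
    assert unit.estimate == pytest.approx(fit.params["dose_medium"])
    assert unit.se == pytest.approx(fit.bse["dose_medium"])
    assert unit.ci_lower <= unit.estimate <= unit.ci_upper
    assert 0 <= unit.p_value <= 1
    zero = wald_contrast(fit, np.zeros(len(fit.params)))
    assert zero.estimate == 0.0
    assert zero.se == 0.0


def test_collinear_design_reported():
    X, y, groups = toy_clustered_data()
    X = np.column_stack([X, X[:, 1] + X[:, 2]])
    with pytest.raises(CollinearDesignError):
        WCLSRegressor().fit(X, y, groups=groups)


def test_empty_and_mismatched_inputs_rejected():
    with pytest.raises(ValueError):
        WCLSRegressor().fit(np.empty((0, 2)), np.empty(0))
    X, y, groups = toy_clustered_data()
    with pytest.raises(ValueError):
        WCLSRegressor().fit(X, y[:-1])
    with pytest.raises(ValueError):
        WCLSRegressor().fit(X, y, sample_weight=np.zeros(len(y)))
    y2 = y.copy()
    y2[0] = np.nan
    with pytest.raises(ValueError):
        WCLSRegressor().fit(X, y2)


def test_fit_result_round_trips_through_json(tmp_path, weekly_table):
    fit = fit_wcls(ModelSpec("anxiety"), weekly_table)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = fit.__class__.from_json(path)
    pd.testing.assert_series_equal(fit.params, back.params)
    pd.testing.assert_frame_equal(fit.vcov, back.vcov)
    assert back.n_clusters == fit.n_clusters


def test_sklearn_estimator_protocol():
    est = WCLSRegressor(small_sample_correction="mancl-derouen")
    assert est.get_params() == {"small_sample_correction": "mancl-derouen"}
    est.set_params(small_sample_correction=False)
    X, y, groups = toy_clustered_data()
    est.fit(X, y, groups=groups)
    pred = est.predict(X)
    assert pred.shape == y.shape
    # R^2 via the RegressorMixin contract
    assert est.score(X, y) > 0
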