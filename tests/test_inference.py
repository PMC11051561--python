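"""Standardization, nested models, interaction probes, BH, SES factor, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ednt.inference import (
    ModelFit,
    bh_adjust,
    correlation_matrix,
    empty_model,
    fit_nested_models,
    johnson_neyman,
    nested_f,
    regression_power,
    required_sample_size,
    ses_factor,
    simple_slopes,
    standardize,
)

MODEL3_TERMS = ["const", "pi_prop_c", "raven_z", "sex", "age_z", "sex_x_raven", "sex_x_age"]


def _synthetic_fit(params, cov, df_resid=148):
    """ModelFit with hand-constructed coefficients and covariance."""
    idx = MODEL3_TERMS
    p = pd.Series(params, index=idx, dtype=float)
    V = pd.DataFrame(cov, index=idx, columns=idx, dtype=float)
    se = pd.Series(np.sqrt(np.diag(V)), index=idx)
    return ModelFit(
        outcome="DD", model_id=3, n=df_resid + 7, terms=idx[1:],
        params=p, bse=se, tvalues=p / se.replace(0, np.nan),
        pvalues=pd.Series(np.nan, index=idx), cov_params=V,
        df_resid=df_resid, rsquared=0.1, rsquared_adj=0.1,
        f_overall=np.nan, f_overall_p=np.nan,
    )


def _cohort(n=160, seed=0, interaction=60.0):
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n)
    age = rng.integers(43, 71, n)
    age_z = (age - age.mean()) / age.std(ddof=1)
    raven = rng.normal(18, 4, n)
    pi_prop = rng.uniform(0.3, 0.6, n)
    pe_prop = rng.uniform(0.05, 0.3, n)
    dd = 40 + 70 * sex - 5 * age_z + interaction * sex * age_z + rng.normal(0, 150, n)
    pes = 230 + 40 * sex + 20 * age_z + rng.normal(0, 300, n)
    return pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(n)], "sex": sex, "age_months": age,
         "raven_raw": raven, "pi_prop": pi_prop, "pe_prop": pe_prop,
         "dd_ms": dd, "pes_ms": pes}
    )


# --- standardization -------------------------------------------------------

def test_standardize_symmetric_triple():
    df = pd.DataFrame({"age_months": [52, 55, 58], "raven_raw": [10, 20, 30]})
    out = standardize(df, center_columns=())
    assert out.age_z.tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_constant_column_errors():
    df = pd.DataFrame({"age_months": [52, 55, 58], "raven_raw": [20, 20, 20]})
    with pytest.raises(ValueError, match="raven_raw"):
        standardize(df, center_columns=())


def test_age_to_z_mapping_months():
    """With cohort mean 4y-7m (55 mo) and SD 5 mo, 4y-4m (52 mo) is z=-0.6."""
    assert (52 - 55) / 5 == pytest.approx(-0.6)


def test_proportions_centered_not_scaled():
    df = pd.DataFrame(
        {"age_months": [50, 55, 60], "raven_raw": [10, 20, 30], "pi_prop": [0.3, 0.4, 0.8]}
    )
    out = standardize(df, center_columns=("pi_prop",))
    assert out.pi_prop_c.mean() == pytest.approx(0.0)
    assert out.pi_prop_c.max() - out.pi_prop_c.min() == pytest.approx(0.5)


# --- empty model and nested sequence --------------------------------------

def test_empty_model_two_point():
    res = empty_model([100.0, 300.0])
    assert res["intercept"] == pytest.approx(200.0)
    assert res["se"] == pytest.approx(100.0)
    assert res["df"] == 1


def test_empty_model_equals_one_sample_t(child_classified):
    """Empty-model intercept/t reproduce the sample mean and the one-sample
    t-test (independent scipy route) exactly."""
    from ednt.effects import cohort_effects

    classified, _ = child_classified
    dd = cohort_effects(classified)["dd_ms"].dropna()
    res = empty_model(dd)
    t_ref, p_ref = sps.ttest_1samp(dd, 0.0)
    assert res["intercept"] == pytest.approx(dd.mean(), rel=1e-12)
    assert res["t"] == pytest.approx(t_ref, rel=1e-12)
    assert res["p"] == pytest.approx(p_ref, rel=1e-12)


def test_nested_sequence_structure_and_df():
    """Model 2 adds 4 terms -> dF df (4, n-5); model 3 adds 2 -> (2, n-7);
    model-1 intercept equals the outcome mean exactly."""
    cohort = _cohort(n=154)
    fits = fit_nested_models(cohort, "DD")
    assert [f.model_id for f in fits] == [1, 2, 3]
    assert fits[0].params["const"] == pytest.approx(cohort.dd_ms.mean(), rel=1e-12)
    assert fits[1].delta_f_df == (4, 154 - 5)
    assert fits[2].delta_f_df == (2, 154 - 7)
    assert fits[1].terms == ["pi_prop_c", "raven_z", "sex", "age_z"]
    assert fits[2].terms[-2:] == ["sex_x_raven", "sex_x_age"]


def test_intercept_only_fit_on_three_values():
    df = pd.DataFrame(
        {"subject_id": list("abcdefghij"), "dd_ms": [1.0, 2, 3, 1, 2, 3, 1, 2, 3, 2],
         "pi_prop": [0.41, 0.55, 0.38, 0.47, 0.60, 0.33, 0.52, 0.44, 0.36, 0.58],
         "raven_raw": [12, 25, 9, 18, 30, 14, 22, 11, 27, 16],
         "age_months": np.arange(50, 60), "sex": [0, 1] * 5, "pes_ms": 1.0,
         "pe_prop": [0.12, 0.25, 0.09, 0.18, 0.30, 0.14, 0.22, 0.11, 0.27, 0.16]}
    )
    fits = fit_nested_models(df, "DD")
    assert fits[0].params["const"] == pytest.approx(2.0)
    assert fits[0].df_resid == 9


def test_nested_f_equals_t_squared_for_single_term():
    """Adding one regressor: the nested F equals the squared t of that term."""
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    x = rng.normal(size=60)
    y = 2 + 0.5 * x + rng.normal(size=60)
    X = sm.add_constant(x)
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.ones_like(x)).fit()
    f, p = nested_f(reduced.ssr, full.ssr, 1, int(full.df_resid))
    assert f == pytest.approx(full.tvalues[1] ** 2, rel=1e-10)
    assert p == pytest.approx(full.pvalues[1], rel=1e-10)


def test_casewise_deletion_per_outcome():
    """A missing PES for one subject shrinks the PES models by one case but
    leaves the DD models at full n."""
    cohort = _cohort(n=100)
    cohort.loc[0, "pes_ms"] = np.nan
    assert fit_nested_models(cohort, "PES")[0].n == 99
    assert fit_nested_models(cohort, "DD")[0].n == 100


def test_rank_deficient_design_reported():
    cohort = _cohort(n=60)
    cohort["sex"] = 1  # constant sex makes sex collinear with the intercept
    with pytest.raises(ValueError, match="rank-deficient|zero variance"):
        fit_nested_models(cohort, "DD")


# --- simple slopes and region of significance ------------------------------

def test_simple_slopes_zero_and_sum():
    V = np.eye(7) * 4.0
    fit = _synthetic_fit([20, 0, 0, 75, 0, 0, 0], V)
    slopes = simple_slopes(fit)
    assert slopes.slope_ms.tolist() == [0.0, 0.0]
    fit2 = _synthetic_fit([20, 0, 0, 75, -8.43, 0, 62.62], V)
    slopes2 = simple_slopes(fit2).set_index("group")
    assert slopes2.loc["boys", "slope_ms"] == pytest.approx(-8.43)
    assert slopes2.loc["girls", "slope_ms"] == pytest.approx(-8.43 + 62.62)


def test_simple_slopes_reparameterization_oracle():
    """Recoding sex (1 = male) swaps the roles of the two slopes: the refitted
    model must reproduce boys'/girls' slopes exactly."""
    cohort = _cohort(n=200, seed=8)
    fit3 = fit_nested_models(cohort, "DD")[-1]
    slopes = simple_slopes(fit3).set_index("group")

    flipped = cohort.assign(sex=1 - cohort.sex)
    fit3_f = fit_nested_models(flipped, "DD")[-1]
    slopes_f = simple_slopes(fit3_f).set_index("group")
    assert slopes.loc["boys", "slope_ms"] == pytest.approx(
        slopes_f.loc["girls", "slope_ms"], rel=1e-9
    )
    assert slopes.loc["boys", "f"] == pytest.approx(slopes_f.loc["girls", "f"], rel=1e-9)


def test_simple_slopes_requires_interaction_term():
    cohort = _cohort(n=60)
    fit2 = fit_nested_models(cohort, "DD")[1]
    with pytest.raises(ValueError, match="sex_x_age"):
        simple_slopes(fit2)


def test_ros_constructed_boundary_at_minus_0p6_sd():
    """Coefficients built so the girls' CI lower bound touches zero exactly
    at z = -0.6: the continuous boundary must map to mean - 0.6 SD months."""
    df_resid = 148
    tcrit = sps.t.ppf(0.975, df_resid)
    v = 100.0
    B = 20.0  # small enough that the negative-side root falls outside the range
    A = tcrit * np.sqrt(v) + 0.6 * B
    V = np.zeros((7, 7))
    V[0, 0] = v  # variance only on the intercept: Var(yhat) constant
    fit = _synthetic_fit([A, 0, 0, 0, B, 0, 0], V, df_resid=df_resid)
    mean_m, sd_m = 55.0, 5.0
    res = johnson_neyman(fit, 1, mean_m, sd_m, (43, 70), grid_step_months=0.1)
    assert res.direction == "significant_above"
    assert res.boundary_age_months_continuous == pytest.approx(mean_m - 0.6 * sd_m, abs=1e-6)
    assert res.boundary_age_months == pytest.approx(52.0, abs=0.1 + 1e-9)


def test_ros_always_when_flat_and_significant():
    """Zero slopes with an intercept CI excluding zero: significant at every
    age (direction 'always')."""
    V = np.zeros((7, 7))
    V[0, 0] = 25.0
    fit = _synthetic_fit([100, 0, 0, 0, 0, 0, 0], V)
    res = johnson_neyman(fit, 0, 55.0, 5.0, (43, 70))
    assert res.direction == "always"
    assert res.boundary_age_months is None


def test_ros_never_when_flat_and_null():
    V = np.zeros((7, 7))
    V[0, 0] = 10000.0
    fit = _synthetic_fit([1.0, 0, 0, 0, 0, 0, 0], V)
    res = johnson_neyman(fit, 0, 55.0, 5.0, (43, 70))
    assert res.direction == "never"
    assert res.boundary_age_months is None


def test_ros_closed_form_matches_grid_search():
    """On 100 random coefficient/covariance draws the continuous root agrees
    with a 0.1-month brute-force grid scan to within one grid step."""
    rng = np.random.default_rng(12)
    checked = 0
    for _ in range(100):
        L = rng.normal(scale=8.0, size=(7, 7))
        V = L @ L.T / 7
        params = rng.normal(scale=[60, 10, 10, 60, 30, 10, 30])
        fit = _synthetic_fit(params, V)
        mean_m, sd_m = 55.0, 5.0
        res = johnson_neyman(fit, 1, mean_m, sd_m, (43, 70), grid_step_months=0.1)
        months = np.arange(43, 70 + 1e-9, 0.1)
        z = (months - mean_m) / sd_m
        idx = fit.params.index
        u = pd.Series(0.0, index=idx); u["const"] = 1.0; u["sex"] = 1.0
        w = pd.Series(0.0, index=idx); w["age_z"] = 1.0; w["sex_x_age"] = 1.0
        est = (u @ fit.params) + (w @ fit.params) * z
        var = (u @ V @ u) + 2 * (u @ V @ w) * z + (w @ V @ w) * z**2
        sig = np.abs(est) > sps.t.ppf(0.975, fit.df_resid) * np.sqrt(var)
        transitions = months[1:][np.diff(sig.astype(int)) != 0]
        if res.boundary_age_months_continuous is not None and len(transitions):
            gaps = np.abs(transitions - res.boundary_age_months_continuous)
            assert gaps.min() <= 0.1 + 1e-9
            checked += 1
    assert checked >= 30  # enough informative draws to trust the agreement


# --- correlations and BH ----------------------------------------------------

def test_bh_hand_worked_example():
    """p = {.01,.02,.03,.04} with m=4: step-up gives .04 for every entry."""
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adj[i] = running
    return adj


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=25))
def test_bh_matches_bruteforce_stepup(pvals):
    assert bh_adjust(pvals) == pytest.approx(_bh_bruteforce(pvals), rel=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=20))
def test_bh_dominates_raw_and_is_monotone(pvals):
    p = np.asarray(pvals)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_correlation_matrix_collinear_and_bh():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=50)})
    out = correlation_matrix(df, ["a", "b", "c"])
    assert out["r"].loc["a", "b"] == pytest.approx(1.0)
    assert out["p_adj"].loc["a", "b"] < 1e-10
    assert (out["p_adj"].loc["a", "c"] >= out["p_raw"].loc["a", "c"]) or np.isclose(
        out["p_adj"].loc["a", "c"], out["p_raw"].loc["a", "c"]
    )


def test_correlation_matrix_constant_column_missing():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
    out = correlation_matrix(df, ["a", "b"])
    assert np.isnan(out["r"].loc["a", "b"])


def test_spearman_variant_runs():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    out = correlation_matrix(df, ["a", "b"], method="spearman")
    assert -1 <= out["r"].loc["a", "b"] <= 1


# --- SES factor -------------------------------------------------------------

def test_ses_factor_recovers_known_loadings():
    """Indicators generated from a 1-factor model with loadings
    (.40, .78, .51, .57) at n=5000: ML recovery within .05."""
    rng = np.random.default_rng(6)
    lam = np.array([0.40, 0.78, 0.51, 0.57])
    f = rng.standard_normal(5000)
    X = f[:, None] * lam + rng.standard_normal((5000, 4)) * np.sqrt(1 - lam**2)
    df = pd.DataFrame(X, columns=["edu_years", "income", "rooms", "cars"])
    out = ses_factor(df)
    assert out["loadings"].to_numpy() == pytest.approx(lam, abs=0.05)
    assert out["loadings"]["income"] > 0
    assert out["scores"].mean() == pytest.approx(0.0, abs=1e-8)
    assert not out["heywood"]


def test_ses_factor_orthogonal_noise_near_zero_loadings():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.standard_normal((5000, 4)), columns=["edu_years", "income", "rooms", "cars"]
    )
    out = ses_factor(df)
    # ML FA on pure noise latches onto the top sampling eigenvalue, so
    # "near zero" means well below the smallest generative loading (.40)
    assert np.abs(out["loadings"].to_numpy()).max() < 0.3


def test_ses_factor_needs_enough_rows():
    df = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 4)))
    with pytest.raises(ValueError, match=">= 20"):
        ses_factor(df)


# --- power ------------------------------------------------------------------

def test_required_sample_size_reference_values():
    """The noncentral-F iteration reproduces published G*Power solutions for
    the regression R-squared test (f2=.15 and .35 with six predictors), and
    gives N=130 for the small-effect setup (f2 = .10/.90, alpha .05,
    power .80)."""
    assert required_sample_size(0.13043478, 6).required_n == 98  # f2 = .15
    assert required_sample_size(0.25925926, 6).required_n == 46  # f2 = .35
    assert required_sample_size(0.10, 6).required_n == 130


def test_required_sample_size_minimality():
    spec = required_sample_size(0.10, 6)
    assert regression_power(spec.required_n, 0.10, 6) >= 0.80
    assert regression_power(spec.required_n - 1, 0.10, 6) < 0.80


def test_power_monotonicity_and_limit():
    assert regression_power(10_000, 0.10, 6) == pytest.approx(1.0, abs=1e-9)
    assert required_sample_size(0.20, 6).required_n <= required_sample_size(0.10, 6).required_n
    assert (
        required_sample_size(0.10, 6, target_power=0.90).required_n
        >= required_sample_size(0.10, 6, target_power=0.80).required_n
    )


def test_power_invalid_inputs():
    with pytest.raises(ValueError):
        required_sample_size(0.0, 6)
    with pytest.raises(ValueError):
        required_sample_size(0.1, 6, alpha=1.5)
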