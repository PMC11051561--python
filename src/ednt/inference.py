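"""Cohort-level statistics for the PES/DD analysis.

The modeling strategy is a sequence of nested ordinary-least-squares
models per outcome (PES or DD, in ms):

* model 1 — empty (intercept only); its intercept and t statistic are
  algebraically the sample mean and one-sample t-test of the effect;
* model 2 — adds the matched condition-proportion covariate (PE
  proportion for PES, PI proportion for DD; mean-centered), the
  standardized Raven score, sex (0 = male, 1 = female) and standardized
  age;
* model 3 — adds the sex x Raven and sex x age interactions.

Successive models are compared with the nested-model F test on residual
sums of squares.  The sex x age interaction is probed with simple
slopes (per-sex age slope and its F(1, df_resid)) and a Johnson-Neyman
region-of-significance analysis that maps the standardized-age boundary
back to months.  Supporting procedures: BH-corrected zero-order
correlation matrices, a one-factor maximum-likelihood SES factor with
Thomson regression scores, and the noncentral-F sample-size computation
for the fixed-model multiple-regression F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import FactorAnalysis
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

OUTCOME_COLUMNS = {"PES": "pes_ms", "DD": "dd_ms"}
PROP_COLUMNS = {"PES": "pe_prop", "DD": "pi_prop"}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(
    cohort: pd.DataFrame,
    z_columns: tuple[str, ...] = ("age_months", "raven_raw"),
    center_columns: tuple[str, ...] = ("pe_prop", "pi_prop"),
    standardize_props: bool = False,
) -> pd.DataFrame:
    """Add ``age_z``/``raven_z`` and centered proportion columns.

    z-scores use the sample SD (ddof=1) over the rows supplied — pass
    the modeled subset.  Proportions are mean-centered but left on
    their natural scale by default (so model intercepts read as the
    grand effect at average proportions); ``standardize_props`` rescales
    them too.
    """
    out = cohort.copy()
    names = {"age_months": "age_z", "raven_raw": "raven_z"}
    for col in z_columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize {col!r}: zero variance")
        out[names.get(col, f"{col}_z")] = (x - x.mean()) / sd
    for col in center_columns:
        if col not in out:
            continue
        x = out[col].astype(float)
        if standardize_props:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"cannot standardize {col!r}: zero variance")
            out[f"{col}_c"] = (x - x.mean()) / sd
        else:
            out[f"{col}_c"] = x - x.mean()
    return out


# ---------------------------------------------------------------------------
# nested models
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    outcome: str
    model_id: int
    n: int
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    rsquared: float
    rsquared_adj: float
    f_overall: float
    f_overall_p: float
    delta_r2: float | None = None
    delta_f: float | None = None
    delta_f_df: tuple[int, int] | None = None
    delta_f_p: float | None = None
    _results: object = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "model_id": self.model_id,
                "outcome": self.outcome,
            }
        )


def _model_terms(model_id: int, outcome: str, include_sex: bool) -> list[str]:
    prop = PROP_COLUMNS[outcome] + "_c"
    if model_id == 1:
        return []
    base = [prop, "raven_z"] + (["sex"] if include_sex else []) + ["age_z"]
    if model_id == 2:
        return base
    if model_id == 3:
        if not include_sex:
            raise ValueError("model 3 (sex interactions) requires sex in the design")
        return base + ["sex_x_raven", "sex_x_age"]
    raise ValueError(f"unknown model_id {model_id}")


def nested_f(rss_reduced: float, rss_full: float, df_num: int, df_resid_full: int) -> tuple[float, float]:
    """Nested-model F test on residual sums of squares.

    F = ((RSS_reduced - RSS_full) / df_num) / (RSS_full / df_resid_full);
    when a single term is added, F equals the squared t statistic of that
    term in the larger model.
    """
    fstat = ((rss_reduced - rss_full) / df_num) / (rss_full / df_resid_full)
    return float(fstat), float(sps.f.sf(fstat, df_num, df_resid_full))


def fit_nested_models(
    cohort: pd.DataFrame,
    outcome: str,
    include_sex: bool = True,
    standardize_props: bool = False,
) -> list[ModelFit]:
    """Fit the nested OLS sequence for one outcome.

    Casewise deletion is applied once, over the union of columns used by
    the largest model, so every model in the sequence is fitted to the
    same subjects and the nested F comparisons are valid.  Covariate
    standardization/centering is computed on that modeled subset.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    ycol = OUTCOME_COLUMNS[outcome]
    raw_cols = [ycol, PROP_COLUMNS[outcome], "raven_raw", "age_months"]
    if include_sex:
        raw_cols.append("sex")
    data = cohort.dropna(subset=raw_cols).copy()
    n = len(data)
    if n < 10:
        raise ValueError(f"need >= 10 non-missing rows for {outcome}; have {n}")
    data = standardize(
        data,
        z_columns=("age_months", "raven_raw"),
        center_columns=(PROP_COLUMNS[outcome],),
        standardize_props=standardize_props,
    )
    if include_sex:
        data["sex_x_raven"] = data["sex"] * data["raven_z"]
        data["sex_x_age"] = data["sex"] * data["age_z"]

    max_model = 3 if include_sex else 2
    fits: list[ModelFit] = []
    prev = None
    for model_id in range(1, max_model + 1):
        terms = _model_terms(model_id, outcome, include_sex)
        X = sm.add_constant(data[terms], has_constant="add") if terms else pd.DataFrame(
            {"const": np.ones(n)}, index=data.index
        )
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient design for model {model_id}: terms {terms}")
        res = sm.OLS(data[ycol].astype(float), X).fit()
        fit = ModelFit(
            outcome=outcome,
            model_id=model_id,
            n=n,
            terms=terms,
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            cov_params=res.cov_params(),
            df_resid=res.df_resid,
            rsquared=res.rsquared,
            rsquared_adj=res.rsquared_adj,
            f_overall=float(res.fvalue) if terms else np.nan,
            f_overall_p=float(res.f_pvalue) if terms else np.nan,
            _results=res,
        )
        if prev is not None:
            df_num = len(terms) - len(prev.terms)
            df_den = int(fit.df_resid)
            fstat, fp = nested_f(float(prev._results.ssr), float(res.ssr), df_num, df_den)
            fit.delta_r2 = fit.rsquared - prev.rsquared
            fit.delta_f = fstat
            fit.delta_f_df = (df_num, df_den)
            fit.delta_f_p = fp
        fits.append(fit)
        prev = fit
    return fits


def empty_model(values: pd.Series | np.ndarray) -> dict:
    """Intercept-only model == one-sample t-test of the effect against 0."""
    x = pd.Series(values).dropna().to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("empty model needs >= 2 non-missing values")
    mean = x.mean()
    se = x.std(ddof=1) / np.sqrt(n)
    t = mean / se if se > 0 else np.inf * np.sign(mean)
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return {"intercept": mean, "se": se, "t": t, "df": df, "p": p, "n": n}


# ---------------------------------------------------------------------------
# interaction probes
# ---------------------------------------------------------------------------

def simple_slopes(fit3: ModelFit) -> pd.DataFrame:
    """Per-sex age slope from a model-3 fit.

    Boys' slope is the age coefficient; girls' slope adds the sex x age
    coefficient.  Standard errors come from the coefficient covariance,
    and the test statistic is F(1, df_resid) = (slope / SE)^2.
    """
    if "sex_x_age" not in fit3.params.index:
        raise ValueError("simple_slopes requires a model-3 fit with a sex_x_age term")
    V = fit3.cov_params
    rows = []
    for sex, label in ((0, "boys"), (1, "girls")):
        w = pd.Series(0.0, index=fit3.params.index)
        w["age_z"] = 1.0
        w["sex_x_age"] = float(sex)
        slope = float(w @ fit3.params)
        se = float(np.sqrt(w @ V @ w))
        fstat = (slope / se) ** 2 if se > 0 else np.inf
        p = float(sps.f.sf(fstat, 1, fit3.df_resid))
        rows.append(
            {"sex": sex, "group": label, "slope_ms": slope, "se": se,
             "f": fstat, "df": (1, int(fit3.df_resid)), "p": p}
        )
    return pd.DataFrame(rows)


@dataclass
class RoSResult:
    sex_group: str
    direction: str  # significant_above | significant_below | never | always
    boundary_age_months: float | None  # first significant month on the grid
    boundary_age_months_continuous: float | None  # Johnson-Neyman root
    estimate_at_boundary_ms: float | None
    ci95_at_boundary_ms: tuple[float, float] | None
    alpha: float = 0.05


def _effect_and_var(fit3: ModelFit, sex: int, z: np.ndarray, covariates: dict):
    """Model-implied outcome and its variance along a standardized-age axis."""
    idx = fit3.params.index
    base = pd.Series(0.0, index=idx)
    base["const"] = 1.0
    if "sex" in idx:
        base["sex"] = float(sex)
    for name, value in covariates.items():
        if name in idx:
            base[name] = float(value)
        if name == "raven_z" and "sex_x_raven" in idx:
            base["sex_x_raven"] = float(sex) * float(value)
    slope = pd.Series(0.0, index=idx)
    slope["age_z"] = 1.0
    if "sex_x_age" in idx:
        slope["sex_x_age"] = float(sex)

    b = fit3.params.to_numpy()
    V = fit3.cov_params.to_numpy()
    u = base.to_numpy()
    w = slope.to_numpy()
    A = u @ b
    B = w @ b
    v0 = u @ V @ u
    v1 = u @ V @ w
    v2 = w @ V @ w
    est = A + B * z
    var = v0 + 2 * v1 * z + v2 * z * z
    return est, var, (A, B, v0, v1, v2)


def johnson_neyman(
    fit3: ModelFit,
    sex_group: int,
    age_mean_months: float,
    age_sd_months: float,
    age_range_months: tuple[float, float],
    covariate_values: dict | None = None,
    grid_step_months: float = 1.0,
    alpha: float = 0.05,
) -> RoSResult:
    """Region of significance of the model-implied effect along age.

    Evaluates the predicted outcome for the given sex (other covariates
    at their centered means by default) with pointwise ``1 - alpha``
    CIs from the coefficient covariance, on a monthly age grid over the
    observed range; reports the boundary month at which the CI first
    excludes zero, together with the continuous Johnson-Neyman root of
    |estimate| = t_crit * SE.  The headline boundary is the grid month
    (ages are recorded in whole months); the continuous root is kept for
    cross-checking.
    """
    covariates = covariate_values or {}
    lo, hi = age_range_months
    months = np.arange(lo, hi + 1e-9, grid_step_months)
    z = (months - age_mean_months) / age_sd_months
    est, var, (A, B, v0, v1, v2) = _effect_and_var(fit3, sex_group, z, covariates)
    tcrit = sps.t.ppf(1 - alpha / 2, fit3.df_resid)
    half = tcrit * np.sqrt(var)
    sig = np.abs(est) > half

    label = {0: "boys", 1: "girls"}.get(sex_group, str(sex_group))

    # continuous Johnson-Neyman boundary: roots of (A+Bz)^2 = t^2 (v0+2v1 z+v2 z^2)
    t2 = tcrit**2
    qa = B * B - t2 * v2
    qb = 2 * (A * B - t2 * v1)
    qc = A * A - t2 * v0
    roots = np.roots([qa, qb, qc]) if abs(qa) > 1e-300 else (
        np.array([-qc / qb]) if abs(qb) > 0 else np.array([])
    )
    real = sorted(float(r.real) for r in np.atleast_1d(roots) if abs(r.imag) < 1e-8)
    zlo, zhi = (lo - age_mean_months) / age_sd_months, (hi - age_mean_months) / age_sd_months
    in_range = [r for r in real if zlo <= r <= zhi]
    continuous = age_mean_months + in_range[0] * age_sd_months if in_range else None

    if sig.all():
        return RoSResult(label, "always", None, continuous, None, None, alpha)
    if not sig.any():
        return RoSResult(label, "never", None, continuous, None, None, alpha)
    first = int(np.argmax(sig))
    last = len(sig) - 1 - int(np.argmax(sig[::-1]))
    if sig[-1] and not sig[0]:
        direction, b_idx = "significant_above", first
    elif sig[0] and not sig[-1]:
        direction, b_idx = "significant_below", last
    else:
        direction, b_idx = "significant_above", first  # disjoint regions: report onset
    b_month = float(months[b_idx])
    b_est = float(est[b_idx])
    ci = (float(est[b_idx] - half[b_idx]), float(est[b_idx] + half[b_idx]))
    return RoSResult(label, direction, b_month, continuous, b_est, ci, alpha)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(
    cohort: pd.DataFrame,
    columns: list[str],
    method: str = "pearson",
) -> dict:
    """Zero-order correlations with BH-adjusted two-tailed p-values.

    Pairwise deletion per cell; the BH step-up is applied once across
    the unique off-diagonal p-values of the table.  Returns ``r``,
    ``p_raw``, ``p_adj`` and ``n`` frames.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=columns, columns=columns)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            sub = cohort[[columns[i], columns[j]]].dropna()
            m = len(sub)
            n.iloc[i, j] = n.iloc[j, i] = m
            if m < 3:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            x = sub.iloc[:, 0].astype(float)
            y = sub.iloc[:, 1].astype(float)
            if x.std() == 0 or y.std() == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            if method == "pearson":
                rv, pv = sps.pearsonr(x, y)
            else:
                rv, pv = sps.spearmanr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
            pairs.append((i, j))
            pvals.append(pv)
    p_adj = p.copy()
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), a in zip(pairs, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
    return {"r": r, "p_raw": p, "p_adj": p_adj, "n": n, "method": method}


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# SES factor
# ---------------------------------------------------------------------------

def ses_factor(indicators: pd.DataFrame, income_column: str | None = None) -> dict:
    """One-factor maximum-likelihood factor analysis with regression scores.

    Indicators (typically mother education years, household income,
    rooms, cars) are standardized internally; loadings are reported on
    the standardized scale and the sign is oriented so the income
    indicator (by name, else the indicator with the largest absolute
    loading) loads positively.  Scores are Thomson regression-method
    factor scores, re-standardized to sample SD 1.  A loading at or
    beyond |1| (Heywood case) is clipped and flagged with a warning.
    """
    data = indicators.dropna()
    if len(data) < 20:
        raise ValueError("ses_factor needs >= 20 complete rows")
    Z = (data - data.mean()) / data.std(ddof=1)
    fa = FactorAnalysis(n_components=1, random_state=0)
    fa.fit(Z.to_numpy())
    loadings = pd.Series(fa.components_[0], index=data.columns)

    if income_column is None:
        candidates = [c for c in data.columns if "income" in str(c).lower()]
        income_column = candidates[0] if candidates else loadings.abs().idxmax()
    if loadings[income_column] < 0:
        loadings = -loadings
        flip = -1.0
    else:
        flip = 1.0

    heywood = bool((loadings.abs() >= 1.0).any())
    if heywood:
        warnings.warn("Heywood case: loading magnitude >= 1; clipped", RuntimeWarning)
        loadings = loadings.clip(-1.0, 1.0)

    scores = flip * fa.transform(Z.to_numpy()).ravel()
    scores = scores / np.std(scores, ddof=1)
    score_series = pd.Series(scores, index=data.index, name="ses_score")
    return {"loadings": loadings, "scores": score_series, "heywood": heywood, "n": len(data)}


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    r_squared: float
    n_predictors: int
    alpha: float
    target_power: float
    required_n: int
    achieved_power: float


def regression_power(n: int, r_squared: float, n_predictors: int, alpha: float = 0.05) -> float:
    """Power of the fixed-model multiple-regression F test at sample size n.

    Effect size f^2 = R^2 / (1 - R^2); the test statistic under the
    alternative is noncentral F(u, n-u-1) with noncentrality f^2 * n.
    """
    u = n_predictors
    df2 = n - u - 1
    if df2 < 1:
        return 0.0
    f2 = r_squared / (1.0 - r_squared)
    fcrit = sps.f.ppf(1 - alpha, u, df2)
    return float(sps.ncf.sf(fcrit, u, df2, f2 * n))


def required_sample_size(
    r_squared: float,
    n_predictors: int,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_cap: int = 1_000_000,
) -> PowerSpec:
    """Smallest N whose regression-F power reaches the target.

    Power is monotone in N, so a linear scan from the smallest
    identifiable model suffices (a bracketed doubling keeps the scan
    short for tiny effects).
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    lo = n_predictors + 2
    hi = lo
    while regression_power(hi, r_squared, n_predictors, alpha) < target_power:
        hi *= 2
        if hi > n_cap:
            raise ValueError(f"target power unreachable below N = {n_cap}")
    while lo < hi:
        mid = (lo + hi) // 2
        if regression_power(mid, r_squared, n_predictors, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return PowerSpec(
        r_squared=r_squared,
        n_predictors=n_predictors,
        alpha=alpha,
        target_power=target_power,
        required_n=lo,
        achieved_power=regression_power(lo, r_squared, n_predictors, alpha),
    )
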