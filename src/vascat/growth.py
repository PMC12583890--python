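"""Longitudinal growth-curve models on the per-subject indices.

Each outcome (Slope or Response Variability, one value per participant-year)
is modeled with a linear mixed-effects model:

    y_jt = b0 + b1 year_c + b2 grade_c + b3 (year_c x grade_c)
           + u0_j + u1_j year_c + e_jt

with testing year (1-4, within-subject) and start grade (1-3, between-
subject) centered at the grand means of the included rows, and the maximal
random-effects structure on participants: a random intercept and a random
slope of testing year, with their correlation.  Estimation is restricted
maximum likelihood via statsmodels MixedLM; standardized betas come from a
full refit on z-scored outcome and predictors.

Degrees of freedom for t statistics use the residual convention
df = N - (n fixed effects + n variance-covariance parameters) by default; a
between-within (containment) convention is available.  Both are documented
conventions rather than exact finite-sample theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMParams


class ModelingError(ValueError):
    """Raised for a growth dataset the model cannot be fit to."""


TERMS = ["Intercept", "year_c", "grade_c", "year_c:grade_c"]


def build_growth_dataset(indices: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Assemble the growth-model table for one outcome.

    Centers testing year and start grade at the grand means of the included
    (screened-in) rows and adds their product as the interaction term.
    """
    if outcome not in indices.columns:
        raise ModelingError(f"outcome column {outcome!r} not present")
    data = indices.dropna(subset=[outcome]).copy()
    year_counts = data.groupby("subject_id")["testing_year"].nunique()
    if (year_counts < 2).all():
        raise ModelingError("need at least one subject with >= 2 years")
    data["outcome"] = data[outcome].astype(float)
    for raw, cen in [("testing_year", "year_c"), ("start_grade", "grade_c")]:
        vals = data[raw].astype(float)
        if vals.nunique() < 2:
            raise ModelingError(f"predictor {raw!r} is constant")
        data[cen] = vals - vals.mean()
    data["year_x_grade"] = data["year_c"] * data["grade_c"]
    data.attrs["year_mean"] = float(data["testing_year"].mean())
    data.attrs["grade_mean"] = float(data["start_grade"].mean())
    data.attrs["outcome_name"] = outcome
    return data


@dataclass
class GrowthFit:
    """Fixed-effect table, variance components and metadata for one outcome."""

    table: pd.DataFrame           # term, B, SE, CI_low, CI_high, t, df, p, beta_std, ...
    vc: dict                      # var_intercept, var_year_slope, corr, resid_var
    meta: dict                    # estimation method, convergence, fallbacks
    year_mean: float
    grade_mean: float
    fe_cov: np.ndarray = field(repr=False, default=None)  # cov of fixed effects

    @property
    def coef(self) -> pd.Series:
        return self.table.set_index("term")["B"]


def _fit_mixedlm(data: pd.DataFrame, structure: str):
    """Fit one random-effects structure; returns (result, n_vc_params)."""
    formula = "outcome ~ year_c * grade_c"
    if structure == "maximal":
        md = smf.mixedlm(formula, data, groups=data["subject_id"], re_formula="~year_c")
        return md.fit(reml=True, method=["lbfgs", "powell"]), 4
    if structure == "uncorrelated":
        md = smf.mixedlm(formula, data, groups=data["subject_id"], re_formula="~year_c")
        free = MixedLMParams.from_components(
            fe_params=np.ones(4), cov_re=np.eye(2)
        )
        return md.fit(reml=True, free=free, method=["lbfgs", "powell"]), 3
    if structure == "intercept":
        md = smf.mixedlm(formula, data, groups=data["subject_id"])
        return md.fit(reml=True, method=["lbfgs", "powell"]), 2
    if structure == "ols":
        # terminal rung: no random effects at all (handles degenerate,
        # zero-residual data exactly)
        res = smf.ols(formula, data).fit()
        return res, 1
    raise ValueError(structure)


def _fe_arrays(res) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(res, "fe_params"):
        return np.asarray(res.fe_params, float), np.asarray(res.bse_fe, float)
    return np.asarray(res.params, float), np.asarray(res.bse, float)


def _try_ladder(data: pd.DataFrame):
    """Maximal structure first; fall back (flagged) if it will not converge."""
    notes = []
    for structure in ("maximal", "uncorrelated", "intercept", "ols"):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                res, n_vc = _fit_mixedlm(data, structure)
            converged = bool(getattr(res, "converged", True))
            singular = any("singular" in str(w.message).lower() for w in wlist)
            if converged and np.all(np.isfinite(_fe_arrays(res)[1])):
                if singular:
                    notes.append(f"{structure}: boundary (singular) fit")
                return res, n_vc, structure, notes
            notes.append(f"{structure}: did not converge")
        except Exception as exc:
            notes.append(f"{structure}: {type(exc).__name__}: {exc}")
    raise ModelingError("no random-effects structure converged: " + "; ".join(notes))


def _extract_vc(res, structure: str) -> dict:
    if structure == "ols":
        return {
            "var_intercept": 0.0,
            "var_year_slope": 0.0,
            "corr_intercept_slope": 0.0,
            "resid_var": float(res.scale),
        }
    scale = float(res.scale)
    cov_re = np.atleast_2d(np.asarray(res.cov_re)) * 1.0
    var_int = float(cov_re[0, 0])
    if structure in ("maximal", "uncorrelated") and cov_re.shape[0] > 1:
        var_slope = float(cov_re[1, 1])
        cov_is = float(cov_re[0, 1])
        denom = np.sqrt(var_int * var_slope)
        corr = float(cov_is / denom) if denom > 0 else 0.0
    else:
        var_slope, corr = 0.0, 0.0
    return {
        "var_intercept": var_int,
        "var_year_slope": var_slope,
        "corr_intercept_slope": float(np.clip(corr, -1.0, 1.0)),
        "resid_var": scale,
    }


def _dof(data: pd.DataFrame, n_vc: int, df_method: str) -> float:
    n = len(data)
    if df_method == "residual":
        return float(n - (4 + n_vc))
    if df_method == "between_within":
        # within-subject predictors: observations minus subjects minus slopes
        return float(n - data["subject_id"].nunique() - 3)
    raise ValueError(f"unknown df_method {df_method!r}")


def _term_table(res, df: float) -> pd.DataFrame:
    B, SE = _fe_arrays(res)
    t = np.zeros_like(B)
    nz = SE > 0
    t[nz] = B[nz] / SE[nz]
    t[~nz & (B != 0)] = np.sign(B[~nz & (B != 0)]) * np.inf
    crit = stats.t.ppf(0.975, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "term": TERMS,
            "B": B,
            "SE": SE,
            "CI_low": B - crit * SE,
            "CI_high": B + crit * SE,
            "t": t,
            "df": df,
            "p": p,
        }
    )


def fit_growth_model(
    data: pd.DataFrame, *, df_method: str = "residual", standardize: bool = True
) -> GrowthFit:
    """Fit the growth model for one outcome and assemble the coefficient table.

    Falls back from the maximal random-effects structure to uncorrelated
    random effects, then to a random intercept only, if estimation fails;
    every fallback or boundary fit is flagged in ``meta``, never silent.
    """
    res, n_vc, structure, notes = _try_ladder(data)
    df = _dof(data, n_vc, df_method)
    table = _term_table(res, df)

    if standardize:
        zdata = data.copy()
        sds = {}
        for col in ("outcome", "year_c", "grade_c"):
            sd = float(zdata[col].std(ddof=1))
            sds[col] = sd
            zdata[col] = (zdata[col] - zdata[col].mean()) / sd
        zdata["year_x_grade"] = zdata["year_c"] * zdata["grade_c"]
        try:
            zres, _, zstructure, znotes = _try_ladder(zdata)
            zt = _term_table(zres, df)
            table["beta_std"] = zt["B"]
            table["beta_CI_low"] = zt["CI_low"]
            table["beta_CI_high"] = zt["CI_high"]
        except ModelingError as exc:
            notes.append(f"standardization failed: {exc}")
            table["beta_std"] = np.nan
            table["beta_CI_low"] = np.nan
            table["beta_CI_high"] = np.nan

    meta = {
        "estimation": "REML (statsmodels MixedLM)",
        "structure": structure,
        "df_method": df_method,
        "df": df,
        "n_obs": int(len(data)),
        "n_subjects": int(data["subject_id"].nunique()),
        "converged": True,
        "notes": notes,
        "outcome": data.attrs.get("outcome_name", "outcome"),
    }
    return GrowthFit(
        table=table,
        vc=_extract_vc(res, structure),
        meta=meta,
        year_mean=data.attrs.get("year_mean", float(data["testing_year"].mean())),
        grade_mean=data.attrs.get("grade_mean", float(data["start_grade"].mean())),
        fe_cov=np.asarray(res.cov_params())[:4, :4],
    )


def marginal_predictions(
    fit: GrowthFit,
    years: np.ndarray | list,
    grades: np.ndarray | list,
    *,
    observed_year_range: tuple[float, float] = (1, 4),
    observed_grade_range: tuple[float, float] = (1, 3),
) -> pd.DataFrame:
    """Fixed-effect predictions on a testing-year x start-grade grid.

    Predicted outcome is the fixed-effect linear combination at each grid
    point with delta-method confidence intervals from the fixed-effect
    covariance.  Grid points outside the observed predictor range produce a
    warning, not an error.
    """
    years = np.asarray(years, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if years.min() < observed_year_range[0] or years.max() > observed_year_range[1]:
        warnings.warn("prediction grid extends beyond observed testing years")
    if grades.min() < observed_grade_range[0] or grades.max() > observed_grade_range[1]:
        warnings.warn("prediction grid extends beyond observed start grades")

    B = fit.table["B"].to_numpy()
    df = float(fit.table["df"].iloc[0])
    crit = stats.t.ppf(0.975, df)
    rows = []
    for g in grades:
        for yr in years:
            yc = yr - fit.year_mean
            gc = g - fit.grade_mean
            xvec = np.array([1.0, yc, gc, yc * gc])
            pred = float(xvec @ B)
            se = float(np.sqrt(xvec @ fit.fe_cov @ xvec))
            rows.append(
                {
                    "testing_year": yr,
                    "start_grade": g,
                    "predicted": pred,
                    "SE": se,
                    "CI_low": pred - crit * se,
                    "CI_high": pred + crit * se,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    """First-session practice contrast: (year1->2 change) minus mean later change."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    n_subjects: int


def first_session_contrast(indices: pd.DataFrame, outcome: str) -> ContrastResult:
    """Test for a one-time practice jump after the first session.

    For every subject with year 1, year 2 and at least one later consecutive
    pair, computes (y2 - y1) minus the mean of later year-to-year changes; a
    steady (linear) developmental trend gives ~0, while task-learning
    concentrated between the first two sessions gives a large value of the
    sign of the jump.  The contrast is averaged over subjects with a t-based
    interval.
    """
    per_subject = []
    for sid, grp in indices.groupby("subject_id"):
        series = grp.set_index("testing_year")[outcome].sort_index()
        years = series.index.to_numpy()
        if not {1, 2} <= set(years):
            continue
        d12 = series.loc[2] - series.loc[1]
        later = [
            series.loc[y + 1] - series.loc[y]
            for y in years
            if y >= 2 and (y + 1) in series.index
        ]
        if not later:
            continue
        per_subject.append(d12 - float(np.mean(later)))
    if len(per_subject) < 2:
        raise ModelingError("practice contrast needs >= 3 years for >= 2 subjects")
    arr = np.asarray(per_subject, dtype=float)
    n = arr.size
    est = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(n))
    df = n - 1
    if se == 0.0:
        t = 0.0 if est == 0.0 else np.inf * np.sign(est)
        p = 1.0 if est == 0.0 else 0.0
        crit = 0.0
    else:
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        crit = stats.t.ppf(0.975, df)
    return ContrastResult(
        estimate=est,
        se=se,
        ci_low=est - crit * se,
        ci_high=est + crit * se,
        t=float(t),
        df=float(df),
        p=p,
        n_subjects=n,
    )


def simulate_growth_dataset(
    n_subjects: int,
    *,
    b0: float = 0.0,
    b_year: float = 0.0,
    b_grade: float = 0.0,
    b_interaction: float = 0.0,
    sd_intercept: float = 1.0,
    sd_year_slope: float = 0.0,
    sd_resid: float = 1.0,
    years: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a growth dataset from the linear mixed model.

    Used by the calibration suites (type-I error, CI coverage): subjects are
    assigned round-robin to start grades 1-3 and observed for all years.
    """
    rng = np.random.default_rng(seed)
    rows = []
    grades = np.arange(n_subjects) % 3 + 1
    u0 = rng.normal(0, sd_intercept, n_subjects)
    u1 = rng.normal(0, sd_year_slope, n_subjects)
    year_mean = (1 + years) / 2.0
    for i in range(n_subjects):
        gc = grades[i] - 2.0
        for yr in range(1, years + 1):
            yc = yr - year_mean
            y = (
                b0 + b_year * yc + b_grade * gc + b_interaction * yc * gc
                + u0[i] + u1[i] * yc + rng.normal(0, sd_resid)
            )
            rows.append(
                {
                    "subject_id": f"G{i:04d}",
                    "start_grade": int(grades[i]),
                    "testing_year": yr,
                    "value": y,
                }
            )
    return pd.DataFrame(rows)
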