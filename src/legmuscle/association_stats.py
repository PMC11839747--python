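"""Association models for muscle measures: standardized multiple regression,
partial Pearson correlations, estimated marginal means by sex, hierarchical
regression with ΔR², and residual diagnostics.

The modelling conventions mirror common practice for cohort muscle-health
analyses:

* Standardized models z-score the outcome and every predictor (sex is coded
  female=0 / male=1 and then z-scored like any other column) with n-1 SDs,
  so a coefficient is the expected SD change in the outcome per SD of the
  predictor. With a single predictor this reduces to the Pearson r.
* Estimated marginal means (EMMs) come from the *unstandardized* model
  y ~ age + bmi + sex, predicting each sex at the sample-mean age and BMI,
  with delta-method standard errors.
* Hierarchical fits add one muscle measure to the age+BMI+sex base model;
  ΔR² = R²_full - R²_base is tested with F_change = ΔR²(n-p_full-1)/(1-R²_full)
  on (1, n-p_full-1) df, which for a single added term equals the squared
  t of that term.

Missing values are handled by listwise deletion with a logged count. No
multiple-testing correction is applied across muscles: p-values are
reported per muscle at face value, and users comparing many muscles should
account for that themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

SEX_CODES = {"female": 0.0, "male": 1.0}


def _encode_sex(col: pd.Series) -> pd.Series:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        bad = set(col.dropna().unique()) - set(SEX_CODES)
        if bad:
            raise ValueError(f"unrecognised sex codes: {sorted(bad)}")
        return col.map(SEX_CODES).astype(float)
    return col.astype(float)


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"predictor {name!r} is constant (zero SD); cannot standardize")
    return (v - v.mean()) / sd


def _prepare(y, X: pd.DataFrame, outcome_name: str) -> tuple[np.ndarray, pd.DataFrame]:
    X = X.copy()
    if "sex" in X.columns:
        X["sex"] = _encode_sex(X["sex"])
    df = X.astype(float)
    df[outcome_name] = np.asarray(y, dtype=float)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("listwise deletion dropped %d of %d rows", n0 - len(df), n0)
    return df[outcome_name].to_numpy(), df.drop(columns=[outcome_name])


@dataclass(frozen=True)
class ModelFit:
    """OLS fit on standardized variables: coefficients, inference, fit stats."""

    outcome: str
    predictors: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    f_stat: float
    f_pvalue: float
    r2: float
    n: int
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)

    @property
    def df_model(self) -> int:
        return len(self.predictors)

    @property
    def df_resid(self) -> int:
        return self.n - len(self.predictors) - 1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta, "se": self.se,
            "t": self.tvalues, "p": self.pvalues,
        }, index=list(self.predictors))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tab = self.summary().to_string(float_format=lambda v: f"{v:0.4f}")
        return (f"Standardized OLS: {self.outcome} ~ {' + '.join(self.predictors)}\n"
                f"{tab}\nR2 = {self.r2:0.4f}, F({self.df_model}, {self.df_resid}) "
                f"= {self.f_stat:0.3f}, p = {self.f_pvalue:0.4g}, n = {self.n}")


def fit_standardized_lm(y, X: pd.DataFrame, outcome_name: str = "y") -> ModelFit:
    """Multiple linear regression with all variables z-scored (n-1 SDs)."""
    yv, Xd = _prepare(y, X, outcome_name)
    preds = tuple(Xd.columns)
    if len(yv) <= len(preds) + 1:
        raise ValueError(f"n={len(yv)} too small for {len(preds)} predictors")
    yz = _zscore(yv, outcome_name)
    Xz = np.column_stack([_zscore(Xd[c].to_numpy(), c) for c in preds])
    res = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return ModelFit(
        outcome=outcome_name, predictors=preds,
        beta=res.params[1:].copy(), se=res.bse[1:].copy(),
        tvalues=res.tvalues[1:].copy(), pvalues=res.pvalues[1:].copy(),
        f_stat=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        r2=float(res.rsquared), n=int(res.nobs),
        residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues))


def partial_pearson(y, x, Z: pd.DataFrame | None = None) -> tuple[float, float]:
    """Partial Pearson correlation of y and x controlling for Z.

    Residualizes both variables on Z (with intercept) by OLS and correlates
    the residuals; with empty Z this is the plain Pearson r. The two-tailed
    p comes from t = r sqrt((n-2-|Z|)/(1-r²)) on n-2-|Z| df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if Z is None or (hasattr(Z, "shape") and getattr(Z, "shape", (0,))[-1] == 0):
        k = 0
        ry, rx = y - y.mean(), x - x.mean()
    else:
        Zd = Z.copy()
        if "sex" in Zd.columns:
            Zd["sex"] = _encode_sex(Zd["sex"])
        Zm = sm.add_constant(Zd.to_numpy(dtype=float))
        k = Zm.shape[1] - 1
        ry = y - Zm @ np.linalg.lstsq(Zm, y, rcond=None)[0]
        rx = x - Zm @ np.linalg.lstsq(Zm, x, rcond=None)[0]
    n = len(y)
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} controls")
    ss_y, ss_x = (ry ** 2).sum(), (rx ** 2).sum()
    if ss_x <= 1e-24 * max((x - x.mean()).var() * n, 1.0):
        raise ValueError("x has no residual variance after controls; "
                         "partial correlation undefined")
    if ss_y <= 1e-24 * max(((y - y.mean()) ** 2).sum(), 1.0):
        # y fully explained by the controls: nothing left to correlate
        return 0.0, 1.0
    r = float((ry * rx).sum() / np.sqrt(ss_y * ss_x))
    df = n - 2 - k
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


@dataclass(frozen=True)
class MarginalMeans:
    emm_female: float
    emm_male: float
    se_female: float
    se_male: float
    n: int


def emmeans_by_sex(y, X: pd.DataFrame) -> MarginalMeans:
    """Estimated marginal means of y by sex at sample-mean age and BMI.

    Fits the unstandardized OLS y ~ covariates + sex and predicts each sex
    with all other covariates at their sample means; SEs by the delta
    method from the coefficient covariance.
    """
    if "sex" not in X.columns:
        raise ValueError("X must contain a 'sex' column")
    yv, Xd = _prepare(y, X, "y")
    sex = Xd["sex"].to_numpy()
    if len(np.unique(sex)) < 2:
        raise ValueError("both sexes must be present to compute marginal means")
    cols = [c for c in Xd.columns if c != "sex"] + ["sex"]
    Xm = sm.add_constant(Xd[cols].to_numpy(dtype=float))
    res = sm.OLS(yv, Xm).fit()
    x_ref = np.r_[1.0, Xd[cols[:-1]].mean().to_numpy(dtype=float), 0.0]
    out = {}
    for label, code in (("female", 0.0), ("male", 1.0)):
        x = x_ref.copy()
        x[-1] = code
        out[label] = (float(x @ res.params),
                      float(np.sqrt(x @ res.cov_params() @ x)))
    return MarginalMeans(emm_female=out["female"][0], emm_male=out["male"][0],
                         se_female=out["female"][1], se_male=out["male"][1],
                         n=int(res.nobs))


@dataclass(frozen=True)
class HierarchicalFit:
    """Base (age+BMI+sex) vs full (base + one muscle measure) comparison."""

    base: ModelFit
    full: ModelFit
    added: str
    delta_r2: float
    f_change: float
    p_change: float

    def summary(self) -> pd.DataFrame:
        df = self.full.summary()
        df.loc["(model)"] = [np.nan, np.nan, np.nan, np.nan]
        return df


def hierarchical_lm(y, base: pd.DataFrame, addition, addition_name: str = "measure",
                    outcome_name: str = "y") -> HierarchicalFit:
    """Hierarchical regression: variance in y explained by one added measure
    beyond the base covariates, as ΔR² with an F-change test."""
    Xfull = base.copy()
    Xfull[addition_name] = np.asarray(addition, dtype=float)
    # align listwise deletion across both models
    yv, Xd = _prepare(y, Xfull, outcome_name)
    if len(yv) <= len(Xd.columns) + 2:
        raise ValueError(f"n={len(yv)} too small for the hierarchical comparison")
    base_cols = [c for c in Xd.columns if c != addition_name]
    fit_base = fit_standardized_lm(yv, Xd[base_cols], outcome_name)
    fit_full = fit_standardized_lm(yv, Xd, outcome_name)
    delta = fit_full.r2 - fit_base.r2
    df2 = fit_full.df_resid
    denom = 1.0 - fit_full.r2
    f_change = delta * df2 / denom if denom > 0 else np.inf
    p = float(stats.f.sf(f_change, 1, df2)) if np.isfinite(f_change) else 0.0
    return HierarchicalFit(base=fit_base, full=fit_full, added=addition_name,
                           delta_r2=float(delta), f_change=float(f_change),
                           p_change=p)


@dataclass(frozen=True)
class ResidualDiagnostics:
    shapiro_w: float
    shapiro_p: float
    scale_location_r: float
    n: int


def residual_diagnostics(fit: ModelFit) -> ResidualDiagnostics:
    """Normality (Shapiro–Wilk) and a scale-location heteroscedasticity summary.

    The scale-location statistic is the Pearson correlation between fitted
    values and sqrt(|standardized residuals|); values near 0 indicate
    homoscedasticity.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    n = len(resid)
    if not (3 <= n <= 5000):
        raise ValueError(f"residual diagnostics support 3 <= n <= 5000, got {n}")
    sd = resid.std(ddof=1)
    if sd <= 1e-10:  # outcome is standardized, so this means a perfect fit
        raise ValueError("constant residuals: diagnostics undefined")
    w, p = stats.shapiro(resid)
    scaled = np.sqrt(np.abs(resid / sd))
    if np.ptp(fit.fitted) == 0 or np.ptp(scaled) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fit.fitted, scaled)[0, 1])
    return ResidualDiagnostics(shapiro_w=float(w), shapiro_p=float(p),
                               scale_location_r=r, n=n)


def association_tables(measures: pd.DataFrame, cohort: pd.DataFrame,
                       measure_col: str = "volume_ml") -> pd.DataFrame:
    """Per-(muscle, side) standardized age+BMI+sex model for one measure.

    Produces one row per muscle/side with standardized β (SE) and p for
    age, BMI and sex, plus the overall F, its p and R² — the per-muscle
    association table shape used throughout this package.
    """
    rows = []
    for (muscle, side), grp in measures.groupby(["muscle", "side"], sort=True):
        df = grp.merge(cohort, on="participant_id")
        if df[measure_col].isna().all():
            continue
        fit = fit_standardized_lm(df[measure_col],
                                  df[["age", "bmi", "sex"]], measure_col)
        row = {"muscle": muscle, "side": side, "n": fit.n,
               "F": fit.f_stat, "F_p": fit.f_pvalue, "r2": fit.r2}
        for i, pred in enumerate(fit.predictors):
            row[f"beta_{pred}"] = fit.beta[i]
            row[f"se_{pred}"] = fit.se[i]
            row[f"p_{pred}"] = fit.pvalues[i]
        rows.append(row)
    return pd.DataFrame(rows)


def force_tables(measures: pd.DataFrame, cohort: pd.DataFrame,
                 measure_col: str = "volume_ml") -> pd.DataFrame:
    """Hierarchical force models per muscle/side: ΔR² of one muscle measure
    for the same-side plantarflexion force beyond age+BMI+sex."""
    rows = []
    for (muscle, side), grp in measures.groupby(["muscle", "side"], sort=True):
        force_col = f"pf_{side}"
        if force_col not in cohort.columns:
            continue
        df = grp.merge(cohort, on="participant_id").dropna(
            subset=[measure_col, force_col])
        if len(df) < 8:
            logger.warning("(%s, %s): only %d usable rows, skipped", muscle, side, len(df))
            continue
        hf = hierarchical_lm(df[force_col], df[["age", "bmi", "sex"]],
                             df[measure_col], addition_name=measure_col,
                             outcome_name=force_col)
        i = hf.full.predictors.index(measure_col)
        rows.append({"muscle": muscle, "side": side, "n": hf.full.n,
                     "beta": hf.full.beta[i], "se": hf.full.se[i],
                     "F_change": hf.f_change, "p_change": hf.p_change,
                     "delta_r2": hf.delta_r2, "r2_full": hf.full.r2})
    return pd.DataFrame(rows)
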