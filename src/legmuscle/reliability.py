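"""Agreement statistics between two measurement sources.

Covers rater-vs-rater and model-vs-reference comparisons of the muscle
measures: ICC(2,1) in the Shrout–Fleiss sense (two-way random effects,
absolute agreement, single measures), Bland–Altman bias and 95% limits of
agreement with a proportional-bias regression, MAE and RMSE, and a
two-sample t-test for subgroup accuracy comparisons.

The ICC is written out from the two-way ANOVA mean squares rather than
delegated to a library, so its semantics are explicit:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with n subjects, k = 2 raters, MSR/MSC/MSE the row (subject), column
(rater) and residual mean squares. Absolute agreement penalises a constant
offset between raters, unlike a Pearson correlation. The estimate can be
negative. All standard deviations use the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _as_pairs(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an n x 2 array of paired measurements, got {arr.shape}")
    arr = arr[~np.isnan(arr).any(axis=1)]
    return arr


def icc_2_1(x) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    arr = _as_pairs(x)
    n, k = arr.shape
    if n < 3:
        raise ValueError(f"ICC(2,1) needs at least 3 complete pairs, got {n}")
    grand = arr.mean()
    if np.allclose(arr, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_intercept: float
    sd_diff: float
    n: int


def bland_altman(x) -> BlandAltman:
    """Bland–Altman bias, 95% limits of agreement and proportional-bias line.

    Differences d = col1 - col2; bias = mean(d); LoA = bias ± 1.96 sd(d);
    proportional bias from the OLS of d on the pairwise mean (col1+col2)/2.
    """
    arr = _as_pairs(x)
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"Bland–Altman needs at least 3 pairs, got {n}")
    d = arr[:, 0] - arr[:, 1]
    m = arr.mean(axis=1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(m) > 0:
        slope, intercept = np.polyfit(m, d, 1)
    else:
        slope, intercept = 0.0, bias
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd,
                       prop_bias_slope=float(slope),
                       prop_bias_intercept=float(intercept),
                       sd_diff=sd, n=n)


def agreement_report(measures_a: pd.DataFrame, measures_b: pd.DataFrame,
                     value_columns: tuple[str, ...] = ("volume_ml", "imf_pct")
                     ) -> pd.DataFrame:
    """Per-(muscle, side, measure) agreement between two measures tables.

    Joins the tables on (participant_id, muscle, side); unmatched rows are
    dropped and counted in the log. Strata with fewer than 3 complete pairs
    are reported with missing statistics.
    """
    keys = ["participant_id", "muscle", "side"]
    merged = measures_a.merge(measures_b, on=keys, suffixes=("_a", "_b"))
    n_a, n_b, n_m = len(measures_a), len(measures_b), len(merged)
    if n_m < max(n_a, n_b):
        logger.warning("agreement join kept %d of %d/%d rows", n_m, n_a, n_b)
    rows = []
    for (muscle, side), grp in merged.groupby(["muscle", "side"], sort=True):
        for col in value_columns:
            pairs = grp[[f"{col}_a", f"{col}_b"]].dropna().to_numpy(dtype=float)
            row = {"muscle": muscle, "side": side, "measure": col,
                   "n": pairs.shape[0]}
            if pairs.shape[0] < 3:
                logger.warning("stratum (%s, %s, %s): only %d pairs, skipped",
                               muscle, side, col, pairs.shape[0])
                row.update({k: np.nan for k in
                            ("icc21", "bias", "loa_low", "loa_high", "slope",
                             "intercept", "mae", "rmse")})
            else:
                ba = bland_altman(pairs)
                d = pairs[:, 0] - pairs[:, 1]
                row.update({
                    "icc21": icc_2_1(pairs),
                    "bias": ba.bias, "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high, "slope": ba.prop_bias_slope,
                    "intercept": ba.prop_bias_intercept,
                    "mae": float(np.abs(d).mean()),
                    "rmse": float(np.sqrt((d ** 2).mean())),
                })
            rows.append(row)
    return pd.DataFrame(rows)


def subgroup_compare(errors_group1, errors_group2, *, welch: bool = False
                     ) -> tuple[float, int, float]:
    """Two-tailed two-sample t-test on signed errors between two subgroups.

    Pooled-variance (Student) by default, appropriate for equal group sizes;
    set ``welch=True`` for unequal variances.

    Returns (t, df, p).
    """
    a = np.asarray(errors_group1, dtype=float)
    b = np.asarray(errors_group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, len(a) + len(b) - 2, 1.0
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), int(res.df), float(res.pvalue)
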