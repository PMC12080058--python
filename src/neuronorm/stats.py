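"""Inferential statistics on deviation scores and AD biomarkers.

Age adjustment of biomarkers uses coefficients learnt on controls only;
correlations use Pearson's r with pairwise deletion of missing values
(reporting the n actually used); group contrasts use pooled-SD Cohen's d
and Welch's unequal-variance t-test; longitudinal change uses paired
t-tests.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BIOMARKER_COLUMNS",
    "add_ptau_abeta_ratio",
    "age_adjust",
    "correlate",
    "bonferroni_threshold",
    "cohens_d",
    "welch_t",
    "paired_t",
]

BIOMARKER_COLUMNS = ["csf_ptau", "csf_ttau", "csf_abeta42", "ptau_abeta42_ratio"]


def add_ptau_abeta_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Add the p-tau / abeta42 ratio column where both are present."""
    out = table.copy()
    out["ptau_abeta42_ratio"] = out["csf_ptau"] / out["csf_abeta42"]
    return out


def age_adjust(
    biomarkers: pd.DataFrame,
    controls: pd.DataFrame,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize biomarkers on age, with coefficients fit on controls only.

    A linear fit ``biomarker ~ age`` is estimated per column on the
    control rows; the fitted line (slope and intercept) is then
    subtracted from every row of ``biomarkers``.  Cases whose true age
    slope differs from the controls' therefore retain a residual age
    association — by design, since the controls define "normal ageing".
    """
    if len(controls) < 3:
        raise ValueError("need at least 3 control rows to fit age coefficients")
    cols = columns or [c for c in BIOMARKER_COLUMNS if c in biomarkers.columns]
    out = biomarkers.copy()
    age_c = controls["age"].to_numpy(float)
    age_all = biomarkers["age"].to_numpy(float)
    for col in cols:
        y = controls[col].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(age_c)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete control rows for {col!r}")
        slope, intercept = np.polyfit(age_c[ok], y[ok], 1)
        out[col] = biomarkers[col].to_numpy(float) - (slope * age_all + intercept)
    return out


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise deletion; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    res = sps.pearsonr(x[ok], y[ok])
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cohens_d(subgroup, controls) -> float:
    """Pooled-SD Cohen's d, ``(mean(subgroup) - mean(controls)) / s_pooled``.

    Positive values mean the subgroup is higher than controls.
    """
    a = np.asarray(subgroup, dtype=float)
    b = np.asarray(controls, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    n: tuple[int, ...]


def welch_t(group_a, group_b) -> TTestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        n=(len(a), len(b)),
    )


def paired_t(baseline, followup) -> TTestResult:
    """Two-sided paired t-test (one-sample t on followup - baseline)."""
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if x.shape != y.shape:
        raise ValueError("baseline and followup must be matched pairs")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 matched pairs")
    diff = y - x
    if diff.std(ddof=1) == 0:
        if (diff == 0).all():
            return TTestResult(t=0.0, df=float(n - 1), p=1.0, n=(n,))
        raise ValueError("zero difference variance")
    res = sps.ttest_rel(y, x)
    return TTestResult(
        t=float(res.statistic), df=float(n - 1), p=float(res.pvalue), n=(n,)
    )
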