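"""Demographic and lifestyle contrasts of predicted age / aging rate.

Covers the descriptive population comparisons: one-way ANOVA across racial
groups, an (optionally outlier-trimmed) Welch t-test between sexes with an
age-adjusted ANCOVA variant, and per-lifestyle-factor contrasts of
predicted biological age within chronological age strata, reported as mean
difference (delta, years) with 95% CI and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diffexpr import welch_t_test

__all__ = ["ContrastResult", "cohens_d", "anova_by_group", "sex_contrast",
           "lifestyle_contrasts", "significance_stars"]

DEFAULT_AGE_STRATA = ((40.0, 49.0), (50.0, 59.0), (60.0, 69.0))


@dataclass
class ContrastResult:
    grouping: str
    stratum: str
    n_a: int
    n_b: int
    delta: float               # mean(A) - mean(B)
    ci_lower: float
    ci_upper: float
    cohen_d: float
    statistic: float
    p: float
    ancova_coef: float | None = None
    ancova_p: float | None = None
    empty: bool = False


def cohens_d(x, y) -> float:
    """Standardized mean difference with pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def anova_by_group(values, groups) -> tuple[float, float]:
    """One-way ANOVA F and p across the levels of ``groups``."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def _trim(values: np.ndarray, fraction: float) -> np.ndarray:
    if fraction <= 0:
        return values
    k = int(np.floor(fraction * len(values)))
    if k == 0:
        return values
    return np.sort(values)[k:-k]


def _welch_ci(x, y, alpha: float = 0.05) -> tuple[float, float]:
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        delta = x.mean() - y.mean()
        return float(delta), float(delta)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(se2)
    delta = x.mean() - y.mean()
    return float(delta - half), float(delta + half)


def sex_contrast(values, sex, ages=None, trim: float = 0.0) -> ContrastResult:
    """Male-vs-female contrast by Welch t-test, optionally with symmetric
    per-group trimming of extreme values, plus an age-adjusted ANCOVA
    (linear model value ~ sex + age) when ``ages`` is given."""
    values = np.asarray(values, float)
    sex = np.asarray(sex)
    levels = sorted(pd.unique(sex))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 sexes, got {levels}")
    a = _trim(values[sex == levels[1]], trim)   # e.g. male
    b = _trim(values[sex == levels[0]], trim)   # e.g. female
    t, _, p = welch_t_test(a, b)
    lo, hi = _welch_ci(a, b)
    result = ContrastResult(
        grouping="sex", stratum=f"{levels[1]}-vs-{levels[0]}",
        n_a=len(a), n_b=len(b), delta=float(a.mean() - b.mean()),
        ci_lower=lo, ci_upper=hi, cohen_d=cohens_d(a, b), statistic=t, p=p)
    if ages is not None:
        ages = np.asarray(ages, float)
        ind = (sex == levels[1]).astype(float)
        fit = sm.OLS(values, sm.add_constant(np.column_stack([ind, ages]))).fit()
        result.ancova_coef = float(fit.params[1])
        result.ancova_p = float(fit.pvalues[1])
    return result


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def lifestyle_contrasts(predicted_age, participants: pd.DataFrame,
                        factors, age_strata=DEFAULT_AGE_STRATA
                        ) -> pd.DataFrame:
    """Unhealthy-vs-healthy contrasts of predicted age per factor and age
    stratum.

    ``participants`` must carry ``chronological_age`` and a 0/1
    ``{factor}_flag`` column per factor (1 = unhealthy). Delta is
    mean(unhealthy) - mean(healthy). Strata with an empty group are kept
    in the table flagged ``empty`` rather than dropped.
    """
    predicted_age = np.asarray(predicted_age, float)
    age = participants["chronological_age"].to_numpy(float)
    rows = []
    for factor in factors:
        flag = participants[f"{factor}_flag"].to_numpy(float)
        for lo_age, hi_age in age_strata:
            stratum = f"{lo_age:.0f}-{hi_age:.0f}"
            in_stratum = (age >= lo_age) & (age <= hi_age)
            unhealthy = predicted_age[in_stratum & (flag == 1)]
            healthy = predicted_age[in_stratum & (flag == 0)]
            if len(unhealthy) < 2 or len(healthy) < 2:
                rows.append(ContrastResult(
                    grouping=factor, stratum=stratum, n_a=len(unhealthy),
                    n_b=len(healthy), delta=np.nan, ci_lower=np.nan,
                    ci_upper=np.nan, cohen_d=np.nan, statistic=np.nan,
                    p=np.nan, empty=True).__dict__)
                continue
            t, _, p = welch_t_test(unhealthy, healthy)
            lo, hi = _welch_ci(unhealthy, healthy)
            rows.append(ContrastResult(
                grouping=factor, stratum=stratum,
                n_a=len(unhealthy), n_b=len(healthy),
                delta=float(unhealthy.mean() - healthy.mean()),
                ci_lower=lo, ci_upper=hi,
                cohen_d=cohens_d(unhealthy, healthy),
                statistic=t, p=p).__dict__)
    table = pd.DataFrame(rows)
    table["stars"] = ["" if pd.isna(p) else significance_stars(p) for p in table["p"]]
    return table
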