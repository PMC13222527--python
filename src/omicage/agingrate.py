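"""Per-participant aging metrics derived from clock predictions.

Two standard definitions are provided: the ratio-based *aging rate*
(predicted biological age / chronological age; >1 means accelerated aging)
and the *residual age acceleration* (predicted age minus the value expected
from an OLS regression of predicted on chronological age over a reference
population). Decile stratification of either metric feeds the survival
analyses.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_aging_rate",
    "compute_residual_accel",
    "stratify_deciles",
    "orthogonality_report",
    "build_records",
]


def compute_aging_rate(predicted, chronological):
    """Aging rate = predicted / chronological age; chronological must be > 0."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if np.any(chronological <= 0):
        raise ValueError("chronological age must be positive")
    return predicted / chronological


def compute_residual_accel(records: pd.DataFrame, fit_population_ids) -> pd.Series:
    """Residual age acceleration.

    OLS of predicted on chronological age is fit over ``fit_population_ids``
    (typically the healthy training population) and the residual
    ``p - (a + b*c)`` is returned for every record. Residuals over the
    fitting population sum to zero and are orthogonal to chronological age.
    """
    fit_rows = records[records["participant_id"].isin(set(fit_population_ids))]
    if len(fit_rows) < 10:
        raise ValueError("need at least 10 fitting rows")
    c = fit_rows["chronological_age"].to_numpy(float)
    p = fit_rows["predicted_age"].to_numpy(float)
    if np.ptp(c) == 0:
        raise ValueError("degenerate chronological-age variance in fitting population")
    slope, intercept = np.polyfit(c, p, 1)
    expected = intercept + slope * records["chronological_age"].to_numpy(float)
    return pd.Series(records["predicted_age"].to_numpy(float) - expected,
                     index=records.index, name="age_accel_residual")


def build_records(participant_id, chronological_age, predicted_age,
                  fit_population_ids=None) -> pd.DataFrame:
    """Assemble the per-participant aging record table (id, c, p, rate, and
    residual acceleration if a fitting population is given)."""
    records = pd.DataFrame({
        "participant_id": np.asarray(participant_id),
        "chronological_age": np.asarray(chronological_age, float),
        "predicted_age": np.asarray(predicted_age, float),
    })
    records["aging_rate"] = compute_aging_rate(
        records["predicted_age"], records["chronological_age"])
    if fit_population_ids is not None:
        records["age_accel_residual"] = compute_residual_accel(records, fit_population_ids)
    return records


def stratify_deciles(records: pd.DataFrame, metric: str = "aging_rate"
                     ) -> tuple[list[str], list[str]]:
    """Top and bottom aging deciles.

    Group size is ``ceil(n/10)`` each. Ordering is by ``(metric,
    participant_id)`` so tie handling is deterministic; fully degenerate
    metrics fall back to identifier order with a warning.
    """
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to stratify deciles")
    m = math.ceil(n / 10)
    if records[metric].nunique() == 1:
        warnings.warn(f"metric {metric!r} is constant; deciles chosen by id order")
    ordered = records.sort_values([metric, "participant_id"], kind="mergesort")
    bottom = list(ordered["participant_id"].iloc[:m])
    top = list(ordered["participant_id"].iloc[-m:])
    return top, bottom


def orthogonality_report(records: pd.DataFrame) -> dict:
    """Descriptive diagnostics of the aging rate.

    Reports the Pearson correlation between aging rate and chronological
    age (a well-calibrated rate is near-orthogonal to age), per-sex means
    when a ``sex`` column is present, and summary moments.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    rate = records["aging_rate"].to_numpy(float)
    c = records["chronological_age"].to_numpy(float)
    if np.ptp(rate) == 0 or np.ptp(c) == 0:
        r_age = None  # correlation undefined for a constant input
    else:
        r_age = float(stats.pearsonr(rate, c).statistic)
    report = {
        "n": int(len(records)),
        "pearson_r_rate_vs_age": r_age,
        "rate_mean": float(np.mean(rate)),
        "rate_sd": float(np.std(rate, ddof=1)),
    }
    if "sex" in records.columns:
        means = records.groupby("sex")["aging_rate"].mean()
        report["rate_mean_by_sex"] = {k: float(v) for k, v in means.items()}
    return report
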