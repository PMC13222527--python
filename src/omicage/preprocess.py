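"""Cohort filtering, imputation, encoding and train/test partitioning.

The conventions implemented here follow common practice for population
biobank analyses: decimal chronological age from calendar dates (365.25
days/year), exclusion of rows with more than 20% missing omics values
(strictly greater than; exactly 20% is retained), subgroup-mean/mode
imputation of demographics (subgroup = sex x 10-year age band), omics
missing values set to zero, z-scoring with parameters estimated on the
training rows only, and one-hot encoding with a stable sorted level order.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "decimal_age",
    "filter_cohort",
    "impute",
    "encode_standardize",
    "split",
    "SplitSpec",
]

DAYS_PER_YEAR = 365.25
ESSENTIAL_DEMOGRAPHICS = ("chronological_age", "sex")
MAX_OMICS_MISSING = 0.20


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


def decimal_age(birth_date, sampling_date) -> float:
    """Chronological age as the decimal difference between two calendar
    dates, using 365.25 days per year.

    Raises ``ValueError`` if sampling precedes birth.
    """
    birth = _as_date(birth_date)
    sampling = _as_date(sampling_date)
    days = (sampling - birth).days
    if days < 0:
        raise ValueError(f"sampling date {sampling} precedes birth date {birth}")
    return days / DAYS_PER_YEAR


def filter_cohort(
    participants: pd.DataFrame,
    omics: pd.DataFrame,
    events: pd.DataFrame,
    max_omics_missing: float = MAX_OMICS_MISSING,
    essential: tuple[str, ...] = ESSENTIAL_DEMOGRAPHICS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the cohort inclusion rules and split by baseline disease status.

    Exclusions, applied in order: per-row omics missingness strictly greater
    than ``max_omics_missing``; missing essential demographics; no follow-up
    record in ``events``. Survivors are partitioned into a healthy cohort
    (no ``baseline_*`` flag set) and a disease cohort. Returns
    ``(healthy, disease, log)`` where ``log`` counts exclusions per rule.
    """
    omics = omics.set_index("participant_id")
    biomarker_cols = [c for c in omics.columns]
    frac_missing = omics[biomarker_cols].isna().mean(axis=1)
    too_missing = set(frac_missing.index[frac_missing > max_omics_missing])

    miss_essential = set(
        participants.loc[
            participants[list(essential)].isna().any(axis=1), "participant_id"
        ]
    )
    followed = set(events["participant_id"]) if len(events) else set()
    no_followup = set(participants["participant_id"]) - followed

    log = {
        "n_input": int(len(participants)),
        "excluded_omics_missing": sorted(too_missing),
        "excluded_missing_essential": sorted(miss_essential - too_missing),
        "excluded_no_followup": sorted(no_followup - too_missing - miss_essential),
    }
    excluded = too_missing | miss_essential | no_followup
    kept = participants[~participants["participant_id"].isin(excluded)].copy()

    baseline_cols = [c for c in kept.columns if c.startswith("baseline_")]
    if baseline_cols:
        has_disease = kept[baseline_cols].fillna(0).astype(float).sum(axis=1) > 0
    else:
        has_disease = pd.Series(False, index=kept.index)
    healthy = kept[~has_disease].reset_index(drop=True)
    disease = kept[has_disease].reset_index(drop=True)
    log.update(
        n_excluded=int(len(excluded)),
        n_healthy=int(len(healthy)),
        n_disease=int(len(disease)),
    )
    return healthy, disease, log


def _age_band(age: pd.Series) -> pd.Series:
    return (age // 10 * 10).astype("Int64")


def impute(
    participants: pd.DataFrame,
    omics: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing values.

    Continuous demographics get the mean of their sex x decade-of-age
    subgroup (overall mean if the subgroup has no observed value);
    categorical demographics get the subgroup mode with lexicographically
    smallest level breaking ties; missing omics cells are set to zero.
    A column with no observed value at all raises ``ValueError``.
    """
    participants = participants.copy()
    omics = omics.copy()
    group = list(zip(participants["sex"], _age_band(participants["chronological_age"])))
    group = pd.Series(group, index=participants.index)

    skip = {"participant_id", "chronological_age", "sex"}
    for col in participants.columns:
        if col in skip or not participants[col].isna().any():
            continue
        series = participants[col]
        if series.notna().sum() == 0:
            raise ValueError(f"column entirely missing: {col}")
        if pd.api.types.is_numeric_dtype(series):
            overall = series.mean()
            filled = series.groupby(group).transform(lambda s: s.fillna(s.mean()))
            participants[col] = filled.fillna(overall)
        else:
            overall_mode = sorted(series.dropna().mode())[0]

            def _fill_mode(s: pd.Series) -> pd.Series:
                observed = s.dropna()
                if observed.empty:
                    return s.fillna(overall_mode)
                return s.fillna(sorted(observed.mode())[0])

            participants[col] = series.groupby(group).transform(_fill_mode)

    value_cols = [c for c in omics.columns if c != "participant_id"]
    omics[value_cols] = omics[value_cols].fillna(0.0)
    return participants, omics


def encode_standardize(
    features: pd.DataFrame,
    train_ids,
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Z-score numeric columns and one-hot encode categorical columns.

    ``features`` must be indexed by participant identifier. Standardization
    parameters (mean, SD) are estimated on the rows in ``train_ids`` ONLY
    and applied to every row — a leakage guard for downstream model
    evaluation. Zero-variance columns become all-zeros with a warning.
    One-hot levels are the sorted training levels; an unseen level at
    transform time encodes as all-zeros for that factor. Returns the design
    matrix and a manifest recording parameters and column provenance.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("train_ids is empty")
    if categorical is None:
        categorical = [
            c for c in features.columns if not pd.api.types.is_numeric_dtype(features[c])
        ]
    numeric = [c for c in features.columns if c not in categorical]
    train = features.loc[train_ids]

    manifest: dict = {"standardize": {}, "one_hot": {}, "zero_variance": [],
                      "unseen_levels": {}}
    out = {}
    for col in numeric:
        mean = float(train[col].mean())
        sd = float(train[col].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"zero-variance column {col!r} mapped to zeros")
            manifest["zero_variance"].append(col)
            out[col] = pd.Series(0.0, index=features.index)
        else:
            out[col] = (features[col] - mean) / sd
        manifest["standardize"][col] = {"mean": mean, "sd": sd}

    for col in categorical:
        levels = sorted(train[col].dropna().unique())
        manifest["one_hot"][col] = levels
        seen = features[col].isin(levels)
        if not seen.all():
            unseen = sorted(set(features.loc[~seen, col].dropna()))
            manifest["unseen_levels"][col] = unseen
        for level in levels:
            out[f"{col}_{level}"] = (features[col] == level).astype(float)

    design = pd.DataFrame(out, index=features.index)
    manifest["columns"] = list(design.columns)
    return design, manifest


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction {self.train_fraction} outside (0, 1)")


def split(participant_ids, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simple random train/test partition of participant identifiers,
    reproducible under ``spec.seed``. Train size is ``round(fraction * n)``.
    """
    ids = np.asarray(list(participant_ids))
    if len(ids) < 5:
        raise ValueError("need at least 5 participants to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(spec.train_fraction * len(ids)))
    return ids[perm[:n_train]], ids[perm[n_train:]]
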