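"""Incident-disease risk classification with stepwise feature designs.

Four nested feature designs are compared at fixed follow-up horizons:

* model 1 — omics (proteins + metabolites) + demographics (age, sex, BMI)
  + aging rate;
* model 2 — model 1 without the aging rate;
* model 3 — omics only;
* model 4 — proteins only.

Each design is scored by stratified 10-fold cross-validated AUC with a
gradient-boosted tree classifier; the fold partition is shared across
designs so fold-level AUC differences are paired. The model-1 vs model-2
contrast isolates the incremental value of the aging rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

import lightgbm as lgb

__all__ = [
    "MODEL_DESIGNS",
    "RiskResult",
    "label_at_horizon",
    "make_folds",
    "fit_eval_risk",
    "run_design_suite",
    "compare_models",
]

#: block composition of the four designs
MODEL_DESIGNS = {
    "model1": ("proteomics", "metabolomics", "demographics", "aging_rate"),
    "model2": ("proteomics", "metabolomics", "demographics"),
    "model3": ("proteomics", "metabolomics"),
    "model4": ("proteomics",),
}

DEFAULT_CLASSIFIER_PARAMS = {
    "n_estimators": 150, "learning_rate": 0.05, "num_leaves": 31,
    "class_weight": "balanced", "verbose": -1, "n_jobs": 1,
}


@dataclass
class RiskResult:
    design: str
    disease: str
    horizon: float
    fold_aucs: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


def label_at_horizon(events_table: pd.DataFrame, disease: str, horizon: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary incident-disease labels at a follow-up horizon.

    Label 1: event within ``horizon`` years of sampling. Label 0:
    event-free with follow-up >= horizon. Participants censored before the
    horizon without an event carry no usable label and are excluded.
    Returns ``(ids, labels, excluded_ids)``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    sub = events_table[events_table["disease"] == disease]
    if len(sub) == 0:
        raise ValueError(f"disease {disease!r} absent from events table")
    t = sub["time_years"].to_numpy(float)
    e = sub["event"].to_numpy(int)
    ids = sub["participant_id"].to_numpy()
    case = (e == 1) & (t <= horizon)
    control = (t >= horizon) & ~case
    usable = case | control
    return ids[usable], case[usable].astype(int), ids[~usable]


def make_folds(labels, n_folds: int = 10, seed: int = 0):
    """Label-stratified fold partition, reusable across designs for paired
    comparison."""
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def fit_eval_risk(features: pd.DataFrame, labels, seed: int = 0,
                  n_folds: int = 10, folds=None, params: dict | None = None,
                  design: str = "custom", disease: str = "", horizon: float = 0.0,
                  ) -> RiskResult:
    """Cross-validated AUC of a gradient-boosted classifier on one design."""
    if isinstance(features, pd.DataFrame):
        X = features.reset_index(drop=True)
    else:
        arr = np.asarray(features, float)
        X = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < (n_folds if folds is None else len(folds)):
        raise ValueError("minority class smaller than the number of folds")
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    p = dict(DEFAULT_CLASSIFIER_PARAMS, **(params or {}))
    aucs = []
    for tr, te in folds:
        model = lgb.LGBMClassifier(random_state=seed, **p)
        model.fit(X.iloc[tr], y[tr])
        scores = model.predict_proba(X.iloc[te])[:, 1]
        aucs.append(roc_auc_score(y[te], scores))
    return RiskResult(design=design, disease=disease, horizon=horizon,
                      fold_aucs=np.asarray(aucs))


def run_design_suite(blocks: dict[str, pd.DataFrame], labels, seed: int = 0,
                     n_folds: int = 10, params: dict | None = None,
                     designs: dict[str, tuple[str, ...]] | None = None,
                     disease: str = "", horizon: float = 0.0,
                     ) -> dict[str, RiskResult]:
    """Evaluate every design on identical folds.

    ``blocks`` maps block name (``proteomics``, ``metabolomics``,
    ``demographics``, ``aging_rate``) to a row-aligned feature frame.
    """
    designs = designs or MODEL_DESIGNS
    y = np.asarray(labels, dtype=int)
    folds = make_folds(y, n_folds=n_folds, seed=seed)
    results = {}
    for name, block_names in designs.items():
        missing = [b for b in block_names if b not in blocks]
        if missing:
            raise ValueError(f"design {name} needs missing blocks {missing}")
        features = pd.concat([blocks[b] for b in block_names], axis=1)
        results[name] = fit_eval_risk(features, y, seed=seed, folds=folds,
                                      params=params, design=name,
                                      disease=disease, horizon=horizon)
    return results


def compare_models(results: dict[str, RiskResult], reference: str = "model2",
                   target: str = "model1") -> dict:
    """Paired fold-level AUC contrast between two designs.

    Returns the per-fold differences, their mean, and a Wilcoxon
    signed-rank p (p=1 when all differences vanish).
    """
    a = results[target].fold_aucs
    b = results[reference].fold_aucs
    if len(a) != len(b):
        raise ValueError("fold count mismatch between designs")
    diff = a - b
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff).pvalue)
    return {
        "target": target, "reference": reference,
        "fold_delta_auc": diff, "mean_delta_auc": float(diff.mean()),
        "wilcoxon_p": p,
    }


def summary_table(all_results: dict[tuple[str, float], dict[str, RiskResult]]) -> pd.DataFrame:
    """Flatten a {(disease, horizon): {design: RiskResult}} mapping into a
    tidy per-fold AUC table."""
    rows = []
    for (disease, horizon), per_design in all_results.items():
        for design, res in per_design.items():
            for fold, auc in enumerate(res.fold_aucs):
                rows.append({"disease": disease, "horizon": horizon,
                             "model": design, "fold": fold, "auc": float(auc)})
    return pd.DataFrame(rows)
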