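"""Shapley-attribution feature ranking and subset-size selection.

A baseline gradient-boosted tree regressor is trained on the full biomarker
panel against chronological age. Per-sample additive Shapley attributions
(the tree-path-dependent algorithm, computed natively by LightGBM via
``pred_contrib``) are averaged in absolute value over the training samples
to rank features. Predictive performance of the full stacking clock is then
swept over top-k subsets, and k is chosen at the start of the performance
plateau (or fixed by override).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import lightgbm as lgb

from . import clock as _clock
from sklearn.model_selection import KFold

__all__ = ["FeatureRanking", "rank_features", "attribution_matrix",
           "sweep_subset_sizes", "choose_k", "modality_counts"]

DEFAULT_GRID = tuple(range(50, 801, 50))
DEFAULT_LGBM_PARAMS = {
    "n_estimators": 500, "learning_rate": 0.05, "num_leaves": 31,
    "verbose": -1, "n_jobs": 1,
}


@dataclass
class FeatureRanking:
    """Ordered feature ranking by mean absolute Shapley attribution.

    ``table`` has columns ``feature``, ``score``, ``rank`` and is sorted by
    non-increasing score with ties broken by feature name.
    """

    table: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def top(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ValueError(f"k={k} exceeds {len(self.table)} ranked features")
        return list(self.table["feature"].iloc[:k])


def attribution_matrix(X_train: pd.DataFrame, age_train, seed: int = 0,
                       params: dict | None = None) -> tuple[np.ndarray, np.ndarray, object]:
    """Fit the baseline regressor and return per-sample Shapley attributions.

    Returns ``(contribs, expected, model)`` where ``contribs`` is
    n_samples x n_features and ``expected`` the per-sample expected model
    output, so that ``contribs.sum(axis=1) + expected == prediction``
    (the additivity identity of Shapley attributions).
    """
    p = dict(DEFAULT_LGBM_PARAMS, **(params or {}))
    if not isinstance(X_train, pd.DataFrame):
        X_train = pd.DataFrame(np.asarray(X_train, float))
        X_train.columns = [f"x{i}" for i in range(X_train.shape[1])]
    y = np.asarray(age_train, dtype=float)
    if not np.all(np.isfinite(X_train.to_numpy())) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training data")
    model = lgb.LGBMRegressor(random_state=seed, **p)
    model.fit(X_train, y)
    raw = model.predict(X_train, pred_contrib=True)
    return raw[:, :-1], raw[:, -1], model


def rank_features(X_train: pd.DataFrame, age_train, seed: int = 0,
                  params: dict | None = None) -> FeatureRanking:
    """Rank features by mean |attribution| over the training samples."""
    if len(X_train) < 50:
        raise ValueError("need at least 50 training rows to rank features")
    contribs, _, _ = attribution_matrix(X_train, age_train, seed=seed, params=params)
    names = (list(X_train.columns) if isinstance(X_train, pd.DataFrame)
             else [f"x{i}" for i in range(contribs.shape[1])])
    scores = np.mean(np.abs(contribs), axis=0)
    table = (
        pd.DataFrame({"feature": names, "score": scores})
        .sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return FeatureRanking(table=table, seed=seed,
                          params=dict(DEFAULT_LGBM_PARAMS, **(params or {})))


def sweep_subset_sizes(
    X_train: pd.DataFrame,
    age_train,
    ranking: FeatureRanking,
    grid=None,
    folds: int = 5,
    seed: int = 0,
    clock_config: "_clock.ClockConfig | None" = None,
) -> pd.DataFrame:
    """Cross-validated clock performance over top-k feature subsets.

    For each k in ``grid`` the full stacking clock is trained on each of
    ``folds`` CV training splits (shared across k) and evaluated on the
    pooled held-out predictions. Returns a table with columns
    ``k, pearson_r, rmse, mae``.
    """
    grid = sorted(grid) if grid is not None else [k for k in DEFAULT_GRID if k <= X_train.shape[1]]
    if not grid:
        raise ValueError("empty subset-size grid")
    if grid[-1] > X_train.shape[1]:
        raise ValueError(f"k={grid[-1]} exceeds {X_train.shape[1]} features")
    y = np.asarray(age_train, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(np.arange(len(y))))
    rows = []
    for k in grid:
        cols = ranking.top(k)
        Xk = X_train[cols]
        oof = np.empty(len(y))
        for tr, te in splits:
            model = _clock.fit(Xk.iloc[tr], y[tr], clock_config, seed=seed)
            oof[te] = _clock.predict(model, Xk.iloc[te])
        err = oof - y
        rows.append({
            "k": k,
            "pearson_r": float(stats.pearsonr(oof, y).statistic),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "mae": float(np.mean(np.abs(err))),
        })
    return pd.DataFrame(rows)


def choose_k(sweep: pd.DataFrame, tol: float = 0.005, override: int | None = None) -> int:
    """Smallest k whose Pearson r is within ``tol`` of the sweep maximum
    (plateau rule); ``override`` short-circuits the rule (e.g. a fixed
    k=300)."""
    if override is not None:
        return int(override)
    if len(sweep) == 0:
        raise ValueError("empty sweep")
    best = sweep["pearson_r"].max()
    ok = sweep[sweep["pearson_r"] >= best - tol]
    return int(ok["k"].min())


def modality_counts(ranking: FeatureRanking, k: int) -> dict[str, int]:
    """Protein/metabolite composition of the top-k features (column-name
    prefix convention ``prot_``/``metab_``)."""
    top = ranking.top(k)
    n_prot = sum(1 for f in top if f.startswith("prot_"))
    n_metab = sum(1 for f in top if f.startswith("metab_"))
    return {"protein": n_prot, "metabolite": n_metab, "other": k - n_prot - n_metab}
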