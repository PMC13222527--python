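"""Stacked-generalization biological-age regressor.

The clock stacks three complementary base learners — ordinary least squares,
elastic-net-regularized linear regression, and a gradient-boosted tree
ensemble (LightGBM) — under a gradient-boosted meta-learner (XGBoost).
Stacking proceeds in the standard leakage-free order:

1. the training rows are partitioned into k seeded folds;
2. each base learner is trained on k-1 folds and predicts the held-out
   fold, yielding an out-of-fold (OOF) prediction matrix that covers every
   training row exactly once per base learner;
3. the meta-learner is trained on the OOF matrix against chronological age;
4. the base learners are refit on the complete training set for deployment.

Predicted age divided by chronological age is the aging rate consumed by
every downstream analysis (see :mod:`omicage.agingrate`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LinearRegression
from sklearn.model_selection import KFold

import lightgbm as lgb
import xgboost as xgb

__all__ = ["ClockConfig", "ClockModel", "ClockMetrics", "fit", "predict", "evaluate", "ablate"]

BASE_LEARNERS = ("ols", "enet", "lgbm")


@dataclass
class ClockConfig:
    """Hyperparameters of the stacking ensemble.

    ``meta`` may be ``"xgboost"`` (default), ``"mean"`` (unweighted average
    of base predictions) or ``"identity"`` (pass-through; requires a single
    base learner) — the degenerate options exist for verification.
    """

    base_learners: tuple[str, ...] = BASE_LEARNERS
    meta: str = "xgboost"
    folds: int = 5
    #: affine age-bias correction: regression-to-the-mean compresses
    #: predictions toward the cohort mean age, which leaves the ratio-based
    #: aging rate with a spurious 1/age trend. The correction fits
    #: pred = delta + gamma*age on the (out-of-fold) training predictions and
    #: deploys (pred - delta)/gamma, restoring rate-vs-age orthogonality.
    calibrate_age_bias: bool = True
    enet_l1_ratio: float = 0.5
    enet_n_alphas: int = 25
    enet_cv: int = 3
    enet_max_iter: int = 5000
    lgbm_params: dict = field(default_factory=lambda: {
        "n_estimators": 150, "learning_rate": 0.1, "num_leaves": 15,
        "max_bin": 63, "colsample_bytree": 0.5, "verbose": -1, "n_jobs": 1,
    })
    xgb_params: dict = field(default_factory=lambda: {
        "n_estimators": 200, "learning_rate": 0.05, "max_depth": 3, "n_jobs": 1,
    })

    def validate(self) -> None:
        unknown = set(self.base_learners) - set(BASE_LEARNERS)
        if unknown:
            raise ValueError(f"unknown base learners: {sorted(unknown)}")
        if not self.base_learners:
            raise ValueError("at least one base learner required")
        if self.meta == "identity" and len(self.base_learners) != 1:
            raise ValueError("identity meta-learner requires exactly one base learner")
        if self.meta not in ("xgboost", "mean", "identity"):
            raise ValueError(f"unknown meta-learner {self.meta!r}")


def _make_base(name: str, cfg: ClockConfig, seed: int):
    if name == "ols":
        return LinearRegression()
    if name == "enet":
        return ElasticNetCV(
            l1_ratio=cfg.enet_l1_ratio,
            alphas=cfg.enet_n_alphas,  # length of the automatic alpha grid
            cv=cfg.enet_cv,
            max_iter=cfg.enet_max_iter,
            random_state=seed,
        )
    if name == "lgbm":
        return lgb.LGBMRegressor(random_state=seed, **cfg.lgbm_params)
    raise ValueError(name)


@dataclass
class ClockModel:
    config: ClockConfig
    feature_names: list[str]
    fold_assignment: np.ndarray      # fold index per training row
    oof_predictions: np.ndarray      # n_train x n_base, leakage-free
    base_models: dict                # refit on the full training set
    meta_model: object | None
    seed: int
    train_index: np.ndarray          # row identifiers seen at fit time
    constant_age: float | None = None  # degenerate case: zero-variance target
    calibration: tuple[float, float] = (0.0, 1.0)  # (delta, gamma)

    @property
    def fold_hash(self) -> str:
        """Digest of the fold assignment; identical across configurations
        fitted with the same seed and row count."""
        return hashlib.md5(self.fold_assignment.tobytes()).hexdigest()


@dataclass
class ClockMetrics:
    pearson_r: float
    rmse: float
    mae: float
    r2: float


def _as_matrix(X, feature_names: list[str] | None = None) -> tuple[np.ndarray, list[str], np.ndarray]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature columns do not match the fitted model; "
                    f"missing={missing[:5]} extra={extra[:5]}"
                )
            X = X[feature_names]
            names = feature_names
        return X.to_numpy(dtype=float), names, np.asarray(X.index)
    arr = np.asarray(X, dtype=float)
    names = feature_names or [f"x{i}" for i in range(arr.shape[1])]
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise ValueError("feature count mismatch with fitted model")
    return arr, names, None


def fit(X_train, age_train, config: ClockConfig | None = None, seed: int = 0) -> ClockModel:
    """Fit the stacking ensemble on the training set.

    The function sees only training data; the fitted model is a pure
    function of ``(X_train, age_train, config, seed)``.
    """
    cfg = config or ClockConfig()
    cfg.validate()
    X, names, index = _as_matrix(X_train)
    y = np.asarray(age_train, dtype=float)
    n = len(y)
    if n < cfg.folds:
        raise ValueError(f"{n} rows < {cfg.folds} folds")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training data")

    if np.ptp(y) == 0.0:
        # Constant target: every learner would predict the constant; skip
        # fitting entirely (elastic-net path selection is undefined here).
        return ClockModel(cfg, names, np.zeros(n, dtype=int), np.full((n, len(cfg.base_learners)), y[0]),
                          {}, None, seed, index, constant_age=float(y[0]))

    # LightGBM is fed a named frame so its stored feature names stay
    # consistent between fit and predict.
    Xdf = pd.DataFrame(X, columns=names)
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    oof = np.full((n, len(cfg.base_learners)), np.nan)
    for k, (tr, te) in enumerate(kf.split(X)):
        fold_assignment[te] = k
        for j, name in enumerate(cfg.base_learners):
            model = _make_base(name, cfg, seed)
            model.fit(Xdf.iloc[tr], y[tr])
            oof[te, j] = model.predict(Xdf.iloc[te])
    assert not np.isnan(oof).any(), "out-of-fold coverage incomplete"

    if cfg.meta == "xgboost":
        meta = xgb.XGBRegressor(random_state=seed, **cfg.xgb_params)
        meta.fit(oof, y)
    else:
        meta = None  # "mean" and "identity" need no fitting

    base_models = {}
    for name in cfg.base_learners:
        model = _make_base(name, cfg, seed)
        model.fit(Xdf, y)
        base_models[name] = model

    calibration = (0.0, 1.0)
    if cfg.calibrate_age_bias:
        if cfg.meta == "xgboost":
            train_pred = meta.predict(oof)
        elif cfg.meta == "mean":
            train_pred = oof.mean(axis=1)
        else:
            train_pred = oof[:, 0]
        gamma, delta = np.polyfit(y, train_pred, 1)
        if gamma > 0.1:  # refuse a degenerate inversion
            calibration = (float(delta), float(gamma))

    return ClockModel(cfg, names, fold_assignment, oof, base_models, meta, seed,
                      index, calibration=calibration)


def predict(model: ClockModel, X) -> np.ndarray:
    """Predict biological age for new samples using the full-train base
    learner refits and the meta-learner."""
    Xm, _, _ = _as_matrix(X, model.feature_names)
    if model.constant_age is not None:
        return np.full(Xm.shape[0], model.constant_age)
    Xdf = pd.DataFrame(Xm, columns=model.feature_names)
    base_preds = np.column_stack(
        [model.base_models[name].predict(Xdf) for name in model.config.base_learners]
    )
    if model.config.meta == "xgboost":
        out = model.meta_model.predict(base_preds)
    elif model.config.meta == "mean":
        out = base_preds.mean(axis=1)
    else:  # identity
        out = base_preds[:, 0]
    delta, gamma = model.calibration
    return (np.asarray(out, dtype=float) - delta) / gamma


def evaluate(model: ClockModel, X_test, age_test) -> ClockMetrics:
    """Standard held-out metrics: Pearson r, RMSE, MAE and R^2 = 1-SSE/SST.

    Asserts that the evaluation rows are disjoint from the training rows
    when identifiers are available, and refuses a zero-variance target.
    """
    _, _, index = _as_matrix(X_test, model.feature_names)
    if index is not None and model.train_index is not None:
        overlap = np.intersect1d(index, model.train_index)
        if len(overlap):
            raise ValueError(f"evaluation rows overlap training rows: {overlap[:5]}")
    y = np.asarray(age_test, dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("age_test has zero variance; correlation undefined")
    return compute_metrics(predict(model, X_test), y)


def compute_metrics(predictions, age) -> ClockMetrics:
    """Pearson r, RMSE, MAE and R^2 = 1 - SSE/SST for a prediction vector."""
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(age, dtype=float)
    if np.ptp(pred) == 0.0 or np.ptp(y) == 0.0:
        r = float("nan")  # correlation undefined for a constant input
    else:
        r = float(stats.pearsonr(pred, y).statistic)
    err = pred - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / sst)
    return ClockMetrics(pearson_r=r, rmse=rmse, mae=mae, r2=r2)


def ablate(X_train, age_train, X_test, age_test,
           config: ClockConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Leave-one-base-learner-out comparison under identical folds.

    Returns one row per configuration (the full ensemble plus each ablated
    variant) with test-set metrics and the fold-assignment hash, which is
    identical across rows by construction.
    """
    cfg = config or ClockConfig()
    rows = []
    variants = [("full", cfg.base_learners)]
    for name in cfg.base_learners:
        kept = tuple(b for b in cfg.base_learners if b != name)
        if kept:
            variants.append((f"drop_{name}", kept))
    for label, learners in variants:
        vcfg = ClockConfig(
            base_learners=learners, meta=cfg.meta,
            folds=cfg.folds, enet_l1_ratio=cfg.enet_l1_ratio,
            enet_n_alphas=cfg.enet_n_alphas, enet_cv=cfg.enet_cv,
            enet_max_iter=cfg.enet_max_iter, lgbm_params=cfg.lgbm_params,
            xgb_params=cfg.xgb_params,
        )
        model = fit(X_train, age_train, vcfg, seed=seed)
        m = evaluate(model, X_test, age_test)
        rows.append({
            "configuration": label,
            "base_learners": "+".join(learners),
            "pearson_r": m.pearson_r, "rmse": m.rmse, "mae": m.mae, "r2": m.r2,
            "fold_hash": model.fold_hash,
        })
    return pd.DataFrame(rows)
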