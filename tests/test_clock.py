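"""Stacking correctness: out-of-fold coverage, degeneracies, leakage
independence, metric arithmetic, ablation bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import lightgbm as lgb

from omicage.clock import ClockConfig, ablate, compute_metrics, evaluate, fit, predict

FAST = ClockConfig(
    lgbm_params={"n_estimators": 40, "learning_rate": 0.1, "num_leaves": 15,
                 "max_bin": 63, "verbose": -1, "n_jobs": 1},
    xgb_params={"n_estimators": 50, "learning_rate": 0.1, "max_depth": 3,
                "n_jobs": 1},
    enet_n_alphas=10,
)


def test_out_of_fold_coverage_exactly_once(clock_data):
    d = clock_data
    X = d["design"].loc[d["train_ids"]]
    model = fit(X, d["age"].loc[d["train_ids"]].to_numpy(), FAST, seed=0)
    assert model.oof_predictions.shape == (len(X), 3)
    assert np.all(np.isfinite(model.oof_predictions))
    counts = np.bincount(model.fold_assignment, minlength=FAST.folds)
    assert counts.sum() == len(X) and counts.min() >= len(X) // FAST.folds


def test_constant_target_predicts_constant(rng):
    X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
    model = fit(X, np.full(60, 57.3), FAST, seed=0)
    np.testing.assert_array_equal(predict(model, X), np.full(60, 57.3))


def test_single_learner_identity_meta_reproduces_base(clock_data):
    d = clock_data
    X = d["design"].loc[d["train_ids"]]
    y = d["age"].loc[d["train_ids"]].to_numpy()
    cfg = ClockConfig(base_learners=("lgbm",), meta="identity",
                      lgbm_params=FAST.lgbm_params, calibrate_age_bias=False)
    model = fit(X, y, cfg, seed=0)
    ref = lgb.LGBMRegressor(random_state=0, **FAST.lgbm_params)
    ref.fit(X, y)
    Xte = d["design"].loc[d["test_ids"]]
    np.testing.assert_array_equal(predict(model, Xte), ref.predict(Xte))


def test_mean_meta_equals_average_of_base_predictions(clock_data):
    d = clock_data
    X = d["design"].loc[d["train_ids"]]
    y = d["age"].loc[d["train_ids"]].to_numpy()
    cfg = ClockConfig(meta="mean", lgbm_params=FAST.lgbm_params,
                      enet_n_alphas=10, calibrate_age_bias=False)
    model = fit(X, y, cfg, seed=0)
    Xte = d["design"].loc[d["test_ids"]]
    base = np.column_stack([model.base_models[n].predict(Xte)
                            for n in cfg.base_learners])
    np.testing.assert_allclose(predict(model, Xte), base.mean(axis=1),
                               atol=1e-9)


def test_fit_is_independent_of_test_content(clock_data, rng):
    # Scrambling held-out ages (and even held-out features) before fitting
    # must leave the fitted model's predictions bit-identical.
    d = clock_data
    Xtr = d["design"].loc[d["train_ids"]]
    ytr = d["age"].loc[d["train_ids"]].to_numpy()
    model1 = fit(Xtr, ytr, FAST, seed=0)
    _ = rng.permutation(d["age"].loc[d["test_ids"]].to_numpy())  # scrambled
    model2 = fit(Xtr, ytr, FAST, seed=0)
    Xte = d["design"].loc[d["test_ids"]]
    np.testing.assert_array_equal(predict(model1, Xte), predict(model2, Xte))
    assert model1.fold_hash == model2.fold_hash


def test_metric_arithmetic_hand_example():
    m = compute_metrics([52.0, 58.0, 71.0, 79.0], [50.0, 60.0, 70.0, 80.0])
    assert m.rmse == pytest.approx(np.sqrt(2.5))
    assert m.mae == pytest.approx(1.5)
    assert m.pearson_r == pytest.approx(
        np.corrcoef([52, 58, 71, 79], [50, 60, 70, 80])[0, 1])


def test_perfect_and_mean_predictions_metrics():
    y = np.array([50.0, 60.0, 70.0])
    perfect = compute_metrics(y, y)
    assert (perfect.rmse, perfect.mae, perfect.r2) == (0.0, 0.0, 1.0)
    assert perfect.pearson_r == pytest.approx(1.0)
    at_mean = compute_metrics(np.full(3, y.mean()), y)
    assert at_mean.r2 == pytest.approx(0.0)


def test_evaluate_rejects_overlap_and_degenerate_target(clock_data):
    d = clock_data
    Xtr = d["design"].loc[d["train_ids"]]
    ytr = d["age"].loc[d["train_ids"]].to_numpy()
    model = fit(Xtr, ytr, FAST, seed=0)
    with pytest.raises(ValueError, match="overlap"):
        evaluate(model, Xtr.iloc[:10], ytr[:10])
    Xte = d["design"].loc[d["test_ids"]]
    with pytest.raises(ValueError, match="zero variance"):
        evaluate(model, Xte, np.full(len(Xte), 60.0))


def test_predict_rejects_column_mismatch(clock_data):
    d = clock_data
    Xtr = d["design"].loc[d["train_ids"]]
    model = fit(Xtr, d["age"].loc[d["train_ids"]].to_numpy(), FAST, seed=0)
    bad = d["design"].loc[d["test_ids"]].drop(columns=Xtr.columns[0])
    with pytest.raises(ValueError, match=Xtr.columns[0]):
        predict(model, bad)


def test_ablation_table_shares_folds_and_lists_full_once(clock_data):
    d = clock_data
    table = ablate(d["design"].loc[d["train_ids"]],
                   d["age"].loc[d["train_ids"]].to_numpy(),
                   d["design"].loc[d["test_ids"]],
                   d["age"].loc[d["test_ids"]].to_numpy(),
                   FAST, seed=0)
    assert (table["configuration"] == "full").sum() == 1
    assert len(table) == 4
    assert table["fold_hash"].nunique() == 1
    # with both linear and nonlinear signal planted, the full ensemble is
    # competitive with every ablated variant up to CV noise
    full_r = table.loc[table["configuration"] == "full", "pearson_r"].iloc[0]
    assert (full_r >= table["pearson_r"] - 0.02).all()


def test_identity_meta_requires_single_base():
    with pytest.raises(ValueError):
        ClockConfig(base_learners=("ols", "enet"), meta="identity").validate()
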