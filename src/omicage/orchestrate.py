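"""End-to-end pipeline driver.

``run_pipeline`` chains every stage on a simulated cohort: generation ->
filtering/imputation/encoding -> attribution-based feature selection ->
stacked clock fit/evaluation/ablation -> aging-rate derivation -> decile
survival stratification -> four-design risk comparison -> differential
abundance -> mediation grid -> demographic contrasts. Each stage writes
versioned CSV outputs plus ``metrics.json`` (purely numeric, byte-identical
across reruns of the same configuration) and ``manifest.json`` (config,
derived stage seeds, timings).

The single global seed is expanded into per-stage seeds with the counter
scheme ``stage_seed_i = (seed * 1009 + i) mod 2^31`` so editing one stage
never perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agingrate, clock, cohortsim, diffexpr, groupstats, mediation, preprocess, risk, select

__all__ = ["RunConfig", "demo_config", "run_pipeline"]

_STAGES = ("simulate", "preprocess", "select", "clock", "agingrate",
           "survival", "risk", "diffexpr", "mediation", "groupstats")


def stage_seed(seed: int, index: int) -> int:
    return (seed * 1009 + index) % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "runs/demo"
    sim: dict = field(default_factory=dict)      # overrides for SimConfig
    train_fraction: float = 0.8
    select_grid: tuple = (40, 80, 120)
    select_folds: int = 3
    select_tol: float = 0.005
    k_override: int | None = None
    clock_folds: int = 5
    clock_lgbm: dict = field(default_factory=lambda: {"n_estimators": 200})
    run_ablation: bool = True
    horizons: tuple = (10.0,)
    risk_folds: int = 10
    risk_min_cases: int = 15
    de_top_up: int = 10
    de_top_down: int = 5
    de_restrict_to_selected: bool = True
    mediation_factors: tuple | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def demo_config(seed: int = 0, out_dir: str = "runs/demo") -> RunConfig:
    """Desk-scale demonstration configuration (~600 participants, 200
    biomarkers) exercising every stage in about a minute."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        sim={
            "n_participants": 600,
            "n_proteins": 150,
            "n_metabolites": 50,
            "n_age_informative": 80,
            "effect_scale": 0.06,
            "noise_sd": 1.0,
            "accel_sd": 0.08,
            "baseline_disease_rate": 0.12,
            "n_up_markers": 8,
            "n_down_markers": 4,
            "marker_effect": 1.2,
        },
        # the demo plants disease markers among non-aging proteins, so the
        # differential-abundance stage scans the full protein panel
        de_restrict_to_selected=False,
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(_STAGES)}
    timings: dict[str, float] = {}
    metrics: dict = {}

    def tick(name):
        timings[name] = time.perf_counter()

    def tock(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # ---- simulate ---------------------------------------------------------
    tick("simulate")
    sim_cfg = cohortsim.SimConfig(**{**config.sim, "seed": seeds["simulate"]})
    participants, omics, events, truth = cohortsim.simulate_cohort(sim_cfg)
    cohortsim.write_cohort(out / "cohort", participants, omics, events, truth)
    tock("simulate")

    # ---- preprocess -------------------------------------------------------
    tick("preprocess")
    healthy, disease, filter_log = preprocess.filter_cohort(participants, omics, events)
    kept = pd.concat([healthy, disease], ignore_index=True)
    omics_kept = omics[omics["participant_id"].isin(set(kept["participant_id"]))]
    kept_imp, omics_imp = preprocess.impute(kept, omics_kept)
    train_ids, test_ids = preprocess.split(
        healthy["participant_id"],
        preprocess.SplitSpec(config.train_fraction, seeds["preprocess"]),
    )
    biomarkers = [c for c in omics_imp.columns if c != "participant_id"]
    omics_indexed = omics_imp.set_index("participant_id")[biomarkers]
    design, manifest_enc = preprocess.encode_standardize(omics_indexed, train_ids)
    (out / "preprocess").mkdir(exist_ok=True)
    with open(out / "preprocess" / "exclusions.json", "w") as fh:
        json.dump(_jsonify(filter_log), fh, indent=1, sort_keys=True)
    metrics["cohort"] = {
        "n_healthy": len(healthy), "n_disease": len(disease),
        "n_train": len(train_ids), "n_test": len(test_ids),
        "n_excluded": filter_log["n_excluded"],
    }
    tock("preprocess")

    # ---- feature selection ------------------------------------------------
    tick("select")
    X_train = design.loc[train_ids]
    age = kept_imp.set_index("participant_id")["chronological_age"]
    y_train = age.loc[train_ids].to_numpy()
    ranking = select.rank_features(X_train, y_train, seed=seeds["select"])
    grid = [k for k in config.select_grid if k <= design.shape[1]]
    clock_cfg = clock.ClockConfig(folds=config.clock_folds,
                                  lgbm_params={**clock.ClockConfig().lgbm_params,
                                               **config.clock_lgbm})
    sweep = select.sweep_subset_sizes(X_train, y_train, ranking, grid=grid,
                                      folds=config.select_folds,
                                      seed=seeds["select"], clock_config=clock_cfg)
    k = select.choose_k(sweep, tol=config.select_tol, override=config.k_override)
    selected = ranking.top(k)
    (out / "select").mkdir(exist_ok=True)
    ranking.table.to_csv(out / "select" / "ranking.csv", index=False)
    sweep.to_csv(out / "select" / "sweep.csv", index=False)
    metrics["selection"] = {
        "k": k,
        "modality_counts": select.modality_counts(ranking, k),
        "sweep": {str(int(row.k)): round(float(row.pearson_r), 6)
                  for row in sweep.itertuples()},
    }
    tock("select")

    # ---- clock ------------------------------------------------------------
    tick("clock")
    model = clock.fit(X_train[selected], y_train, clock_cfg, seed=seeds["clock"])
    X_test = design.loc[test_ids, selected]
    y_test = age.loc[test_ids].to_numpy()
    m = clock.evaluate(model, X_test, y_test)
    metrics["clock"] = {"pearson_r": m.pearson_r, "rmse": m.rmse,
                        "mae": m.mae, "r2": m.r2}
    if config.run_ablation:
        ablation = clock.ablate(X_train[selected], y_train, X_test, y_test,
                                clock_cfg, seed=seeds["clock"])
        ablation.to_csv(out / "ablation.csv", index=False)
        metrics["ablation"] = {
            row.configuration: round(float(row.pearson_r), 6)
            for row in ablation.itertuples()
        }
    tock("clock")

    # ---- aging rate -------------------------------------------------------
    tick("agingrate")
    all_ids = kept_imp["participant_id"].to_numpy()
    predictions = clock.predict(model, design.loc[all_ids, selected])
    records = agingrate.build_records(all_ids, age.loc[all_ids].to_numpy(),
                                      predictions, fit_population_ids=train_ids)
    records = records.merge(
        kept_imp[["participant_id", "sex"]], on="participant_id")
    top_ids, bottom_ids = agingrate.stratify_deciles(records)
    report = agingrate.orthogonality_report(
        records[records["participant_id"].isin(set(test_ids))])
    records.drop(columns="sex").to_csv(out / "aging.csv", index=False)
    metrics["aging_rate"] = {
        "orthogonality_r_test": report["pearson_r_rate_vs_age"],
        "rate_mean": report["rate_mean"], "rate_sd": report["rate_sd"],
    }
    tock("agingrate")

    # ---- survival ---------------------------------------------------------
    tick("survival")
    from . import survival as surv
    diseases = list(sim_cfg.disease_specs)
    metrics["survival"] = {}
    (out / "survival").mkdir(exist_ok=True)
    events_kept = events[events["participant_id"].isin(set(all_ids))]
    for d in diseases:
        c_top, c_bot, lr_stat, lr_p = surv.compare_strata(
            events_kept, top_ids, bottom_ids, d)
        metrics["survival"][d] = {
            "logrank_p": lr_p,
            "top_final_incidence": float(c_top.cumulative_incidence[-1]) if len(c_top.times) else 0.0,
            "bottom_final_incidence": float(c_bot.cumulative_incidence[-1]) if len(c_bot.times) else 0.0,
        }
    tock("survival")

    # ---- risk -------------------------------------------------------------
    tick("risk")
    rate_series = records.set_index("participant_id")["aging_rate"]
    demog_design, _ = preprocess.encode_standardize(
        kept_imp.set_index("participant_id")[["chronological_age", "bmi", "sex"]],
        train_ids)
    sel_prot = [f for f in selected if f.startswith("prot_")]
    sel_metab = [f for f in selected if f.startswith("metab_")]
    metrics["risk"] = {}
    all_results = {}
    for d in diseases:
        for horizon in config.horizons:
            ids_l, labels, _ = risk.label_at_horizon(events_kept, d, horizon)
            ids_l = [i for i in ids_l]
            mask = pd.Index(ids_l)
            n_cases = int(np.sum(labels))
            if n_cases < config.risk_min_cases or n_cases > len(labels) - config.risk_min_cases:
                metrics["risk"][f"{d}@{horizon:g}y"] = {"skipped_n_cases": n_cases}
                continue
            blocks = {
                "proteomics": design.loc[mask, sel_prot],
                "metabolomics": design.loc[mask, sel_metab],
                "demographics": demog_design.loc[mask],
                "aging_rate": rate_series.loc[mask].to_frame(),
            }
            results = risk.run_design_suite(blocks, labels, seed=seeds["risk"],
                                            n_folds=config.risk_folds,
                                            disease=d, horizon=horizon)
            contrast = risk.compare_models(results)
            all_results[(d, horizon)] = results
            metrics["risk"][f"{d}@{horizon:g}y"] = {
                "n": len(labels), "n_cases": n_cases,
                **{name: round(res.mean_auc, 6) for name, res in results.items()},
                "delta_auc_model1_vs_model2": round(contrast["mean_delta_auc"], 6),
            }
    if all_results:
        risk.summary_table(all_results).to_csv(out / "risk_aucs.csv", index=False)
    tock("risk")

    # ---- differential abundance ------------------------------------------
    tick("diffexpr")
    raw_omics = omics_imp.set_index("participant_id")
    disease_ids = set(disease["participant_id"])
    healthy_ids_all = set(healthy["participant_id"])
    prot_cols = ([f for f in sel_prot] if config.de_restrict_to_selected
                 else [c for c in raw_omics.columns if c.startswith("prot_")])
    metrics["diffexpr"] = {}
    if disease_ids and prot_cols:
        table = diffexpr.differential_table(
            raw_omics.loc[sorted(disease_ids), prot_cols],
            raw_omics.loc[sorted(healthy_ids_all), prot_cols])
        up, down = diffexpr.rank_markers(table, config.de_top_up, config.de_top_down)
        table.to_csv(out / "diffexpr.csv", index=False)
        metrics["diffexpr"] = {"top_up": up, "top_down": down,
                               "n_proteins_tested": len(table)}
    tock("diffexpr")

    # ---- mediation --------------------------------------------------------
    tick("mediation")
    factors = list(config.mediation_factors or
                   [f"{f}_score" for f in cohortsim.LIFESTYLE_FACTORS])
    med_data = kept_imp.set_index("participant_id").loc[all_ids, factors].copy()
    med_data["aging_rate"] = rate_series.loc[all_ids].to_numpy()
    for d in diseases:
        ev = events_kept[events_kept["disease"] == d].set_index("participant_id")
        med_data[f"incident_{d}"] = ev.loc[all_ids, "event"].to_numpy()
    grid_results = mediation.mediation_matrix(
        med_data.reset_index(drop=True), factors, "aging_rate",
        [f"incident_{d}" for d in diseases])
    grid_results.to_csv(out / "mediation.csv", index=False)
    metrics["mediation"] = {
        "n_pairs": len(grid_results),
        "n_significant_p10": int(grid_results["significant_p10"].sum()),
        "n_significant_p01": int(grid_results["significant_p01"].sum()),
        "max_decomposition_error": float(np.max(np.abs(
            grid_results["total"] - (grid_results["c_prime"] + grid_results["indirect"])))),
    }
    tock("mediation")

    # ---- group statistics -------------------------------------------------
    tick("groupstats")
    kept_idx = kept_imp.set_index("participant_id").loc[all_ids]
    rate_all = rate_series.loc[all_ids].to_numpy()
    f_stat, f_p = groupstats.anova_by_group(rate_all, kept_idx["race"].to_numpy())
    sexc = groupstats.sex_contrast(rate_all, kept_idx["sex"].to_numpy(),
                                   ages=kept_idx["chronological_age"].to_numpy(),
                                   trim=0.01)
    lifestyle = groupstats.lifestyle_contrasts(
        records.set_index("participant_id").loc[all_ids, "predicted_age"].to_numpy(),
        kept_idx.reset_index(), list(cohortsim.LIFESTYLE_FACTORS),
        age_strata=((44.0, 49.0), (50.0, 59.0), (60.0, 69.0)))
    lifestyle.to_csv(out / "lifestyle_contrasts.csv", index=False)
    metrics["groupstats"] = {
        "race_anova_F": f_stat, "race_anova_p": f_p,
        "sex_delta_rate": sexc.delta, "sex_p": sexc.p,
        "sex_ancova_p": sexc.ancova_p,
    }
    tock("groupstats")

    with open(out / "metrics.json", "w") as fh:
        json.dump(_jsonify(metrics), fh, indent=1, sort_keys=True)
    manifest = {
        "config": _jsonify(dataclasses.asdict(config)),
        "stage_seeds": seeds,
        "encoding": {"n_columns": len(manifest_enc["columns"]),
                     "zero_variance": manifest_enc["zero_variance"]},
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonify(manifest), fh, indent=1, sort_keys=True)
    return out
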