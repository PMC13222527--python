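"""Generator invariants: determinism, degenerate acceleration, missingness
rates, hazard law, file round-trips."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from omicage.cohortsim import SimConfig, simulate_cohort, write_cohort, read_cohort


def test_same_seed_identical_tables():
    cfg = SimConfig(n_participants=150, n_proteins=30, n_metabolites=5,
                    n_age_informative=10, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    for x, y in zip(a[:3], b[:3]):
        assert_frame_equal(x, y)
    assert_frame_equal(a[3].participants, b[3].participants)


def test_zero_acceleration_sd_degenerates_to_identity():
    cfg = SimConfig(n_participants=100, n_proteins=10, n_metabolites=5,
                    n_age_informative=5, accel_sd=0.0, lifestyle_effects={},
                    seed=1)
    participants, _, _, truth = simulate_cohort(cfg)
    assert np.all(truth.participants["acceleration"] == 1.0)
    np.testing.assert_array_equal(
        truth.participants["biological_age"].to_numpy(),
        participants["chronological_age"].to_numpy())


def test_omics_missingness_rate_close_to_configured():
    cfg = SimConfig(n_participants=2000, n_proteins=400, n_metabolites=100,
                    n_age_informative=100, miss_omics=0.03, seed=3)
    _, omics, _, _ = simulate_cohort(cfg)
    cells = omics.drop(columns="participant_id")
    frac = float(cells.isna().to_numpy().mean())
    assert abs(frac - 0.03) < 0.005


def test_exponential_hazard_law_under_null_slope():
    # With a flat hazard (beta=0) the event times are iid exponential,
    # administratively censored: the event fraction matches the closed-form
    # CDF and the censored-time distribution matches the truncated
    # exponential.
    base = 0.05
    cfg = SimConfig(n_participants=10000, n_proteins=2, n_metabolites=1,
                    n_age_informative=0, disease_specs={"d": (base, 0.0)},
                    miss_demog=0.0, miss_omics=0.0, seed=5)
    _, _, events, _ = simulate_cohort(cfg)
    t = events["time_years"].to_numpy()
    e = events["event"].to_numpy()
    expected_frac = 1 - np.exp(-base * cfg.followup_years)
    assert abs(e.mean() - expected_frac) < 3 * np.sqrt(expected_frac / len(e))
    observed = t[e == 1]
    cdf = lambda x: (1 - np.exp(-base * x)) / expected_frac
    ks = stats.kstest(observed, cdf)
    assert ks.pvalue > 0.01


def test_monotone_signal_in_effect_scale():
    # Raising effect_scale must not weaken the link between biological age
    # and the leading principal axis of the informative biomarkers.
    corrs = []
    for scale in (0.02, 0.08):
        cfg = SimConfig(n_participants=500, n_proteins=40, n_metabolites=10,
                        n_age_informative=20, effect_scale=scale,
                        nonlinear_fraction=0.0,
                        miss_demog=0.0, miss_omics=0.0, seed=9)
        _, omics, _, truth = simulate_cohort(cfg)
        informative = truth.biomarkers.loc[
            truth.biomarkers["informative"] == 1, "biomarker"]
        X = omics[list(informative)].to_numpy()
        X = (X - X.mean(0)) / X.std(0)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        pc1 = X @ vt[0]
        b = truth.participants["biological_age"].to_numpy()
        corrs.append(abs(stats.pearsonr(pc1, b).statistic))
    assert corrs[1] >= corrs[0]


def test_planted_subgroup_and_markers_recorded_in_truth():
    cfg = SimConfig(n_participants=200, n_proteins=60, n_metabolites=10,
                    n_age_informative=20, accel_subgroup_frac=0.1,
                    accel_subgroup_value=1.3, n_up_markers=5, n_down_markers=3,
                    marker_effect=2.0, baseline_disease_rate=0.5, seed=2)
    participants, omics, _, truth = simulate_cohort(cfg)
    t = truth.participants
    assert t["planted_subgroup"].sum() == 20
    assert np.all(t.loc[t["planted_subgroup"] == 1, "acceleration"] == 1.3)
    bm = truth.biomarkers
    assert bm["marker_up"].sum() == 5 and bm["marker_down"].sum() == 3
    # planted markers sit on uninformative proteins only
    planted = bm[(bm["marker_up"] == 1) | (bm["marker_down"] == 1)]
    assert (planted["modality"] == "protein").all()
    assert (planted["informative"] == 0).all()


@pytest.mark.parametrize("bad", [
    {"effect_scale": float("nan")},
    {"n_age_informative": 1000},
    {"miss_omics": 1.5},
    {"age_range": (0.0, 70.0)},
    {"accel_sd": -0.1},
])
def test_invalid_configuration_rejected(bad):
    kwargs = dict(n_participants=50, n_proteins=20, n_metabolites=5,
                  n_age_informative=10)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        SimConfig(**kwargs).validate()


class TestRoundTrip:
    def test_simulated_cohort_roundtrips(self, small_cohort, tmp_path):
        _, (participants, omics, events, truth) = small_cohort
        write_cohort(tmp_path, participants, omics, events, truth)
        p2, o2, e2, t2 = read_cohort(tmp_path)
        assert_frame_equal(participants, p2)
        assert_frame_equal(omics, o2)
        assert_frame_equal(events, e2)
        assert_frame_equal(truth.biomarkers, t2.biomarkers)

    def test_empty_cohort_roundtrips_with_headers(self, tmp_path):
        participants = pd.DataFrame(columns=["participant_id", "chronological_age"])
        omics = pd.DataFrame(columns=["participant_id", "prot_0000"])
        events = pd.DataFrame(columns=["participant_id", "disease",
                                       "time_years", "event"])
        write_cohort(tmp_path, participants, omics, events)
        p2, o2, e2, _ = read_cohort(tmp_path)
        assert list(p2.columns) == list(participants.columns)
        assert len(p2) == 0 and len(o2) == 0 and len(e2) == 0

    def test_single_participant_single_biomarker_exact(self, tmp_path):
        participants = pd.DataFrame({"participant_id": ["P1"],
                                     "chronological_age": [61.4142135623731]})
        omics = pd.DataFrame({"participant_id": ["P1"], "prot_0000": [3.14159]})
        events = pd.DataFrame({"participant_id": ["P1"], "disease": ["d"],
                               "time_years": [2.5], "event": [1]})
        write_cohort(tmp_path, participants, omics, events)
        p2, o2, _, _ = read_cohort(tmp_path)
        assert p2.loc[0, "chronological_age"] == participants.loc[0, "chronological_age"]
        assert o2.loc[0, "prot_0000"] == omics.loc[0, "prot_0000"]

    def test_identifier_mismatch_names_offenders(self, tmp_path, small_cohort):
        _, (participants, omics, events, _) = small_cohort
        bad_omics = omics.copy()
        bad_omics.loc[0, "participant_id"] = "P_WRONG"
        with pytest.raises(ValueError, match="P_WRONG"):
            write_cohort(tmp_path, participants, bad_omics, events)
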