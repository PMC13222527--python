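import numpy as np
import pytest

from omicage import cohortsim, preprocess


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    cfg = cohortsim.SimConfig(
        n_participants=300, n_proteins=40, n_metabolites=10,
        n_age_informative=25, seed=7)
    return cfg, cohortsim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clock_data():
    """Standardized design matrix + ages + truth for clock-level tests."""
    cfg = cohortsim.SimConfig(
        n_participants=500, n_proteins=50, n_metabolites=10,
        n_age_informative=30, effect_scale=0.08, accel_sd=0.05,
        miss_demog=0.0, miss_omics=0.0, seed=11)
    participants, omics, events, truth = cohortsim.simulate_cohort(cfg)
    train_ids, test_ids = preprocess.split(
        participants["participant_id"], preprocess.SplitSpec(0.8, 3))
    biomarkers = [c for c in omics.columns if c != "participant_id"]
    design, _ = preprocess.encode_standardize(
        omics.set_index("participant_id")[biomarkers], train_ids)
    age = participants.set_index("participant_id")["chronological_age"]
    return {
        "design": design, "age": age, "truth": truth,
        "train_ids": train_ids, "test_ids": test_ids,
        "events": events,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
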