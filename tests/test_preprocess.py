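"""Filtering, imputation, encoding and splitting rules."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

from omicage.preprocess import (SplitSpec, decimal_age, encode_standardize,
                                filter_cohort, impute, split)


class TestDecimalAge:
    def test_same_day_is_zero(self):
        assert decimal_age(dt.date(1960, 1, 1), dt.date(1960, 1, 1)) == 0.0

    def test_leap_year_span(self):
        # 1960 is a leap year: exactly 366 days elapse
        got = decimal_age(dt.date(1960, 1, 1), dt.date(1961, 1, 1))
        assert got == pytest.approx(366 / 365.25, abs=1e-12)

    def test_matches_numpy_datetime_oracle(self):
        birth, sampling = "1950-03-15", "2010-03-15"
        days = (np.datetime64(sampling) - np.datetime64(birth)) / np.timedelta64(1, "D")
        assert decimal_age(birth, sampling) == pytest.approx(days / 365.25, abs=1e-12)

    def test_sampling_before_birth_rejected(self):
        with pytest.raises(ValueError):
            decimal_age(dt.date(1990, 1, 2), dt.date(1990, 1, 1))


def _toy_tables(n=10, n_biomarkers=10):
    ids = [f"P{i}" for i in range(n)]
    participants = pd.DataFrame({
        "participant_id": ids,
        "chronological_age": np.linspace(45, 70, n),
        "sex": ["female", "male"] * (n // 2),
        "baseline_d": [0] * n,
    })
    omics = pd.DataFrame(
        np.ones((n, n_biomarkers)),
        columns=[f"prot_{j:04d}" for j in range(n_biomarkers)])
    omics.insert(0, "participant_id", ids)
    events = pd.DataFrame({"participant_id": ids, "disease": "d",
                           "time_years": 5.0, "event": 0})
    return participants, omics, events


class TestFilter:
    def test_strictly_above_20pct_excluded_exact_20_retained(self):
        participants, omics, events = _toy_tables(n=10, n_biomarkers=10)
        omics.iloc[0, 1:4] = np.nan       # 30% missing -> excluded
        omics.iloc[1, 1:3] = np.nan       # exactly 20% -> retained
        healthy, disease, log = filter_cohort(participants, omics, events)
        assert log["excluded_omics_missing"] == ["P0"]
        assert "P1" in set(healthy["participant_id"])

    def test_planted_high_missingness_rows_all_excluded(self, rng):
        participants, omics, events = _toy_tables(n=40, n_biomarkers=20)
        targets = [f"P{i}" for i in range(10)]
        cols = omics.columns[1:6]
        omics.loc[omics["participant_id"].isin(targets), cols] = np.nan  # 25%
        healthy, _, log = filter_cohort(participants, omics, events)
        assert log["excluded_omics_missing"] == sorted(targets)
        assert not set(targets) & set(healthy["participant_id"])

    def test_partition_and_other_exclusion_rules(self):
        participants, omics, events = _toy_tables(n=10)
        participants.loc[2, "sex"] = np.nan                  # essential missing
        participants.loc[3, "baseline_d"] = 1                # disease cohort
        events = events[events["participant_id"] != "P4"]    # no follow-up
        healthy, disease, log = filter_cohort(participants, omics, events)
        assert log["excluded_missing_essential"] == ["P2"]
        assert log["excluded_no_followup"] == ["P4"]
        assert set(disease["participant_id"]) == {"P3"}
        assert len(healthy) == 7
        assert log["n_healthy"] + log["n_disease"] + log["n_excluded"] == 10


class TestImpute:
    def _cohort(self):
        return pd.DataFrame({
            "participant_id": ["P0", "P1", "P2", "P3"],
            "chronological_age": [51.0, 52.0, 53.0, 54.0],
            "sex": ["female"] * 4,
            "bmi": [25.0, 27.0, np.nan, 30.0],
            "race": ["white", "asian", "white", None],
        })

    def test_subgroup_mean_for_continuous(self):
        cohort = self._cohort()
        omics = pd.DataFrame({"participant_id": cohort["participant_id"],
                              "prot_0000": [1.0, np.nan, 3.0, 4.0]})
        c2, o2 = impute(cohort, omics)
        # P2's subgroup (female, 50s) observed bmi {25, 27, 30}
        assert c2.loc[2, "bmi"] == pytest.approx((25 + 27 + 30) / 3)
        assert o2.loc[1, "prot_0000"] == 0.0
        assert not c2.isna().any().any() and not o2.isna().any().any()

    def test_two_value_subgroup_mean(self):
        cohort = self._cohort().iloc[:3].copy()
        cohort["bmi"] = [25.0, 27.0, np.nan]
        omics = pd.DataFrame({"participant_id": cohort["participant_id"],
                              "prot_0000": [1.0, 1.0, 1.0]})
        c2, _ = impute(cohort, omics)
        assert c2.loc[2, "bmi"] == 26.0

    def test_categorical_mode_tie_breaks_lexicographically(self):
        cohort = pd.DataFrame({
            "participant_id": list("abcdefg"),
            "chronological_age": [55.0] * 7,
            "sex": ["male"] * 7,
            "race": ["B", "B", "B", "A", "A", "A", None],
        })
        omics = pd.DataFrame({"participant_id": cohort["participant_id"],
                              "prot_0000": 1.0})
        c2, _ = impute(cohort, omics)
        assert c2.loc[6, "race"] == "A"

    def test_idempotent_on_simulated_cohort(self, small_cohort):
        _, (participants, omics, _, _) = small_cohort
        once = impute(participants, omics)
        twice = impute(*once)
        pd.testing.assert_frame_equal(once[0], twice[0])
        pd.testing.assert_frame_equal(once[1], twice[1])

    def test_entirely_missing_column_named_in_error(self):
        cohort = self._cohort()
        cohort["bmi"] = np.nan
        omics = pd.DataFrame({"participant_id": cohort["participant_id"],
                              "prot_0000": 1.0})
        with pytest.raises(ValueError, match="bmi"):
            impute(cohort, omics)


class TestEncodeStandardize:
    def _features(self):
        idx = [f"P{i}" for i in range(6)]
        return pd.DataFrame({
            "x": [3.0, 3.0, 7.0, 7.0, 9.0, 100.0],
            "const": 1.0,
            "color": ["red", "blue", "red", "blue", "red", "green"],
        }, index=idx)

    def test_parameters_from_train_rows_only(self):
        feats = self._features()
        train = ["P0", "P1", "P2", "P3"]   # x = {3,3,7,7}: mean 5, sd 2 (ddof=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design, manifest = encode_standardize(feats, train)
        assert manifest["standardize"]["x"] == {"mean": 5.0, "sd": 2.0}
        assert design.loc["P4", "x"] == pytest.approx((9 - 5) / 2)

    def test_train_columns_mean_zero_sd_one(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 4)),
                             columns=list("abcd"),
                             index=[f"P{i}" for i in range(50)])
        train = [f"P{i}" for i in range(40)]
        design, _ = encode_standardize(feats, train)
        tr = design.loc[train]
        assert np.allclose(tr.mean(), 0.0, atol=1e-9)
        assert np.allclose(tr.std(ddof=0), 1.0, atol=1e-9)

    def test_constant_column_zeroed_with_warning(self):
        feats = self._features()
        with pytest.warns(UserWarning, match="const"):
            design, manifest = encode_standardize(feats, list(feats.index))
        assert (design["const"] == 0).all()
        assert manifest["zero_variance"] == ["const"]

    def test_one_hot_sorted_levels_and_unseen_level(self):
        feats = self._features()
        train = ["P0", "P1", "P2", "P3"]   # levels blue, red; green unseen
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design, manifest = encode_standardize(feats, train)
        assert manifest["one_hot"]["color"] == ["blue", "red"]
        assert design.loc["P5", ["color_blue", "color_red"]].sum() == 0
        assert manifest["unseen_levels"]["color"] == ["green"]

    def test_leakage_guard_test_rows_do_not_affect_transform(self, rng):
        feats = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"),
                             index=[f"P{i}" for i in range(30)])
        train = [f"P{i}" for i in range(20)]
        design1, m1 = encode_standardize(feats, train)
        perturbed = feats.copy()
        perturbed.loc["P25"] += 1000.0
        design2, m2 = encode_standardize(perturbed, train)
        assert m1["standardize"] == m2["standardize"]
        pd.testing.assert_frame_equal(design1.loc[train], design2.loc[train])


class TestSplit:
    def test_sizes_and_disjointness(self):
        tr, te = split([f"P{i}" for i in range(10)], SplitSpec(0.8, 0))
        assert len(tr) == 8 and len(te) == 2
        assert not set(tr) & set(te)

    def test_reproducible_and_seed_sensitive(self):
        ids = [f"P{i}" for i in range(1000)]
        a1, _ = split(ids, SplitSpec(0.8, 5))
        a2, _ = split(ids, SplitSpec(0.8, 5))
        b1, _ = split(ids, SplitSpec(0.8, 6))
        np.testing.assert_array_equal(a1, a2)
        assert set(a1) != set(b1)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            split(["P0", "P1"], SplitSpec(0.8, 0))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(1.2, 0)
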