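"""Synthetic cohort generation for multi-omics aging analyses.

Real cohorts of this kind (plasma proteomics + NMR metabolomics with linked
demographic, lifestyle and incident-disease records) are access-restricted.
This module generates cohorts with the dependence structure the downstream
analyses assume, so every stage of the pipeline can be exercised and its
statistical behaviour verified against known ground truth.

The generative model
--------------------
Each participant ``i`` has a chronological age ``c_i`` drawn uniformly over a
configurable range, and a latent *aging acceleration* ``a_i`` centred at 1:

    a_i = 1 + sum_f effect_f * score_if + Normal(0, accel_sd),   a_i >= floor

where ``score_if in [0, 1]`` are continuous lifestyle scores (higher = less
healthy) and ``effect_f`` are configurable per-factor shifts. True biological
age is the product ``b_i = a_i * c_i``, so ``a_i`` is exactly the quantity a
ratio-based aging rate (predicted age / chronological age) estimates.

Age-informative biomarkers have mean ``intercept_j + slope_j * g(b_i)`` with
``g`` the identity for most and a mild quadratic for a configurable fraction
(so both linear and tree-based learners have signal to find); the remaining
biomarkers are pure noise. Incident-disease times follow an exponential
hazard ``lambda_d(i) = base_d * exp(beta_d * (b_i - mean(c)))`` with
administrative censoring at ``followup_years``. Missingness is injected
completely at random at configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LIFESTYLE_FACTORS",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The nine modifiable lifestyle domains carried by every simulated cohort.
LIFESTYLE_FACTORS = (
    "smoking",
    "alcohol",
    "inactivity",
    "sedentary",
    "sleep",
    "diet",
    "weight",
    "depression",
    "social",
)

RACE_LEVELS = ("asian", "black", "mixed", "other", "white")
RACE_PROBS = (0.10, 0.10, 0.05, 0.05, 0.70)

#: Continuous score above this value marks the participant "unhealthy" for
#: that lifestyle factor (dichotomised group used in group contrasts).
UNHEALTHY_CUTOFF = 0.7


def _default_lifestyle_effects() -> dict[str, float]:
    # Small additive shifts on acceleration per unit score, ordered so that
    # smoking and inactivity are the strongest, matching the usual ranking
    # of lifestyle risk factors in aging studies.
    return {
        "smoking": 0.03,
        "alcohol": 0.02,
        "inactivity": 0.025,
        "sedentary": 0.015,
        "sleep": 0.015,
        "diet": 0.02,
        "weight": 0.02,
        "depression": 0.01,
        "social": 0.01,
    }


def _default_disease_specs() -> dict[str, tuple[float, float]]:
    # disease -> (baseline hazard per year, log-hazard per year of
    # biological age). Chosen so ~5-15% of a 44-75y cohort has an event
    # inside an 11.7-year administrative follow-up.
    return {
        "type2_diabetes": (0.006, 0.08),
        "cardiovascular": (0.008, 0.06),
        "chronic_kidney": (0.004, 0.07),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions used throughout the
    package's simulation studies: a 44-75 year cohort, 600 protein + 200
    metabolite panel with 300 age-informative biomarkers, ~11.7-year
    administrative follow-up, ~2% demographic and ~3% omics missingness.
    """

    n_participants: int = 2000
    n_proteins: int = 600
    n_metabolites: int = 200
    age_range: tuple[float, float] = (44.0, 75.0)
    n_age_informative: int = 300
    effect_scale: float = 0.05       # abundance units per year of biological age
    noise_sd: float = 1.0            # residual biomarker SD
    accel_sd: float = 0.05           # SD of latent acceleration around 1
    accel_floor: float = 0.5         # truncation keeps biological age positive
    nonlinear_fraction: float = 0.2  # of informative biomarkers, quadratic in b
    lifestyle_effects: dict[str, float] = field(default_factory=_default_lifestyle_effects)
    disease_specs: dict[str, tuple[float, float]] = field(default_factory=_default_disease_specs)
    baseline_disease_rate: float = 0.08  # per-disease baseline (prevalent) flag
    followup_years: float = 11.7
    miss_demog: float = 0.02
    miss_omics: float = 0.03
    # Optional planted structures used by recovery studies ----------------
    accel_subgroup_frac: float = 0.0   # fraction with acceleration forced to a value
    accel_subgroup_value: float = 1.2
    n_up_markers: int = 0              # proteins mean-shifted up in baseline-disease rows
    n_down_markers: int = 0
    marker_effect: float = 0.0         # abundance shift magnitude for planted markers
    seed: int = 0

    def validate(self) -> None:
        n_biomarkers = self.n_proteins + self.n_metabolites
        scalars = {
            "n_participants": self.n_participants,
            "effect_scale": self.effect_scale,
            "noise_sd": self.noise_sd,
            "accel_sd": self.accel_sd,
            "followup_years": self.followup_years,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite configuration value: {name}={value!r}")
        if self.n_age_informative > n_biomarkers:
            raise ValueError(
                f"n_age_informative={self.n_age_informative} exceeds panel size "
                f"{n_biomarkers}"
            )
        for name, frac in (
            ("miss_demog", self.miss_demog),
            ("miss_omics", self.miss_omics),
            ("baseline_disease_rate", self.baseline_disease_rate),
            ("accel_subgroup_frac", self.accel_subgroup_frac),
            ("nonlinear_fraction", self.nonlinear_fraction),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name}={frac} outside [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError(f"invalid age_range {self.age_range}")
        if self.accel_sd < 0:
            raise ValueError("accel_sd must be >= 0")
        if self.accel_floor <= 0:
            raise ValueError("accel_floor must be > 0")
        unknown = set(self.lifestyle_effects) - set(LIFESTYLE_FACTORS)
        if unknown:
            raise ValueError(f"unknown lifestyle factors: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth behind a simulated cohort.

    ``participants`` holds the latent acceleration ``a_i`` and true
    biological age ``b_i = a_i * c_i`` per participant; ``biomarkers`` holds
    per-biomarker informativeness flags, slopes and planted-marker flags.
    """

    participants: pd.DataFrame
    biomarkers: pd.DataFrame


def _nonlinear_signal(b: np.ndarray) -> np.ndarray:
    # Mild convex transform of biological age, scaled to a range comparable
    # with the linear signal so neither dominates.
    return (b - 60.0) ** 2 / 15.0


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one synthetic cohort.

    Returns ``(participants, omics, events, truth)``: a participant table,
    a wide participants x biomarkers abundance matrix (columns prefixed
    ``prot_``/``metab_``), a long time-to-event table (one row per
    participant x disease) and the :class:`SimTruth` behind them. The same
    configuration (including seed) always yields identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- demographics -----------------------------------------------------
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    bmi = rng.normal(27.0, 4.0, size=n)

    # --- lifestyle scores and latent acceleration -------------------------
    scores = {f: rng.uniform(0.0, 1.0, size=n) for f in LIFESTYLE_FACTORS}
    accel = np.ones(n) + rng.normal(0.0, cfg.accel_sd, size=n)
    for factor, effect in cfg.lifestyle_effects.items():
        accel += effect * scores[factor]
    if cfg.accel_subgroup_frac > 0:
        k = int(round(cfg.accel_subgroup_frac * n))
        subgroup = rng.choice(n, size=k, replace=False)
    else:
        subgroup = np.array([], dtype=int)
    accel[subgroup] = cfg.accel_subgroup_value
    accel = np.maximum(accel, cfg.accel_floor)
    bio_age = accel * age

    # --- baseline disease flags -------------------------------------------
    diseases = list(cfg.disease_specs)
    baseline = {
        d: (rng.random(n) < cfg.baseline_disease_rate).astype(int) for d in diseases
    }

    # --- biomarker panel ---------------------------------------------------
    p_total = cfg.n_proteins + cfg.n_metabolites
    names = np.array(
        [f"prot_{j:04d}" for j in range(cfg.n_proteins)]
        + [f"metab_{j:04d}" for j in range(cfg.n_metabolites)]
    )
    informative_idx = rng.choice(p_total, size=cfg.n_age_informative, replace=False)
    informative = np.zeros(p_total, dtype=bool)
    informative[informative_idx] = True
    slopes = np.zeros(p_total)
    magnitudes = cfg.effect_scale * rng.uniform(0.5, 1.5, size=cfg.n_age_informative)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_age_informative)
    slopes[informative_idx] = magnitudes * signs
    n_nl = int(round(cfg.nonlinear_fraction * cfg.n_age_informative))
    nonlinear = np.zeros(p_total, dtype=bool)
    if n_nl:
        nonlinear[rng.choice(informative_idx, size=n_nl, replace=False)] = True

    intercepts = rng.normal(10.0, 2.0, size=p_total)
    signal = np.where(
        nonlinear, 0.0, slopes
    ) * bio_age[:, None] + np.where(nonlinear, slopes, 0.0) * _nonlinear_signal(bio_age)[:, None]
    omics_values = intercepts[None, :] + signal + rng.normal(0.0, cfg.noise_sd, size=(n, p_total))

    # --- planted disease markers (uninformative proteins only) -------------
    marker_up = np.zeros(p_total, dtype=bool)
    marker_down = np.zeros(p_total, dtype=bool)
    n_markers = cfg.n_up_markers + cfg.n_down_markers
    if n_markers:
        free = np.flatnonzero(~informative[: cfg.n_proteins])
        if len(free) < n_markers:
            raise ValueError("not enough uninformative proteins for planted markers")
        chosen = rng.choice(free, size=n_markers, replace=False)
        marker_up[chosen[: cfg.n_up_markers]] = True
        marker_down[chosen[cfg.n_up_markers:]] = True
        any_disease = np.zeros(n, dtype=bool)
        for d in diseases:
            any_disease |= baseline[d].astype(bool)
        omics_values[np.ix_(any_disease, marker_up)] += cfg.marker_effect
        omics_values[np.ix_(any_disease, marker_down)] -= cfg.marker_effect

    # --- incident events ----------------------------------------------------
    mean_age = float(np.mean(age))
    event_rows = []
    for d in diseases:
        base, beta = cfg.disease_specs[d]
        lam = base * np.exp(beta * (bio_age - mean_age))
        t_event = rng.exponential(1.0 / lam)
        event = (t_event <= cfg.followup_years).astype(int)
        time_years = np.minimum(t_event, cfg.followup_years)
        event_rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "disease": d,
                    "time_years": time_years,
                    "event": event,
                }
            )
        )
    events = pd.concat(event_rows, ignore_index=True)

    # --- assemble tables ----------------------------------------------------
    participants = pd.DataFrame({"participant_id": ids, "chronological_age": age,
                                 "sex": sex, "race": race, "bmi": bmi})
    for f in LIFESTYLE_FACTORS:
        participants[f"{f}_score"] = scores[f]
        participants[f"{f}_flag"] = (scores[f] > UNHEALTHY_CUTOFF).astype(int)
    for d in diseases:
        participants[f"baseline_{d}"] = baseline[d]

    omics = pd.DataFrame(omics_values, columns=names)
    omics.insert(0, "participant_id", ids)

    # --- MCAR missingness ----------------------------------------------------
    demog_missable = ["bmi", "race"] + [f"{f}_score" for f in LIFESTYLE_FACTORS]
    if cfg.miss_demog > 0:
        for col in demog_missable:
            mask = rng.random(n) < cfg.miss_demog
            participants.loc[mask, col] = np.nan
    if cfg.miss_omics > 0:
        mask = rng.random((n, p_total)) < cfg.miss_omics
        values = omics[names].to_numpy()
        values[mask] = np.nan
        omics[names] = values

    truth = SimTruth(
        participants=pd.DataFrame(
            {
                "participant_id": ids,
                "acceleration": accel,
                "biological_age": bio_age,
                "planted_subgroup": np.isin(np.arange(n), subgroup).astype(int),
            }
        ),
        biomarkers=pd.DataFrame(
            {
                "biomarker": names,
                "modality": ["protein"] * cfg.n_proteins + ["metabolite"] * cfg.n_metabolites,
                "informative": informative.astype(int),
                "slope": slopes,
                "nonlinear": nonlinear.astype(int),
                "marker_up": marker_up.astype(int),
                "marker_down": marker_down.astype(int),
            }
        ),
    )
    return participants, omics, events, truth


# ---------------------------------------------------------------------------
# File round-trip (CSV, missing values as empty fields)
# ---------------------------------------------------------------------------

_FILES = {
    "participants": "participants.csv",
    "omics": "omics.csv",
    "events": "events.csv",
    "truth_participants": "truth_participants.csv",
    "truth_biomarkers": "truth_biomarkers.csv",
}


def write_cohort(
    out_dir: str | Path,
    participants: pd.DataFrame,
    omics: pd.DataFrame,
    events: pd.DataFrame,
    truth: SimTruth | None = None,
) -> dict[str, Path]:
    """Write cohort tables as CSV under ``out_dir``; missing values become
    empty fields. Returns the mapping of table name to written path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _check_ids(participants, omics, events)
    paths = {}
    tables = {"participants": participants, "omics": omics, "events": events}
    if truth is not None:
        tables["truth_participants"] = truth.participants
        tables["truth_biomarkers"] = truth.biomarkers
    for key, df in tables.items():
        path = out_dir / _FILES[key]
        df.to_csv(path, index=False)
        paths[key] = path
    return paths


def read_cohort(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth | None]:
    """Read tables written by :func:`write_cohort`; validates identifier
    consistency across tables."""
    in_dir = Path(in_dir)
    participants = pd.read_csv(in_dir / _FILES["participants"])
    omics = pd.read_csv(in_dir / _FILES["omics"])
    events = pd.read_csv(in_dir / _FILES["events"])
    truth = None
    tp = in_dir / _FILES["truth_participants"]
    tb = in_dir / _FILES["truth_biomarkers"]
    if tp.exists() and tb.exists():
        truth = SimTruth(participants=pd.read_csv(tp), biomarkers=pd.read_csv(tb))
    _check_ids(participants, omics, events)
    return participants, omics, events, truth


def _check_ids(participants: pd.DataFrame, omics: pd.DataFrame, events: pd.DataFrame) -> None:
    pid = set(participants["participant_id"])
    oid = set(omics["participant_id"])
    eid = set(events["participant_id"]) if len(events) else set()
    if pid != oid:
        offending = sorted(pid.symmetric_difference(oid))[:10]
        raise ValueError(
            f"participant/omics identifier mismatch, e.g. {offending}"
        )
    extra = eid - pid
    if extra:
        raise ValueError(f"event identifiers absent from participants: {sorted(extra)[:10]}")
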