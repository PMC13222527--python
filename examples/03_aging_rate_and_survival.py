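"""Derive aging rates, stratify deciles, and compare cumulative incidence.

Participants in the top aging-rate decile should accumulate incident
disease faster than the bottom decile whenever the hazard rises with
biological age.
"""

from omicage import agingrate, cohortsim, survival

cfg = cohortsim.SimConfig(n_participants=2000, n_proteins=4, n_metabolites=2,
                          n_age_informative=0, accel_sd=0.15,
                          disease_specs={"cvd": (0.01, 0.15)}, seed=6)
participants, _, events, truth = cohortsim.simulate_cohort(cfg)

# use the known acceleration as the aging metric to isolate the survival
# machinery; example 02 shows how a fitted clock produces the same metric
records = truth.participants.rename(columns={"acceleration": "aging_rate"})
top, bottom = agingrate.stratify_deciles(records)

c_top, c_bot, lr_stat, lr_p = survival.compare_strata(events, top, bottom, "cvd")
inc_top = 1 - survival.survival_at(c_top, 10.0)[0]
inc_bot = 1 - survival.survival_at(c_bot, 10.0)[0]
print(f"10-year cumulative incidence: top decile {inc_top:.3f}, "
      f"bottom decile {inc_bot:.3f}")
print(f"log-rank statistic {lr_stat:.1f}, p = {lr_p:.2e}")
# a several-fold incidence gap with a tiny log-rank p: accelerated agers
# develop the disease earlier and more often.
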