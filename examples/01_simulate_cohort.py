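"""Simulate a small multi-omics aging cohort and inspect its structure.

The generator produces a participant table (demographics + lifestyle), a
wide biomarker matrix (proteins + metabolites), a long time-to-event table,
and the latent ground truth (each participant's aging acceleration and true
biological age) that the rest of the pipeline tries to recover.
"""

from omicage import cohortsim

cfg = cohortsim.SimConfig(n_participants=500, n_proteins=100,
                          n_metabolites=30, n_age_informative=50, seed=1)
participants, omics, events, truth = cohortsim.simulate_cohort(cfg)

print(f"participants: {participants.shape}, omics: {omics.shape}, "
      f"events: {events.shape}")
print("\nfirst participant:")
print(participants.iloc[0, :6].to_string())
acc = truth.participants["acceleration"]
print(f"\nlatent acceleration: mean {acc.mean():.3f}, sd {acc.std():.3f}")
print(f"event rate over {cfg.followup_years} y follow-up: "
      f"{events['event'].mean():.3f}")
# acceleration is centred near 1 (its mean is shifted slightly above 1 by
# the lifestyle effects); ~10% of participant-disease pairs see an event.
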