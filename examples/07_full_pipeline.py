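"""Run the complete demonstration pipeline and print the key metrics.

Chains every stage (simulate, preprocess, select, clock, aging rate,
survival, risk, differential abundance, mediation, group statistics) on a
~600-participant cohort; outputs land under runs/demo/.
"""

import json

from omicage import demo_config, run_pipeline

cfg = demo_config(seed=1, out_dir="runs/demo")
out = run_pipeline(cfg)
metrics = json.loads((out / "metrics.json").read_text())

c = metrics["clock"]
print(f"clock: r = {c['pearson_r']:.3f}, RMSE = {c['rmse']:.2f} y")
print(f"selected k = {metrics['selection']['k']} features "
      f"({metrics['selection']['modality_counts']})")
print(f"rate-age orthogonality r = "
      f"{metrics['aging_rate']['orthogonality_r_test']:.3f}")
for disease, row in metrics["survival"].items():
    print(f"survival {disease}: log-rank p = {row['logrank_p']:.3f}")
print(f"top up-markers: {metrics['diffexpr']['top_up'][:5]} ...")
print(f"mediation pairs significant at 0.1: "
      f"{metrics['mediation']['n_significant_p10']}/"
      f"{metrics['mediation']['n_pairs']}")
print(f"\nfull metrics: {out / 'metrics.json'}")
# at this desk scale the clock reaches r ~ 0.85-0.9; survival and
# mediation signals are weak by design (small n, modest hazard slopes) --
# the simulation studies in omicage.studies measure them at full power.
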