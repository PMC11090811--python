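"""Generate a synthetic multi-project camera-trap study and inspect it.

Builds a complete study — detections, deployments, comparison periods,
species traits, project covariates — with known per-population effects,
then prints its dimensions and one ground-truth entry.
"""

from wildshift.simulate import SimConfig, simulate_study

cfg = SimConfig(seed=1, n_projects=4, species_pool_size=8,
                stations_per_project=8, period_length_days=30,
                true_mean_beta=-0.2)
tables, truth = simulate_study(cfg)

print(f"detections: {len(tables['detections']):6d} rows")
print(f"deployments:{len(tables['deployments']):6d} rows")
print(f"species pool: {len(tables['traits'])}, projects: {cfg.n_projects}")

pop = truth["populations"][0]
print("\nfirst population ground truth:")
print(f"  {pop['project_id']} / {pop['species']}")
print(f"  true log rate change beta = {pop['true_beta']:+.3f} "
      "(negative = less activity under higher human activity)")
print(f"  true log risk ratio rr    = {pop['true_rr']:+.3f} "
      "(positive = more nocturnal under higher human activity)")
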