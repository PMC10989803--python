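"""Full pipeline: selection schemes, CMTB, CMRA, and resistance potential.

Computes the two community indexes under both OTU-selection schemes
(cumulative-abundance prefixes and random fixed-richness draws), min-max
standardizes each across samples, combines them into the resistance
potential sqrt(CMTB_stand^2 + CMRA_stand^2), and checks that the index
ranks samples consistently across scheme-by-level variants.
"""

import pandas as pd

import commresist as cr

scen = cr.scenario_with(cr.scenario_default(), n_samples=150, n_otus=300)
sim = cr.generate_community(scen)
std = cr.standardize_env(sim.env)

cum = cr.compute_indices(sim.counts, std, cr.SelectionScheme.cumulative((0.75, 0.90)))
rnd = cr.compute_indices(
    sim.counts, std, cr.SelectionScheme.random((100,), replicates=50, seed=1)
)
print(cum[cum.level == 0.9].head())

both = pd.concat([cum, rnd], ignore_index=True)
for index in ("cmtb", "cmra"):
    mi = cr.method_independence(both, index)
    print(f"\nmin cross-variant Pearson r for {index.upper()}: {mi.r.min():.3f}")
print("  -> high r means either selection scheme yields the same community ranking")

top = cum[cum.level == 0.9].nlargest(3, "resistance_potential")
print("\nMost resistant communities at the 0.90 cumulative level:")
print(top[["sample_id", "richness", "cmtb", "cmra", "resistance_potential"]])
print("  -> resistance potential in [0, sqrt(2)]: high values combine broad "
      "tolerance with compensatory dynamics")
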