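"""Richness-gradient preset: specialist addition drives richness up, CMTB down.

The preset concentrates specialist niche optima toward one end of the
latent gradient, so communities there are richer but dominated by
narrow-niche taxa. The richness-CMTB relationship is then examined with
linear-vs-quadratic OLS selected by AIC.
"""

import commresist as cr

sim = cr.generate_community(cr.scenario_richness_gradient())
std = cr.standardize_env(sim.env)
tb = cr.tolerance_breadth_all(sim.counts, std)
rel = cr.to_relative_abundance(sim.counts)

rich = cr.richness(sim.counts).to_numpy()
cmtb_all = rel.values.T @ tb.tb

lin, quad = cr.fit_best(rich, cmtb_all)
chosen = quad if quad.selected else lin
print(f"richness range: {rich.min()}..{rich.max()}")
print(f"selected model: {chosen.model} (AIC {chosen.aic:.1f} vs "
      f"{(lin if quad.selected else quad).aic:.1f}), R^2 = {chosen.r2:.3f}")
slope = (chosen.coefficients[1] + 2 * chosen.coefficients[2] * rich.mean()
         if chosen.model == "quadratic" else chosen.coefficients[1])
print(f"slope at mean richness: {slope:.2e}")
print("  -> negative: richer communities carry a larger share of narrow-niche "
      "specialists, so their mean tolerance breadth is lower")

d, label = cr.cohens_d(cmtb_all[sim.region == 0], cmtb_all[sim.region == 1])
print(f"\nCohen's d of CMTB between the two regions: {d:.2f} ({label})")
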