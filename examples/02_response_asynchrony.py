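"""Pairwise response asynchrony and the community mean (CMRA).

Response asynchrony RA = -Spearman(rho) of two OTUs' relative-abundance
profiles across samples: +1 means the pair trades off perfectly along the
gradient (compensatory), -1 means they rise and fall together. A sample's
CMRA averages RA over distinct pairs weighted by abundance products.
"""

import numpy as np
from scipy.stats import spearmanr

import commresist as cr

scen = cr.scenario_with(cr.scenario_default(), n_samples=150, n_otus=150)
sim = cr.generate_community(scen)

rel = cr.to_relative_abundance(sim.counts)
ra = cr.spearman_matrix(rel)
print(f"RA matrix: {len(ra.otu_ids)} x {len(ra.otu_ids)}, "
      f"range [{np.nanmin(ra.ra):.3f}, {np.nanmax(ra.ra):.3f}]")

# asynchrony grows with the distance between specialist niche optima
spec = np.nonzero(~sim.niches.is_generalist)[0]
iu = np.triu_indices(len(spec), k=1)
dmu = np.abs(sim.niches.mu[spec][:, None] - sim.niches.mu[spec][None, :])[iu]
rsub = ra.ra[np.ix_(spec, spec)][iu]
ok = np.isfinite(rsub)
rho = spearmanr(dmu[ok], rsub[ok]).statistic
print(f"Spearman(|optimum distance|, RA) among specialists = {rho:.3f}")
print("  -> pairs with distant optima respond more asynchronously, as the model intends")

cmra_first = cr.cmra(rel.values[:, 0], ra)
print(f"\nCMRA of sample {sim.counts.sample_ids[0]}: {cmra_first:.4f}")
print("  -> near 0: synchronous and compensatory pairs balance; "
      "positive values mean compensation dominates")
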