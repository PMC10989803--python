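# commresist

Estimates how resistant a soil (or any) microbial community is likely to be
to environmental change, from nothing more than an OTU count table and a
table of environmental measurements. It is aimed at microbial ecologists
working with amplicon survey data across an environmental gradient.

## The indexes

Two complementary community properties are quantified:

**Tolerance breadth (TB)** of an OTU *m*: with $a_j$ its reads in sample
*j* and $x_j$ sample *j*'s vector of z-scored environmental variables, the
abundance-weighted centroid of its occupied samples is

$$C = \frac{\sum_j a_j x_j}{\sum_j a_j},$$

and TB is the abundance-weighted mean distance to it,

$$\mathrm{TB}_m = \frac{\sum_j a_j \lVert x_j - C \rVert}{\sum_j a_j}.$$

Large TB marks a habitat generalist, small TB a specialist; labels are
assigned at symmetric TB quantiles (e.g. 0.95/0.05). The **community mean
tolerance breadth** (CMTB) of a sample is the relative-abundance-weighted
mean TB of its (selected) OTUs.

**Response asynchrony (RA)** of an OTU pair is the negated Spearman
correlation of their relative-abundance profiles across all samples
($\mathrm{RA}_{ij} = -\rho_{ij}$); +1 is perfectly compensatory, −1
perfectly synchronous. The **community mean response asynchrony** (CMRA)
weights each pair by the product of relative abundances:

$$\mathrm{CMRA} = \frac{\sum_{i<j} a_i a_j \mathrm{RA}_{ij}}{\sum_{i<j} a_i a_j}.$$

OTUs enter each sample's indexes by one of two selection schemes — the most
abundant OTUs up to a cumulative-abundance level (0.75–0.90), or a fixed
number drawn at random from those present (averaged over 100 replicate
draws) — and the schemes are checked against each other for consistency.
After min–max standardizing each index onto [0, 1] across samples, the
**resistance potential** combines them:

$$\mathrm{RP} = \sqrt{\mathrm{CMTB}_\mathrm{stand}^2 + \mathrm{CMRA}_\mathrm{stand}^2} \in [0, \sqrt{2}].$$

A niche-model simulator (Gaussian niches on a latent gradient shared by six
correlated observed variables, multinomial fixed-depth counts) provides
communities with known ground truth, so every estimator is validated by
parameter recovery. See `docs/methods.md` for the model details.

## Worked example

```python
import commresist as cr
from scipy.stats import spearmanr

sim = cr.generate_community(cr.scenario_default())   # 400 samples, 600 OTUs
std = cr.standardize_env(sim.env)
tb  = cr.tolerance_breadth_all(sim.counts, std)
print(spearmanr(sim.niches.sigma, tb.tb).statistic)  # 0.906

out = cr.compute_indices(sim.counts, std, cr.SelectionScheme.cumulative((0.9,)))
print(out[["sample_id", "cmtb", "cmra", "resistance_potential"]].head(3))
```

prints a rank correlation of **0.906** between each OTU's true niche breadth
and its estimated TB — the estimator orders taxa by their real tolerance
range — followed by the per-sample indexes, e.g.

```
  sample_id      cmtb      cmra  resistance_potential
0     S0000  1.900172 -0.292112              0.825109
1     S0001  1.660488 -0.257733              0.377087
2     S0002  1.602039 -0.210672              0.458617
```

where `cmtb` is the mean tolerance breadth of the selected OTUs (in
standardized-environment distance units), `cmra` their weighted pairwise
asynchrony (−1…1), and `resistance_potential` the combined standardized
index (0…√2; larger = more buffered against environmental change).

The scripts in `examples/` walk through each capability: TB estimation and
ecotype classification, the asynchrony matrix, the full two-scheme pipeline,
and the richness-gradient preset in which specialist addition makes richer
communities *less* tolerant on average.

A thin CLI mirrors the library:

```sh
commresist simulate --preset richness_gradient --seed 42 --out sim/
commresist tb --counts sim/counts.tsv --env sim/env.csv --out tb.csv
commresist indices --counts sim/counts.tsv --env sim/env.csv \
    --scheme cumulative --levels 0.75,0.9 --out indices.csv
commresist analyze --indices indices.csv --out report/
```

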