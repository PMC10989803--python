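# Methods

## Tolerance breadth

Tolerance breadth (TB) is an abundance-weighted multivariate dispersion: for
OTU *m* with reads $a_j$ in sample *j* and standardized environment vectors
$x_j$, the weighted centroid of occupied samples is
$C = \sum_j a_j x_j / \sum_j a_j$ and
$\mathrm{TB}_m = \sum_j a_j \lVert x_j - C\rVert / \sum_j a_j$. It is
unbounded above, zero when the OTU occupies one sample (or several samples
with identical environments), and invariant to positive rescaling of the
weights, so raw counts and relative abundances are interchangeable (tested).

Distances are Euclidean on z-scored variables. Dispersion around a weighted
centroid can be computed from any dissimilarity via principal coordinates;
the direct computation in variable space is exactly the PCoA route when the
dissimilarity is Euclidean (no negative eigenvalues), and is O(OTUs × samples
× variables) rather than O(samples³). A PCoA path with the standard
negative-eigenvalue correction $z = \sqrt{\max(z_+^2 - z_-^2, 0)}$ is
provided for non-Euclidean metrics; equivalence of the two paths under
Euclidean input is asserted by test.

Standardization uses the sample-sd (n−1) convention over *all* samples in
the supplied environment table, so TB values of different OTUs share one
environmental scale. Consequence: TB values are only comparable within one
standardization scope; subsetting samples changes the scale.

Generalists/specialists are the upper/lower tails of the TB distribution at
a symmetric quantile pair (q, 1−q), q ∈ (0.5, 1); the conventional choices
are 0.75–0.95. Quantiles use linear interpolation (type 7). Thresholds are
inclusive (≥ / ≤); an OTU qualifying for both tails — possible only for
degenerate TB distributions — is labelled `neither` and logged.

## Response asynchrony

$\mathrm{RA}_{ij} = -\rho_{ij}$, the negated Spearman correlation of two
OTUs' relative-abundance profiles. Ranks use the average-ties convention.
Correlations are computed once over the full sample set, zeros included;
this treats shared absence as synchrony, which is the intended reading of a
cross-sectional gradient design. A per-pair co-occupied-samples variant
(`occupied_only=True`) is exposed for sensitivity analysis, not as the
default. OTUs with constant profiles have undefined rho; their entries are
NaN and they drop out of both the numerator and denominator of every CMRA.

CMRA averages RA over unordered distinct pairs (i < j), weighted by
abundance products. Self-pairs are excluded: each would contribute a
constant −1 and bias every community toward apparent synchrony. CMRA is
bounded by the min/max of the selected pairwise RA values and is invariant
to uniform rescaling of the weights (both tested). The implementation is a
single matrix quadratic form per sample (exactly equal to the explicit pair
loop), so 100 replicate selections over 400 samples run in seconds.

## Selection schemes and the resistance potential

Cumulative mode takes the smallest descending-abundance prefix whose
cumulative relative abundance reaches the level (ties broken by OTU id
order; the cumulative comparison uses a 1e-12 guard against float
round-off). Random mode draws a fixed number of OTUs uniformly from those
present, with per-(sample, level) substreams derived from one master seed so
results are independent of iteration order; indexes are computed per
replicate and then averaged. Samples whose richness is below a random level
are excluded from that level with a warning — never silently.

Weights are the original within-sample relative abundances of the selected
OTUs, not renormalized; both indexes are ratio-weighted means, so
renormalization is a no-op (tested).

Min–max standardization maps each index onto [0, 1] across all samples
within one scheme-by-level variant; a zero range raises an error naming the
degenerate index. The resistance potential is the Euclidean norm of the
standardized pair, in $[0, \sqrt 2]$. Method independence is summarized by
all pairwise Pearson correlations of per-sample index vectors across
variants, computed on the samples shared by each pair (≥ 3 required).

## Regression selection, effect sizes, climate variability

Linear vs quadratic OLS fits are compared by Gaussian-likelihood AIC
(statsmodels convention: k counts intercept, slopes, and the variance). Only
AIC *differences* drive the selection, which is invariant to the additive
likelihood constant (tested against the n·log(RSS/n) + 2k convention); ties
go to the simpler model. Cohen's d uses the pooled n−1 standard deviation
with magnitude labels N/S/M/L at |d| cuts 0.2/0.5/0.8, sign preserved.
Annual climate variability is the mean over years of the within-year CV
(sample sd / mean of the 12 monthly values).

## The simulator

Samples receive a latent gradient position $g_j$ from a two-cluster Gaussian
mixture (means ±1.5, sd 0.6, equal weights), emulating a survey spanning two
environmentally distinct regions. The six observed variables (named after
typical edaphic/climate measurements: pH, moisture, TOC, TN, AMT, AP) are
linear loadings of $g_j$ (mixed signs, magnitudes 0.6–0.95) plus Gaussian
noise of sd 0.3, so they are strongly intercorrelated as in real gradient
data. Each OTU has a Gaussian niche
$\lambda_{mj} = A_m \exp(-(g_j-\mu_m)^2 / 2\sigma_m^2)$ with optimum
$\mu_m \sim U(-2.5, 2.5)$, breadth $\sigma_m \sim U(2, 4)$ for generalists
(30% of the pool) and $U(0.35, 1.1)$ for specialists, and peak intensity
$A_m \sim \mathrm{lognormal}(0, 0.5)$. Counts are one multinomial draw of
fixed depth per sample from the normalized intensities — the natural model
for post-rarefaction tables, with zeros arising when a niche is far from a
sample's gradient position.

Default scenario: 400 samples, 600 OTUs, depth 5000, seed 42 — small enough
for the full pipeline to run in seconds, large enough for stable recovery
statistics. A study-scale preset (472 samples, depth 9736) mirrors the field
design the generator emulates. The `richness_gradient` preset draws
specialist optima from a triangular density increasing along the gradient,
so high-gradient samples recruit from a larger specialist pool: richness
rises while CMTB falls, giving a negative richness–CMTB association driven
by specialist addition. The simulator captures niche structure, regional
clustering, correlated variables, and fixed-depth sampling noise; it does
*not* model compositional sequencing bias, taxon interactions, temporal
dynamics, or spatial autocorrelation — recovery results demonstrate
estimator correctness under the stated model, not robustness to those
real-data complications.

What recovery looks like at the default seed: Spearman(σ_true, TB) ≈ 0.91;
true generalists are ~3.3× enriched among OTUs labelled generalist at
q = 0.75 (the maximum possible given a 30% pool share is 3.33); among
specialist pairs, Spearman(|μ_i − μ_j|, RA) ≈ 0.93; min cross-variant
Pearson r across the feasible scheme×level variants is ≈ 0.94 for CMTB and
≈ 0.99 for CMRA (the CMTB minimum varies roughly 0.86–0.96 over simulator
seeds; the CMRA minimum is stable above 0.98).

One structural note on selection levels: with a 600-OTU pool at depth 5000,
simulated richness tops out near 480, so the fixed-richness levels 500/700/
900 have no qualifying samples and are excluded by the selection rule; the
method-independence check therefore spans the four cumulative levels plus
random selection of 300. The levels themselves are kept at their
conventional values rather than rescaled to the simulation.

## Numerical choices and degenerate inputs

- TB distances via the expanded quadratic form with clipping at 0 before the
  square root (guards tiny negative round-off).
- Relative-abundance columns must sum to 1 within 1e-9; zero-sum samples are
  an error, not a silent NaN.
- Rarefaction is one multivariate-hypergeometric draw per sample from a
  seeded generator; samples below depth raise an error unless `drop_short`
  is set, which logs what was dropped.
- Singleton-occupancy OTUs get TB = 0 and are flagged via `n_occupied` so
  downstream users can filter.
- CMRA with fewer than two usable OTUs is NaN (explicit marker), never 0.
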