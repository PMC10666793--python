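# Methods

## Data model

All analyses run on three carriers.  A `FeatureTable` is a samples ×
taxa matrix of non-negative counts (or per-sample relative abundances
summing to 1); tables are used as-is — no rarefaction is applied,
because none of the downstream statistics requires it and an unstated
subsampling step would add a silent filter.  A `SampleFrame` holds the
per-sample design (site, local area, successional stage A < C < M,
transect coordinate in km) and the environmental variables, each
assigned to one of three blocks: climatic, edaphic, biotic.  Trees are
rooted newick phylogenies with non-negative branch lengths; taxa used
with a tree must be a subset of its tips (a hard error otherwise), and
missing branch lengths default to 0 with a warning.

## Diversity indices

Shannon *H′* uses the natural logarithm; Pielou *J* = *H′*/ln *S*
is undefined (NaN) for single-taxon samples.  Faith PD includes the
path from the observed crown group to the root, the default of the
mainstream implementations; a `include_root=False` flag gives the
crown-only sum.  Weighted UniFrac defaults to the raw form
Σ_e b_e |P_e(x) − P_e(y)| over edges, since published analyses that do
not say otherwise typically use it; the normalised form (divide by
Σ_e b_e (P_e(x)+P_e(y)), bounded in [0, 1]) is a flag.  Both
phylogenetic metrics delegate to scikit-bio and are validated in the
test suite against a brute-force edge-enumeration oracle.

The Sørensen partition uses presence = abundance > 0 with no abundance
filtering.  β_nes is stored as the float difference β_sor − β_sim;
additivity is exact as a rational identity in (a, b, c) and holds to
1 ulp in floats.  The turnover ratio β_sim/β_sor is NaN for identical
samples (β_sor = 0) and such pairs are dropped from correlations.

Per-stage β values are means over qualifying pairs (not multi-sample
statistics): *local* pairs are the four parallel replicates sharing
site and stage (C(4,2) = 6 pairs per cell; cells with fewer than two
samples are skipped with a warning), *continental* pairs share stage
but differ in site.

## Permutation statistics

ANOSIM follows Clarke: with all M = n(n−1)/2 pairwise dissimilarities
ranked (midranks for ties), R = (mean between-group rank − mean
within-group rank)/(M/2), so R = 1 under complete separation and
E[R] = 0 under random labels.  The Mantel statistic is the Spearman
correlation of the off-diagonal entries of two distance matrices.  Both
use the permutation p-value (1 + #{stat_perm ≥ stat_obs})/(perm + 1),
one-sided "greater" by default (the vegan convention); Mantel also
offers two-sided.  Permutation counts default to 999.  Environmental
distance matrices are Euclidean over Z-scored columns (sample sd;
constant columns dropped with a warning), making them invariant to
affine rescaling of any input variable.

Stage contrasts use one-way ANOVA (df = 2 for three stages) with a
Tukey-HSD compact letter display: letters are maximal cliques of the
"not significantly different" graph, assigned 'a' first to the clique
containing the largest mean, so the letters reconstruct the pairwise
significance pattern exactly.  Tukey HSD is a choice — the original
workflow names only "ANOVA" — and is switchable.

## Ubiquitous taxa and the ELAD

Occupancy is the fraction of a scope's samples in which a taxon is
present; membership requires occupancy *strictly above* the threshold
(default 0.85).  The α-vs-ubiquitous-abundance relationship reports
Spearman ρ plus a one-breakpoint piecewise-linear fit (slope 0 after
the break, 81-point grid between the 10th and 90th abundance
percentiles) whose breakpoint estimates where α stops responding.

The cumulative-abundance filter ranks taxa by total relative abundance
(ties broken by taxon id) and keeps the smallest prefix reaching the
target fraction (≥ rule, so an exact boundary is included).

The ELAD is computed on the community's own phylogeny: tips absent
from the community are pruned first.  Each edge contributes one
(A_e, b_e) record, where A_e is the summed relative abundance (or tip
count) below the edge; summaries are log₂-spaced abundance bins (bin
totals conserve total branch length exactly) and the cumulative curve
of branch length over edges ranked by ascending A_e.  The curve's
elbow — the point of maximum distance to the chord joining its
endpoints, reported as a rank fraction — makes "earlier vs later
elbow" comparisons between successional phylogenies assertable.  The
cited ELAD literature does not fix a binning, so both weighting modes
are provided.

## Balanced biogeography

For every pair of sites that both carry all three stages, the same
samples are grouped two ways: *among stages* (three stage groups, each
pooling both sites) and *between sites* (two site groups, each pooling
all stages).  Whole-group ANOSIM would use a fixed sample count; to
decouple the statistic from group size, each of 100 "combinational
comparisons" draws a per-group subset size uniformly from
{4, 6, 8, 10, 12} (capped by availability, never below 2), samples
that many members per group without replacement, and computes R on the
subset.  Site-pair enumeration is exhaustive by default.

The per-combination R values are regressed on inter-site distance by
OLS, one line per scheme.  The response defaults to R rather than R²:
noisy combinations can produce negative R, and squaring would fold
those onto positive values; an `R_squared` flag is available.  The
intersection d* = (b_among − b_between)/(s_between − s_among) is
reported only in the balanced configuration — among-stages slope
significantly negative and between-sites slope significantly positive
(two-sided t-test, α = 0.05) — because a crossing of two flat or
same-signed trends is not the phenomenon of interest.  A bootstrap
interval resamples combination records within each scheme.  Note the
per-combination rows within one site pair share samples and are
correlated; for hypothesis-style statements about slopes the per-pair
mean R is the appropriate unit, and the tests use it.

## Environmental models

Multicollinearity screening removes predictors greedily: while any
pair has |Pearson r| ≥ 0.8, the member of the worst pair with the
larger mean absolute correlation to the remaining predictors is
dropped (column order breaks ties).  All-subset regression enumerates
every predictor subset up to `max_size`, fits OLS, selects the highest
R² (the GoF for linear models), and breaks ties within 1e-9 by the
lower AIC, computed from the Gaussian log-likelihood with its constant
and k = #coefficients + 1 (for σ²).  Singular subsets are skipped
with a warning.  A residual skewness/kurtosis check is reported as a
diagnostic flag, never as a gate.

The PLS path model operates on aligned lower-triangle
pairwise-distance vectors: Z-scored Euclidean distances per
environmental block (one indicator per variable, or one per block),
the integrated-α block (Euclidean over Z-scored PD, richness, Pielou),
and the taxonomic (Bray-Curtis) and phylogenetic (weighted UniFrac) β
blocks.  Estimation is Lohmöller's alternating algorithm with mode A
outer weights and the centroid inner scheme (the common defaults),
tolerance 1e-6 on the maximum score change, at most 300 iterations
(non-convergence raises).  Each latent's sign is fixed to correlate
positively with its first indicator, so results are deterministic.
Path coefficients come from per-equation OLS on latent scores under
the declared acyclic causal order (environment → β diversity →
integrated α by default); GoF = √(mean communality × mean R²).
Pruning removes the single weakest indicator with |loading| < 0.7 and
refits, iterating to a fixpoint; an emptied block removes its latent
and paths.  Because pairwise-distance observations are not
independent, no p-values are attached to paths.

## Synthetic metacommunity generator

The generator emulates the sampling design: sites paired into local
areas along a 3,000 km transect (default 8 sites / 4 areas, offset
±25 km within an area), three stages per site, four parallel
replicates per site × stage, fixed sequencing depth (multinomial,
N = 2,000 reads), species pool of 300.  Species get lognormal base
abundances, uniform home locations, and a niche position on the
successional axis.  The expected composition multiplies the base
abundance by a Gaussian range kernel (width λ = 600 km) and a
stage-affinity weight whose exponent is scaled by the convergence
strength κ (default 1): κ is the strength of stage-driven niche
selection, and at κ = 0 succession imposes no compositional structure
at all.  Convergence acts through κ twice more: species ranges widen
with stage (λ_s = λ(1+κs)), so late-stage communities are alike across
distant sites, and replicate-level lognormal noise shrinks with stage,
so local β falls too.  The domain profile sets whether stage-affinity
breadth broadens with stage (`bacteria_like`: generalist turnover,
α rises A→M) or narrows (`eukaryote_like`: specialist turnover,
α falls).  Environmental columns are smooth monotone functions of
position (climatic), site + stage effects (edaphic) or stage effects
(biotic), each plus Gaussian noise.

What the generator does *not* emulate: unequal group sizes (the field
design had 140/24/36 samples per stage), stage-dependent read depth,
compositional zero-inflation beyond multinomial sampling, taxonomy,
and any attempt to fit the simulator to the deposited field data.
Passing tests therefore demonstrate that the machinery recovers
planted structure of the kind the field data are believed to carry,
not that the field estimates themselves are reproduced.

## Problem sizes and numerical choices

The test suite runs most Monte-Carlo properties at the generator's
default conditions (96 samples, 300 species); scale-sensitive checks
that need many replicate simulations use a reduced 6-site / 150-species
/ 1,000-read configuration, chosen so each simulation still carries all
the planted structure.  The planted-crossing check for the
regression/intersection machinery draws combination-comparison records
directly around two linear group-mean R trends constructed to cross at
1,500 km, because a mechanistic simulation cannot plant an analytic
crossing.  Tie-breaks are deterministic everywhere (column order,
taxon id, first-indicator sign convention); every stochastic routine
takes an explicit seed, and the pipeline writes a config hash alongside
its outputs so a run is reproducible byte-for-byte.

## Known limitations

- The ANOSIM-R-on-distance regression treats combination draws as
  observations; their correlation within a site pair means the
  reported per-line R² and slope p-values are descriptive for raw
  draws.  Aggregate to per-pair means for inference.
- The piecewise-linear breakpoint is a grid estimate, not a smooth
  optimum; its resolution is bounded by the 81-point grid.
- PLS-PM path "significance" is intentionally not reported; bootstrap
  intervals over samples (not pairs) would be the defensible route and
  are left to the user.
- Great-circle handling of lat/lon inputs is limited to a 1-D transect
  coordinate; fully 2-D spatial designs reduce to pairwise distances
  supplied directly.
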