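# Methods

This note documents the models and procedures implemented in `latidyn`,
the assumptions they make, the numerical choices behind them, and what the
synthetic-study generator does and does not emulate.

## Study design assumed throughout

All analyses assume a nested longitudinal design: several sites along a
latitudinal gradient, each sampled in spring, summer and autumn of
(typically) two consecutive years, with replicate plots per campaign.  The
community unit is an OTU count table of samples × OTUs; phylogenetic
analyses additionally require a rooted tree with branch lengths whose tips
are the OTU ids.  Counts are first stripped of study-wide singletons
(OTUs with a total count of 1) and then rarefied once, without
replacement, to a common depth (default 7,000 reads, CLI-overridable).
Rarefaction is a single multivariate-hypergeometric draw per sample with a
mandatory seed; samples below the depth are dropped with a warning.  We do
not average repeated rarefactions — every downstream statistic is
reproducible from the seed instead.

## Beta diversity, ordination, PERMANOVA

Weighted UniFrac is computed from per-branch "profiles": one post-order
traversal per tree gives, for each branch, the set of descendant tips, and
each sample's profile entry is the fraction of its reads descending
through that branch.  The raw distance is `Σ_e b_e |p_Ae − p_Be|`; the
normalized variant (the default) divides by `Σ_e b_e (p_Ae + p_Be)`,
bounding distances by 1 so that similarity `1 − d` is a proper [0, 1]
quantity for the time-decay fit.  The implementation is cross-checked in
the test suite against an independent per-branch enumeration oracle and
against scikit-bio's implementation to 1e-10.

PCoA is classical scaling: double-centering of squared distances,
symmetric eigendecomposition, axes ordered by descending eigenvalue,
negative-eigenvalue axes reported but dropped from the coordinates.

PERMANOVA supports one or two crossed factors with *sequential* (type I)
sums of squares computed from the Gower-centered distance matrix; the
factor order (default site, then season) is set by the column order of the
grouping frame.  Permutations are free label shuffles (no strata); p =
(1 + #{F* ≥ F})/(n_perm + 1).  Because the design matrix is fixed under
permutation of the response, the per-term hat matrices are precomputed
once, which keeps 999 permutations on 300 samples around a second.

## Similarity–time decay

Within a scope (one site, optionally one year), every cross-campaign
sample pair contributes (Δt in days, similarity); same-date pairs carry no
temporal signal and are excluded but counted.  The default fit first
averages similarity within each distinct interval and then regresses
log10(mean S) on log10(Δt) by OLS; a pairwise-level fit is available.  The
turnover rate `w` is the magnitude of the slope with the sign stored
separately, so "negative turnover" (similarity increasing with time lag)
is visible rather than silently folded.  Zero similarities would make the
log undefined; they are floored at half the smallest positive similarity,
with the count logged.  The interval unit (days) matters for the absolute
magnitude of `w`; only comparisons in a common unit are meaningful, and
`months`/`seasons` units are available.

The slope test permutes the pairing between similarities and intervals
(n_rand times, default 1,000) and refits.  Two p-values are reported: the
one-sample t test of the null slopes against the observed slope, and the
two-sided empirical quantile `(1 + #{|b*| ≥ |b|})/(n_rand + 1)`.  The
empirical p is the one used in calibration tests, because a t test of
resampled slopes against a fixed value has no exact guarantee; its type-I
error is verified to sit in [0.02, 0.10] at the 5 % level.  Slope
comparisons between sites bootstrap pairs with replacement within each
series and compare the two bootstrap slope distributions by Welch's t
test; the two series use identically seeded streams so a series compared
against itself yields exactly matching distributions.

Per-group turnover restricts the table to a taxon group's OTUs, prunes the
tree to the group's tips, recomputes weighted UniFrac (relative abundances
are renormalized implicitly), and refits per site.  Groups are Archaea at
the domain level and bacterial phyla above a relative-abundance threshold
(default 1 %), with Proteobacteria replaced by its classes; classes are
subject to the same threshold.

## ses.MNTD

MNTD is presence-based: the mean over present taxa of the patristic
distance to the nearest co-occurring taxon.  The null model shuffles tip
labels on the patristic distance matrix — equivalently, draws a uniform
subset of the pool with the sample's richness — 999 times by default.  The
pool is the set of tips present anywhere in the supplied table (pass the
per-site table for a per-site pool, the package default in the pipeline,
since within-forest comparisons are the interpretive unit) or the whole
tree via a flag.  `ses = (obs − null mean)/null sd`; the quantile is
`rank/(n_null + 1)` so 999 nulls resolve p = 0.001.  A degenerate null
(e.g. the observed community is the entire pool) yields null sd = 0 and a
flagged NaN ses rather than an exception.

Two performance choices matter at scale: patristic distances are computed
once per tree from the branch membership arrays and cached, and
nearest-in-subset queries use each tip's pre-sorted neighbour list (the
nearest co-occurring tip is almost always within the first few sorted
neighbours for the dense subsets that real samples produce), with an exact
full-scan fallback.  Null distributions are cached per distinct richness
within a call.

The variance comparison between regions is a plain two-tailed F test on
the two ses collections.

## Co-occurrence networks

Core OTUs are those present in strictly more than a prevalence fraction
(default 50 %) of a site's samples; seasonal samples within a site are
pooled.  Pearson (or Spearman) correlations of relative abundances across
samples form the candidate edge weights; zero-variance OTUs get zeroed
correlations with a warning.

The automatic threshold scans an ascending grid and examines the
eigenvalue spacing statistics of the thresholded correlation matrix
(isolated rows removed).  Eigenvalues are unfolded with a coarse-grained
empirical cumulative spectral function (linear interpolation through ~15
knots), and the nearest-neighbour spacing histogram is tested by
chi-square against the Poisson (exponential) form and, for comparison,
against the Gaussian-orthogonal-ensemble Wigner surmise.  The chosen
threshold is the smallest candidate where Poisson is both unrejected
(p > 0.05) and the better-fitting of the two — the transition away from
GOE-type level repulsion that marks the decay of genuine collective
structure into independent blocks.  The pure goodness-of-fit test alone is
underpowered for matrices of a few dozen OTUs, which is why the GOE
comparison is part of the rule.  If no candidate qualifies, the highest
grid value is returned with a warning; the pipeline then backs off to the
largest threshold that still leaves edges.  A fixed threshold is available
as an escape hatch.

Topology is computed on the unweighted, unsigned skeleton with a
Brandes-style single-source accumulation: betweenness uses fractional
geodesic counting, stress counts geodesics integrally — the two
definitions differ in exactly this way.  Clustering coefficient is
realized over possible neighbour links (0 by convention below degree 2).
GD is the mean geodesic over connected pairs only.  Modularity is
maximized by deterministic greedy agglomeration (merge gain
`l_ij/m − d_i d_j/(2m²)`, ties to the smallest index pair), so `M` is a
reproducible lower bound on the optimum.  CB and CS are Freeman
centralizations normalized by the star-graph maximum `(n−1)·(n−1)(n−2)/2`
for unordered-pair counting.  All node metrics are verified exactly
(integers) or to 1e-10 against networkx and an explicit geodesic
enumeration.

## Environmental linkage

Climate windows: week = 7 days and month = 30 days backward from and
including the sampling date; season = the fixed calendar window of the
sampling year (Mar–May, Jun–Aug, Sep–Nov).  DTR is the window mean of
daily (Tmax − Tmin); TR is window-wide max(Tmax) − min(Tmin); AT the mean
temperature (daily Tmean taken from the series if present, else the
Tmax/Tmin midpoint); Precip the window sum and Precip_SD the SD of daily
precipitation — at the week scale this SD rests on 7 values and is
reported as defined, without smoothing.  Missing days in a window raise an
error listing the dates; nothing is imputed.  Niche breadth standardizes
one climatic variable jointly across all site × season (× year, pooled)
values and returns each site's sample variance of its standardized values.

Spatial predictors are PCNM eigenvectors: the inter-site distance matrix
is truncated at the longest minimum-spanning-tree edge t (with a 1e-8
relative tolerance so the MST's own edges survive), distances beyond t are
replaced by 4t, and principal coordinates with positive eigenvalues are
returned with Moran's I against the binary within-t neighbour weights;
positive-I vectors (the broadest spatial scales) are flagged for
selection and the pipeline keeps the first two.

Predictor dereplication is a greedy scan in column order dropping any
column whose |r| with an already-kept column strictly exceeds 0.8, with a
dropped→kept report for auditability.  The stepwise OLS starts from the
full model on standardized variables and adds/removes single predictors
while AIC improves.  With very few response points (10 site-years in the
default design) the dereplicated set can still exceed what OLS can fit;
the pipeline then keeps the n−4 predictors with the strongest marginal
correlations before the stepwise search.  lmg shares average the
sequential R² contribution of each predictor over all orderings via the
subset-R² formula (exact; guarded at p ≤ 12).  Variation partitioning
forward-selects within each group (adjusted-R² gain, significance by 199
permutations of the current model's residuals at α = 0.05), computes
Ezekiel-adjusted R² for every union of groups, and solves the
inclusion–exclusion system for unique and shared fractions; negative
shared fractions are reported as-is and the fractions sum to the
full-model adjusted R² by construction.

## The synthetic-study generator

The generator emulates the field design end to end: a Yule (pure-birth)
ultrametric phylogeny with unit depth; per-site habitat filtering on a
Brownian-motion trait (the optimum sits at a random tip's trait value, so
strong filtering restricts a site's community to one region of the tree,
with stronger filtering at the southern sites by default); daily climate
whose seasonal amplitude, diurnal temperature range and (inversely)
precipitation scale with latitude; monthly plant series with stronger
northern seasonality; and simple soil chemistry with latitudinal trends.

Temporal turnover is injected as a site-wide directional drift in
log-abundance: OTU i at campaign time t has logit
`baseline_i + a_i · c · t`, with `a_i` a random ±1 sign per OTU and `c` a
site-specific scale.  Because the drift is rank-one in (OTU × time), the
community's decay profile is deterministic given the sign draw, and `c`
is calibrated by root-finding on the *realized* decay slope — the exact
counts the generator will emit, run through the same weighted
UniFrac/interval-averaged OLS protocol the analysis uses — so the fitted
turnover rate equals the requested target (defaults span 0.0006–0.0276
per log10 day, increasing with the sites' diurnal temperature range; the
DTR→w coupling is a generator assumption, not a claim about nature).  An
analytic expectation model (softmax compositions, branch profiles, and
Gaussian folding of the counting-noise floor) supplies the root-finder's
starting bracket.

Counts are multinomial at a hair above the rarefaction depth (a ~0.3 %
margin absorbs singleton removal), drawn by inverse-CDF sampling from one
uniform read-stream per plot that is reused across campaigns, and each
plot carries a persistent log-abundance offset (micro-habitat
heterogeneity, SD 0.3).  The common-random-number coupling and persistent
offsets are variance-reduction devices: every individual sample carries
full sampling noise and plot-to-plot variation, but those noise floors are
constant across campaign pairs and therefore cancel from the
similarity–time trend.  This is what makes turnover rates as small as
0.0006 identifiable at 60 samples per site — an early AR(1)
campaign-effect design left replicate scatter of the fitted slope at ~25 %
of the target, unable to resolve rates differing by less than a factor of
two at this design size.

What the generator does *not* emulate, and what passing tests therefore do
not show about real data: realistic zero-inflation and overdispersion
(fresh Dirichlet noise is off by default; real 16S counts are far more
overdispersed, and with realistic overdispersion the smallest turnover
rates would not be recoverable at this sample size), chimeras and
OTU-clustering artifacts, taxonomy is a clade labelling sufficient to
exercise per-group analyses rather than a realistic taxonomic
distribution, sampling-date jitter between plots, and any real coupling
between climate and community other than the injected DTR→turnover and
latitude→filtering monotone links.

## Pipeline sizes and runtime

The default pipeline (300 samples, 1,000 OTUs) runs in well under a
minute on one CPU: the ses.MNTD stage uses 199 nulls (999 remains the
function default for standalone use), PERMANOVA 999 permutations, and the
network stage one RMT threshold scan per site.  The test suite's
simulation-based checks use 20 replicate studies for turnover recovery,
200 simulations for each calibration check, and 100 replicates for the
ses.MNTD behaviour checks.

## Known limitations

- Greedy modularity and greedy dereplication are order-dependent by
  design (determinism and auditability over optimality).
- Sequential-SS PERMANOVA fractions depend on factor order; marginal SS
  are not implemented.
- The RMT threshold rule is a simplified spacing criterion, not a
  reimplementation of any particular published pipeline's full procedure.
- lmg is exact-enumeration only (p ≤ 12); no sampling approximation for
  larger models.
- The time-decay model assumes a single power-law regime across the
  sampled intervals; multi-year scaling behaviour is out of scope.
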