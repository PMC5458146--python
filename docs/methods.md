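# Methods

This note documents the models and procedures implemented in `paleospread`,
the parameter choices that matter, and the limits of what the synthetic
tests demonstrate.

## Data model and cleaning

An occurrence links a taxon (name + rank) to a collection (locality) with
palaeocoordinates, a reference (publication) and an age interval
[min_ma, max_ma]. Cleaning removes occurrences that are generically
indeterminate and those carrying any of the exclusion flags (marine, flying,
ichno, oo, soft-tissue) or names on a user-supplied wastebasket list.
Taxonomic identities are deliberately *not* hard-coded: which genera count
as wastebasket or marine is expert judgement, so the filters act on flags
and name lists supplied by the user. Repeated rows of one taxon in one
collection are collapsed to a single occurrence before any counting
(configurable off), matching database occurrence semantics.

Time bins are closed intervals ordered old→young; an occurrence is assigned
to a bin only if its age interval lies entirely within the bin
(boundary-equal ages count as inside). Occurrences spanning a boundary are
excluded from per-bin pools rather than apportioned. The packaged Tr1–Pg2
scheme uses approximate ~9–10 myr stage groupings on the 2016 timescale
(Pg1 = Selandian–Thanetian, Pg2 = Ypresian); it is a convenience default,
clearly approximate, and any scheme can be supplied as CSV.

Richness estimates backed by fewer than `min_refs` references (default 20)
are flagged suppressed but retained in outputs, so the reporting threshold
is an annotation, not a deletion.

## Spread metrics

All geometry lives on a sphere of radius 6371.0 km (mean Earth radius; one
degree of arc ≈ 111.19 km). Localities are binned into equal-angle 1° cells
anchored at (0°, 0°), indexed by floor division, longitudes normalized into
(−180°, 180°]; cell centroids stand in for their member localities, which
removes the contribution of sub-grid locality clustering from all spread
measures. The grid is equal-angle rather than equal-area; cell area shrinks
poleward, which matters little at the temperate palaeolatitudes where most
collections lie, and follows standard practice for this kind of analysis.

The primary spread metric is summed MST length: the minimum total
great-circle length of segments connecting all occupied cells. The MST is
exact (Kruskal over the complete graph); equal-weight ties break toward the
lexicographically smallest cell-id pair, so results are deterministic.
Supporting metrics: maximum pairwise great-circle distance; standard
distance (RMS great-circle distance of cells from their geographic mean
point, the renormalized mean of the cells' unit vectors — lat/lon averaging
would misbehave near the antimeridian); convex-hull area on a Lambert
azimuthal equal-area projection centred on that mean point (area is exact
under an equal-area projection up to hull-edge curvature; for pools
spanning a few thousand km the error is well under 1%); and occupied-cell
count. Hulls of fewer than three non-collinear cells are reported as zero
area with a degenerate flag.

## Equal-spread subsampling

Per bin, the global MST is split by repeatedly deleting the longest edge of
any component whose summed length is at least the ceiling (default
13,000 km, continental scale), then dropping components shorter than the
minimum sampleable spread (default `target × (1 − tolerance)`). A
user-supplied barrier list (cell-id pairs) can force additional splits
where a tree branch crosses a biogeographic barrier; barriers matching no
edge warn and are ignored.

Replicate samples grow inside one regional subtree: start at a uniformly
random cell; repeatedly add the frontier cell joined to the current sample
by the shortest MST edge (ties lexicographic); stop once the induced
subtree length reaches the target; accept whichever of the final two states
(with/without the last cell) is closer to the target, provided it lies in
`target × (1 ± tolerance)`. Growth along tree adjacency guarantees the
sample is connected and its length monotone non-decreasing — this is the
package's resolution of a genuinely open design point (growth by raw
geographic proximity would also be defensible but cannot guarantee either
property). The reported spread is the induced-subtree length, not a
recomputed MST of the sampled cells, again to preserve monotonicity.
Defaults: 20 replicates, target 3,200 km, tolerance ±10%, 100 retries per
replicate before a subtree is declared unsampleable (the continental-data
target; toy worlds in tests and examples use 1,000–2,000 km targets scaled
to their geography). Each replicate draws from an independent stream spawned from
the master seed, so whole runs are reproducible bit for bit.

The ±10% acceptance band mechanically caps the spread variability of
accepted samples (CV ≲ 6%; in practice ~2–5%), versus ~40–80% across
unstandardized regional pools in heterogeneous worlds.

## Richness estimators

**Good's u** — coverage of the sampling pool, 1 − singletons/occurrences. A
singleton is by default a taxon found in exactly one *collection* (the
occurrence-count variant is available for sensitivity). u is the ceiling on
the achievable SQS quorum. (The common verbal gloss "proportion of
non-singleton taxa" divides singleton *taxa* by *occurrences*; the
implemented estimator is the standard one.)

**SQS** — per trial, whole collections are drawn in uniformly random order;
after each draw, coverage = u × Σ(full-pool frequency shares of the
distinct taxa drawn); drawing stops at the quorum (default 0.4) and the
trial's richness is the number of distinct taxa drawn. The estimate is the
mean over `n_trials` (default 100; the trial count is a precision knob, not
a model choice). Pools with u below the quorum return not-available.
Multiplying by u stops sampling earlier in well-covered pools and later in
poorly covered ones, targeting equal coverage of the *true* frequency
distribution. Optional exclusion of the dominant taxon is off by default.
SQS richness is a relative index at fixed coverage, not an absolute count.

**TRiPS** — per-taxon occurrence counts are modelled as Poisson(λ)
conditioned on ≥ 1 (zero-truncated). λ̂ solves λ/(1 − e^(−λ)) = mean count
by bracketed root finding (|residual| < 1e−10); detection probability
p̂ = 1 − e^(−λ̂); richness N̂ = n_obs/p̂. λ folds the bin duration into a
single per-bin intensity. The 95% interval combines a χ²(1)
profile-likelihood interval on λ with binomial uncertainty in n_obs: lower
bound n_obs/p_high, upper bound from profile-likelihood inversion of the
binomial in N at p_low. Simulated coverage at N = 200, λ = 1 is ≈ 93%
(the symmetric alternative of widening both ends with the binomial is
markedly over-conservative, ≈ 99.8%). All-singleton pools put λ̂ at the
zero boundary; such estimates are flagged degenerate and excluded. TRiPS
assumes equal sampling intensity across species; abundance heterogeneity
biases it toward the well-sampled species pool.

Across the 20 spatial replicates of a region × bin, estimates are
aggregated by the mean (SD across replicates reported); the median would
be equally defensible but the mean matches how replicate scatter is usually
summarized.

## Trend models

E[richness] = exp(a + b·t) with t the bin midpoint in Ma. Raw counts use a
negative-binomial likelihood with dispersion α estimated jointly by ML;
when α̂ hits the zero boundary (no overdispersion) the Hessian is singular,
so the fit falls back to the limiting Poisson GLM. SQS and TRiPS series are
non-integer with roughly symmetric error, so they use a Gaussian family
with a log link, fit by unweighted ML, one aggregated point per
region × bin. Reported: slope, Wald SE and two-sided P, residual
df = n − 2, ln increase = |b| × (oldest − youngest midpoint), percent
increase = 100(e^x − 1). Bonferroni correction: p → min(1, p·m) and
threshold α/m. Diversity-dependent (logistic) models are deliberately not
fitted: with ~10 points per series they are not identifiable against the
log-linear alternative.

## Synthetic worlds

The generator emulates the structural causes of the species–area artefact:
species with circular great-circle ranges (centres uniform over a
biogeographic domain, radii lognormal, default median 1,500 km) and fixed
relative abundances (lognormal by default, Fisher-log-series-shaped
alternative); localities clustered by a Thomas-style parent/offspring
process inside a per-bin sampling window; occurrences drawn
abundance-weighted from the species whose ranges cover the locality;
localities grouped into references; ages nested inside their bin. Per-bin
spread multipliers scale the window; locality and cluster-parent counts
scale with window *area*, so the sampling regime is spatially stationary —
a widely sampled bin has more localities at the same density, which is
exactly the coupling that makes raw richness track spread in real data.
True per-bin richness (a constant, exponential or step trajectory) is
recorded alongside, so recovery is checkable.

Default toy scale — 150 species, ~30–40 localities and a few hundred
occurrences per bin over eight 9-myr bins, standardization target 1,200 km
— keeps a full pipeline replicate under ~1.5 s so the 100-replicate
demonstration runs in minutes; these sizes are the package's chosen study
conditions for desk-scale validation, roughly 1/10 of the continental-data
scale.

What the synthetic worlds do *not* contain: plate motion (coordinates are
already "palaeocoordinates"), latitudinal richness gradients, preservation
differences between environments, taxonomic error, or correlated
reference/locality effort structure beyond simple grouping. Passing the
demonstration therefore shows the pipeline removes the *geometric*
species–area artefact under stationary sampling; it cannot show robustness
to every bias in real fossil data.

## Numerical and degenerate-input conventions

Empty pools yield not-available diagnostics rather than errors; quorum > u
yields not-available SQS; all-singleton pools yield degenerate TRiPS;
subtrees below the tolerance band are rejected with a reason; malformed CSV
rows are collected with row numbers, never silently dropped. All stochastic
components (SQS trials, sample growth, world generation) accept explicit
seeds, and the pipeline derives per-stage streams from one master seed.

## Known limitations

- Spherical geometry only (no ellipsoid); hull areas depend mildly on the
  projection centre choice.
- Equal-spread samples equalize MST length, not area; residual area
  differences at equal MST length can leave a small (few percent) richness
  drift across very differently clustered pools.
- SQS trial counts below ~100 leave visible Monte-Carlo noise in per-pool
  estimates; the acceptance checks use more.
- The growth rule explores only tree-adjacent configurations; it cannot
  produce spatially disjoint equal-spread samples.
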