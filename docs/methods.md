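# Methods

This note documents the statistical procedures implemented in `reeffd`,
the defaults and their rationale, the design decisions taken where the
methodology is genuinely open, and the limits of what the synthetic
validation can show.

## Trait coding and functional entities

Input traits are categorical and possibly multi-valued: a cell holds a
non-empty set of category labels (labels are matched after trimming and
case-folding, but reported with their declared spelling). A trait table
is expanded into a binary species × (trait, category) matrix, columns
ordered by trait declaration order then category declaration order.
Each column carries weight `w_k = 1 / (number of categories in its
trait)`, so every trait contributes total weight 1 to distances
regardless of how finely it is categorized; excluding a trait for a
sensitivity run simply removes its column block. Species with identical
binary rows form one *functional entity*; entity ids are assigned after
lexicographically sorting the signatures, which makes them invariant to
row order. Redundancy per entity is the number of member species,
genera and families (set cardinalities; ranked by species count, ties
broken alphabetically by entity id). Diel activity is accepted in trait
tables but excluded from multi-trait analyses by default, because
activity data are typically missing for most deep-reef species;
ordered or quantitative traits are out of scope.

## Trait space

**Gower.** For binary data with column weights the Gower dissimilarity
reduces to a weighted mean of mismatches,
`d(i,j) = Σ_k w_k |x_ik − x_jk| / Σ_k w_k ∈ [0,1]`. It is a metric on
binary vectors (property-tested).

**Cailliez correction.** Gower matrices are generally not Euclidean.
The smallest constant `c` such that `d_ij + c` (off-diagonal) is
Euclidean equals the largest real eigenvalue of the 2n × 2n block
matrix `[[0, 2Δ₁], [−I, −4Δ₂]]`, with Δ₁ and Δ₂ the double-centered
forms of `−D²/2` and `−D/2`. Before solving the eigenproblem the code
checks the spectrum of Δ₁ directly and returns `c = 0` when the input
is already Euclidean (minimum eigenvalue ≥ −1e-9 · max); this is more
robust than thresholding the block-matrix eigenvalue, whose numerical
noise is of order 1e-8.

**PCoA.** Classical scaling: eigendecompose `B = −½ J D² J`, keep axes
with eigenvalue `λ > 1e-8 · λ_max` (floating-point guard), scale
eigenvectors by `√λ`. Variance fractions are reported relative to the
positive spectrum of the corrected matrix, the common convention after
a Cailliez correction. Sign convention: each axis is flipped so its
largest-magnitude loading is positive, making coordinates reproducible
across linear-algebra backends. Fewer than three objects, or a fully
degenerate configuration, is an error. With all axes retained the
embedded Euclidean distances reproduce the corrected dissimilarities to
1e-8 (tested).

The pooled trait space (all species together) is the default reference
frame; per-site or per-subset spaces can be built by subsetting the
trait matrix first.

## Community metrics

Communities are site × 10-m depth bins. Counts are summed within a bin
and divided by the summed length of the distinct transects present
(pooling before division is unbiased under unequal transect lengths,
unlike averaging per-transect densities). Abundance weights for CWM,
FEve, FDis and Rao are square-root transformed by default
(`sqrt_transform=False` disables this): the transform damps dominant
species without inflating rare ones, and using one transform everywhere
keeps the abundance-weighted metrics mutually consistent.

- **CWM** of category k: `Σ_s √a_s x_sk / Σ_s √a_s ∈ [0,1]`; the
  categories of one trait sum to between 1 and the category count.
- **FRic**: convex-hull area of the community's species on two PCoA
  axes (axes (1,2) by default, configurable, e.g. (1,3) for a
  sensitivity run). Abundance-independent; fewer than three distinct
  non-collinear points give 0 with a warning.
- **FEve**: minimum spanning tree over the community's species in
  coordinate space (all positive axes by default); per edge
  `EW = d(i,j)/(w_i + w_j)`, `PEW = EW/ΣEW`, and
  `FEve = (Σ min(PEW, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1))`. Undefined
  below S = 3 (returns NaN with a warning); a fully coincident
  community is perfectly regular (FEve = 1).
- **FDis**: `Σ w_s ‖x_s − c‖` with `c` the weighted centroid.
- **Rao / Simpson / redundancy**: with relative weights `p`,
  `Q = Σ d_ij p_i p_j`, `D = 1 − Σ p_i²`, `R = D − Q =
  Σ_{i≠j}(1 − d_ij) p_i p_j ≥ 0` whenever `d ∈ [0,1]`. Redundancy is
  therefore computed on the *uncorrected* Gower matrix: the Cailliez
  constant would push distances above 1 and break the identity.
- **Rarefaction**: sample-based (sampling units are communities or
  transects); the expected species- or entity-richness at subset size m
  is a seeded Monte-Carlo mean over random subsets (200 draws by
  default), with the full size computed exactly.

## Depth zones and the 75% affinity rule

Zones are ordered, contiguous, half-open depth intervals with optional
site-specific limits; defaults are altiphotic < 40 m, upper mesophotic
40–90, lower mesophotic 90–130, upper rariphotic 130–200, lower
rariphotic 200–300, below rariphotic ≥ 300 — consistent with the
community breaks near 130, 200 and 300 m.

A species' zone profile is, per zone, its mean density over the bins of
that zone where it occurs (so wide zones do not dominate just by
containing more bins; raw sums available via `mode="sum"`), normalized
to shares. Its affinity is the *shortest contiguous run* of zones whose
summed share reaches 0.75; ties are resolved toward the higher total
share, then toward the shallower run. One zone → specialist label, two
zones → hyphenated label, three or more → "generalist" (flagged). The
shortest-run construction, and the tie-breaks, are this package's own
convention for cases the informal rule leaves open; they make the
classifier deterministic, permutation- and scale-invariant.

Per-zone and per-affinity summaries report convex-hull area (and its
fraction of the pooled-space hull), the √-abundance-weighted centroid,
and — for affinity groups — whether the group lies inside the hull of
the community observed at the corresponding zone(s).

## Trait-profile clustering

Each depth bin (sites pooled by default) is described by the
abundance-weighted frequency of each trait category among all
individuals, using raw (untransformed) densities: 32 columns for the
full six-trait schema. Bray–Curtis dissimilarity between profiles is
clustered with Ward's minimum-variance linkage applied to the
dissimilarities (the Lance–Williams recursion; verified against an
independent implementation), with scipy's deterministic
nearest-neighbor-chain agglomeration.

**SIMPROF.** Descending from the root, each node with ≥ 3 objects is
tested for internal structure. The observed statistic is
`π = Σ_r |s_(r) − s̄_(r)|`, comparing the ordered Bray–Curtis
*similarities* (1 − dissimilarity) among the node's objects with the
rank-wise mean profile of 1000 matrices in which every trait-category
column is independently permuted across the node's objects. 999
further permutations provide the null distribution of π, and
`p = (1 + #{π_null ≥ π_obs}) / (1 + 999)`. Significant nodes are split
and their children tested; homogeneous nodes become terminal clusters
(nodes of ≤ 2 objects are never split). A permutation test cannot
resolve p-values below `1/(1 + n_null)`; an `alpha` at or below that
resolution (e.g. the conventional 10⁻⁷ with 999 permutations) behaves
like the resolution limit — a node is then split only when no null π
reaches the observed one. The permutation core is vectorized in
float32 (the ~1e-7 relative rounding is far below permutation noise);
p-values and the partition are reproducible given the seed, and the
partition is invariant to row order.

`primary_split_depth` reduces the root split of a depth-bin dendrogram
to a cut depth: the boundary (among bin edges) that misclassifies the
fewest bins against the root bipartition, shallower boundary on ties.

**PERMANOVA.** One-way: total sum of squared dissimilarities
partitioned into between/within components,
`F = (SS_B/df_B)/(SS_W/df_W)`, `R² = SS_B/SS_total`, p by free
permutation of group labels. The F statistic matches scikit-bio's
implementation (cross-checked in tests). Multi-factor designs are
approximated by running factors separately (depth zone, site).

## Depth trends

Loess: tricube-weighted local polynomial regression (degree 2 by
default, span 0.75 = fraction of points in each local window; the span
must give windows of at least degree + 2 points). `R² = 1 − SSE/SST`
truncated at 0, with a permutation p-value from shuffling the response
(exact under exchangeability; verified by simulation). CWM responses,
bounded in [0,1], are clamped to [1e-4, 1 − 1e-4], smoothed on the
logit scale and back-transformed, so fits never leave (0,1). This
smoother is a deliberately lighter substitute for a beta-likelihood
GAM with REML smoothing selection: adequate for describing trends and
their explained variance, not for formal smooth-term inference. The
depth-by-site interaction is approximated by per-site curves reported
alongside the pooled fit.

## Synthetic surveys and ground truth

The generator emulates a four-island submersible/SCUBA campaign: one
site spans the full 0–450 m gradient, the others 40–300 m; two ~120-m
transects per site × 10-m bin; 250 species; six traits with 32
categories.

Species s has a Gaussian depth response
`a_s(d) = A_s exp(−(d−μ_s)²/2σ_s²)` with peak depth μ_s uniform over
the gradient, breadth σ_s log-normal (median 25 m, log-sd 0.4) and
peak density A_s log-normal (median 0.4 fish per metre of transect,
log-sd 0.9). *Community breaks* (default: 200 m) partition the species
pool: a species' response is truncated at its pool's boundaries (a
configurable soft-break scale relaxes this), and within-trait category
frequencies are drawn independently per pool (Dirichlet, concentration
0.2), so a break is a turnover in trait composition, not merely in
species identity. The skewed category frequencies also make binary
signatures collide at realistic rates — roughly two-thirds as many
entities as species, matching published reef-fish compilations. Each
species additionally receives extra categories per trait with
probability 0.1, emulating fuzzy coding.

*Environmental filtering*: selected categories carry depth windows
(herbivory/corallivory/detritivory ≲ 120–130 m, cleaning and
near-surface position ≲ 100 m, mid-water position and large schools
≲ 200 m, between-reef and vertical mobility ≲ 300 m). Windows
constrain trait assignment (a category is only assigned to species
whose peak lies inside it; an impossible combination is an error
listing the conflicts) and attenuate abundance outside the window as
`exp(−decay · strength · distance)` with decay 0.1 m⁻¹. The
`filter_strength` knob scales only the attenuation, leaving the trait
table untouched — so trait spaces are directly comparable across
strengths, and stronger filtering demonstrably shrinks deep-reef
functional richness.

Observation noise: log-normal site effects (log-sd 0.3), per-species
detection probability 0.9, Poisson counts of expected density ×
transect length; densities below 1e-12 are treated as undetectable.
The noiseless mode returns expected densities exactly and is the basis
of the exact affinity-recovery check. Ground truth records the break
depths, species parameters, expected per-bin category frequencies, and
the affinity label implied by each species' expected (noise-free)
response through the same zone scheme.

What the generator does *not* emulate: observer and gear biases
(submersible avoidance, midwater undercounting), spatial
autocorrelation along transects, temporal variation between survey
years, and within-genus trait correlation beyond the shared pool-level
category frequencies. Passing the simulation-based checks therefore
shows the estimators recover the properties of this generating model,
not that real surveys are free of such biases.

## Validation summary

The test suite checks, among others: every metric (Gower, Bray–Curtis,
FRic, FEve, FDis, Rao/Simpson/redundancy) against independent
brute-force implementations on 100+ random small communities at 1e-8;
closed-form limits (FEve = 1 for regular configurations, FDis = d/2
for a pair, redundancy = 0 at maximal distinctness, Cailliez constant
= 0 on Euclidean input); SIMPROF type-I error at nominal level under an
exchangeable null; recovery of the generated 200-m break by the root
SIMPROF split in ≥ 90% of replicate surveys; exact recovery of
ground-truth depth affinities on noiseless data; and the monotone
decrease of deep (≥ 300 m) functional richness with filtering
strength. `scripts/acceptance.py` recomputes these quantities from
scratch at the sizes stated in its output (a full 250-species survey;
100 null-calibration simulations; 10 break-recovery replicates).

## Known limitations

- Hulls (FRic, zone/affinity spaces) are 2-D only; higher-dimensional
  hull volumes are not implemented.
- PERMANOVA is one-way; no interaction terms or Type-III partitioning.
- The loess smoother provides no analytic confidence bands (the
  permutation p concerns the overall depth signal, not pointwise
  uncertainty).
- Gower handling of missing trait values is not supported: trait
  tables must be complete for the traits used (species with unknown
  traits should be excluded or imputed upstream).
- Functional divergence (FDiv) and over-redundancy indices are not
  implemented.
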