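# reeffd

Trait-based functional diversity of depth-structured reef-fish
communities, from the surface to the deep-sea boundary.

Visual surveys of reef slopes produce long tables of fish counts along
transects at known depths, and trait compilations assign each species
categorical traits (body size class, diet, water-column position,
gregariousness, mobility, reproductive mode) — often several categories
per trait when that best reflects a species' ecology. `reeffd` turns
these two inputs into the standard quantitative description of how
community *function* changes with depth:

- **Fuzzy binary trait coding** — every trait is spread into one 0/1
  column per category, each column weighted by the inverse of its
  trait's category count (`w_k = 1 / n_categories`); species sharing a
  binary signature form one *functional entity*, with species / genus /
  family redundancy counts per entity.
- **Trait space** — weighted Gower dissimilarity
  `d(i,j) = Σ_k w_k |x_ik − x_jk| / Σ_k w_k`, made Euclidean with the
  Cailliez additive correction, then embedded by principal-coordinates
  analysis (PCoA).
- **Functional diversity per community** (site × 10-m depth bin):
  functional richness FRic (convex-hull area on two PCoA axes),
  evenness FEve (regularity of abundance along the minimum spanning
  tree), dispersion FDis (abundance-weighted mean distance to the
  centroid), community-weighted means `CWM_k = Σ √a_s x_sk / Σ √a_s`,
  Rao's quadratic entropy `Q = Σ d_ij p_i p_j`, Simpson diversity
  `D = 1 − Σ p_i²`, and functional redundancy `R = D − Q`; plus
  sample-based species/entity rarefaction.
- **Depth structure** — 10-m binning with transect-length
  normalization, site-specific depth zones (altiphotic → below
  rariphotic), and the 75% depth-affinity rule: a species' affinity is
  the shortest contiguous run of zones capturing ≥ 75% of its
  abundance. Per-zone and per-affinity trait-space hulls and centroids
  quantify environmental filtering.
- **Functional breaks** — abundance-weighted trait-category frequency
  profiles per depth bin, Bray–Curtis dissimilarity, Ward clustering,
  and SIMPROF permutation tests that prune the dendrogram to
  statistically supported clusters; one-way PERMANOVA partitions trait
  variation among depth zones or sites.
- **Depth trends** — loess smoothers (tricube-weighted local
  polynomials) with permutation p-values; bounded CWM responses are
  smoothed on the logit scale.
- **Synthetic surveys** — a generator of multi-site, depth-structured
  communities with unimodal species depth responses, trait-dependent
  environmental filtering, configurable species-pool breaks and full
  ground truth, so every stage is testable without field data.

It is aimed at community ecologists working on reef (and other
depth-zoned) assemblages who want a reproducible, scriptable version of
this workflow in Python.

## Worked example

Everything below runs in a few seconds on synthetic data with a known
species-pool turnover at 200 m:

```python
from reeffd import (SyntheticConfig, generate, expand_traits, derive_entities,
                    trait_space, bin_depths, trait_frequency_profiles,
                    simprof, primary_split_depth)

config = SyntheticConfig(seed=1)          # 4 sites, 0-450 m, 250 species
table, observations, truth = generate(config)

matrix = expand_traits(table)             # 32 weighted binary categories
entities = derive_entities(matrix)
space = trait_space(matrix)               # Gower -> Cailliez -> PCoA

communities = bin_depths(observations)    # site x 10-m bin densities
profiles = trait_frequency_profiles(communities, matrix)
clusters = simprof(profiles, seed=1)      # Ward + SIMPROF pruning

print(f"{len(table.species)} species -> {len(entities)} functional entities")
print(f"PCoA axes 1-2 capture {space.variance_fractions[:2].sum():.1%} of trait variation")
print(f"{len(clusters.clusters)} significant trait clusters over {len(profiles)} depth bins")
print(f"primary functional break at {primary_split_depth(clusters):.0f} m "
      f"(generated turnover: {truth.break_depths[0]:.0f} m)")
```

prints

```
250 species -> 166 functional entities
PCoA axes 1-2 capture 25.8% of trait variation
24 significant trait clusters over 45 depth bins
primary functional break at 200 m (generated turnover: 200 m)
```

The 166 entities are the distinct trait combinations among 250 species
(the remainder are functionally redundant); the first two ordination
axes summarize a quarter of the trait variation; and the root of the
SIMPROF-pruned dendrogram separates the depth bins exactly at the
generated community break.

There is also a CLI mirroring the library
(`reeffd simulate | encode | space | metrics | affinity | cluster |
trend | report`), with `report` running the whole pipeline from a YAML
config and writing CSV/JSON/Newick outputs plus a run log.

## Documentation

`docs/methods.md` describes the statistical model behind every stage,
the defaults and their units, what the synthetic generator does and
does not emulate, and the numerical conventions (eigenvalue tolerances,
tie-breaks, degenerate-input behavior).
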