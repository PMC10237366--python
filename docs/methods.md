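# Methods

This note records the models, the numerical choices, and what the synthetic
study system does and does not emulate.

## Niche model

Each species x season is modelled as an ellipsoidal envelope in environment
space.  Given the deduplicated matrix of environment vectors at occurrence
cells, the fitted object is (μ, Σ, c): inclusion means squared Mahalanobis
distance m²(x) = (x−μ)ᵀΣ⁻¹(x−μ) ≤ c.  The envelope is the (approximate)
minimum-volume ellipsoid covering at least ⌈τ·n⌉ of the n training points;
τ defaults to 0.75, which discards environmental outliers such as vagrants
or misidentified records while keeping the bulk of the cloud.

**Exact enclosing ellipsoid.**  The minimum-volume *enclosing* ellipsoid of a
subset is computed by Khachiyan's algorithm in the Todd–Yıldırım form:
Frank–Wolfe ascent on the D-optimal design dual with away steps and
Sherman–Morrison rank-one inverse updates, stopping when every dual gradient
lies within (1 ± tol)(d+1), tol = 1e-6.  For n < 2d points the dual is
poorly determined and the moment ellipsoid (mean, covariance, max-Mahalanobis
radius) is used instead; the choice is recorded in the fitted `method_`
attribute.  In 2-D the input is first reduced to its convex hull.

**Subset search for τ < 1.**  Three phases, all deterministic:

1. *Iterative trimming* (all problem sizes): fit, drop the ⌊(1−τ)n⌋ points
   with the largest m², refit on the kept set, repeat to a fixed point
   (max 20 rounds).  Trimming rounds use a loosened tolerance (1e-4) because
   the drop decisions are insensitive to it; only the final fit is tight.
2. *Outer-layer enumeration* (n ≤ 30, d = 2 only): every point whose removal
   can shrink the enclosing ellipsoid lies on an outer convex "onion" layer,
   so all drop sets drawn from the first three layers (plus whatever
   trimming dropped) are enumerated exactly, memoizing ellipsoids by their
   hull vertex set.
3. *Exchange polish* (n ≤ 30): steepest-descent single-point exchanges
   between kept and dropped sets, with two-point exchanges tried when single
   ones stall.

Plain trimming alone is a good large-sample approximation but can land a few
percent above the global subset optimum on small samples; with phases 2–3
the fitted volume matched an exhaustive-subset oracle on every random 2-D
instance we tested.  Pipeline-scale fits (9 layers, hundreds to thousands of
points) use trimming alone, where exhaustive verification is impossible and
the estimator is conventional.

**Continuous surface.**  The continuous suitability is exp(−m²/2), rescaled
so its maximum over valid cells is 1.  Any strictly decreasing transform of
m² yields the same binary map and the same rank structure; the Gaussian
kernel form is a convention, chosen for its natural probabilistic reading.

## Geographic projection and modes

Binary maps threshold m² at c; continuous and binary maps are clipped by
cell centroid either to the full study domain (*neutral*) or to the union of
slope polygons containing at least one of the species' cleaned records
(*constrained* — a post-hoc accessible-area assignment; a species recorded
on both slopes is unconstrained in practice).  Constrained support is
therefore always a subset of neutral support.

## Hexagonal PAM

Flat-top hexagons of area 164.8 km² (centroid spacing √(2A/√3) ≈ 13.8 km)
are laid from the region bounding box's lower-left corner; cells are
assigned to the unique lattice hexagon covering their centroid.  The tiered
presence rule (≥ 70% of ≤ 10 cells, ≥ 50% of 11–40, ≥ 30% of > 40; all
comparisons inclusive, NODATA cells excluded from the denominator) converts
cell counts to hexagon presence: small samples must be near-unanimous while
large ones may be patchy.  Hexagons holding no raster cells are recorded as
absences.

## Clustering and cross-season stability

Species are clustered by k-means (Euclidean, 25 seeded restarts) on their
binary occupancy rows.  K is selected by the gap statistic with B = 50
uniform reference draws over the observed feature ranges and the
first-SE-max rule (smallest k with Gap(k) ≥ Gap(k+1) − SE(k+1), falling
back to k_max when the curve keeps rising, as it often does for binary data
against a uniform reference).  Defaults: k_max = 10 at the desk-scale
species counts used here.

June clusters are compared to December over the resident species only:
f(c) = best-match overlap fraction.  Bands are exact thirds — stable
f > 2/3, split 1/3 < f ≤ 2/3, diffuse f ≤ 1/3 — because the conventional
66%/33% figures are rounded thirds; clusters with fewer than 5 residents
are "unknown".  The comparison direction matters (a June cluster may be
stable into December while the reverse view splits), so both directions are
computed and every report carries its direction label.  The UPGMA
(average-linkage) dendrogram is exported in Newick form for visual
inspection only.

## Niche similarity and tests

Schoener's D = 1 − ½Σ|p − q| with each surface normalized over its own
valid cells and the sum over the union of supports; surfaces clipped to
disjoint accessible areas then score D = 0 rather than being undefined.
The null distribution pairs a random June species with a different random
December species (self-pairings excluded, 1000 seeded draws) so
within-species conservatism cannot leak into the null.  Group comparisons:
Welch t (observed vs null), Wilcoxon rank-sum per category pair (exact for
combined n ≤ 50, normal approximation with continuity correction above),
Spearman ρ of D against |June − December| record counts, and Fisher's exact
test of the migrant-related subset's category counts against the rounded
mean counts of 500 random same-size subsets (2xC table, zero columns
dropped; exact conditional enumeration with the probability-ordering
two-sided rule, verified against R's `fisher.test`).

## Grade-of-membership motifs

The site x species PAM is decomposed under the multinomial admixture
likelihood ℓ = Σₙ Σₛ xₙₛ log(Σₖ ωₙₖ θₖₛ) by plain EM with 10 seeded
Dirichlet(1) restarts per K, a log-likelihood tolerance of 0.1, a hard cap
of 500 iterations and a 1e-12 floor on mixture probabilities inside logs.
Empty sites are dropped before fitting.  Motif labels are arbitrary;
comparisons across fits first match motifs by Hungarian assignment on θ row
correlations.  K runs over 2–14 by default with no automatic selection
criterion — the series is meant to be inspected.

## Synthetic study system

The generator emulates a tropical country-scale system on a 100 x 100 km
grid at 1 km resolution: nine standardized environmental layers built from
shared smooth latent fields (Gaussian-smoothed white noise, kernel width 10
cells) plus layer-specific fields — pairwise correlated but bounded well
below |r| = 0.95 — and an "elevation" ridge splitting the domain into two
slope regions.  Species niches are ellipsoids in that environment space:
centres are environment vectors of actual cells near one of 3 archetype
cells (so niches are realizable and geographically structured), covariances
are scaled copies of the global environmental covariance with breadth drawn
from (0.7, 1.2) — giving range sizes from a few percent of the domain to
most of it, mirroring the mix of restricted and widespread species in real
avifaunas.  The true suitable set is the χ²(d, 0.95) Mahalanobis region;
December centres displace June centres by a configurable number of
environment-space SDs along a random direction; 20% of species are winter
(December-only) migrants; a random 30% of residents are flagged
"migrant-related" for the Fisher test (a null flag by construction); half
the species are confined to the slope holding their range centre.
Detection keeps each suitable cell with probability 0.6 by default.

What it does *not* emulate: observation-effort structure (checklists,
duration or distance biases), spatial clustering of observers, taxonomic
error, range dynamics within a season, or any real geographic coordinate
system.  Passing tests therefore demonstrate that the pipeline recovers
known structure under clean sampling assumptions, not that it is robust to
the full messiness of community-science data.

Default problem sizes (60 species, 100 x 100 grid, ~70-hexagon array) were
chosen as the smallest system in which every stage has meaningful sample
sizes — e.g. clusters large enough to escape the "unknown" band; tests use
smaller systems where the property under test allows it.

## Degenerate inputs and numerical conventions

- Constant or collinear environmental layers over a species' cells raise
  explicit errors naming the problem (the MVE is undefined there).
- Points on NODATA cells or outside the extent are dropped with logged
  counts; a species whose points all drop raises an error naming it.
- Thinning is a greedy scan in input-row order; removal is strictly-within
  (< 1 km), so two records exactly 1 km apart both survive.  Inputs must be
  in a projected km coordinate system.
- k-means restarts are seeded; ties across restarts resolve to the best
  inertia as computed, making runs bit-reproducible for a fixed seed.
- All stage randomness derives from the single pipeline seed.

## Known limitations

- The gap statistic against a uniform reference tends to favour large K on
  binary occupancy data; k_max acts as an explicit cap and the full curve is
  exported for inspection.
- The grade-of-membership optimizer is plain EM; it can need many restarts
  for well-separated motifs at large K (an accelerated optimizer is out of
  scope).
- Raster I/O uses plain single-band TIFF with a JSON transform sidecar in a
  local projected km system; georeferenced CRS handling is limited to
  reading user-supplied co-registered layers.
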