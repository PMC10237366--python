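# cooccur

Do co-occurring species form real communities, or do they merely share
ecological niches that happen to coincide in space and time?  `cooccur` is a
pipeline for probing that question with presence-only occurrence data: it
builds ellipsoidal ecological niche models for every species in two seasonal
snapshots (June and December), projects them to binary distribution maps,
aggregates those maps onto a hexagonal sampling array, clusters species by
their co-occurrence patterns, and asks how cohesive those clusters remain
across the year — with randomization nulls to separate genuine seasonal niche
conservatism from chance.

It is written for macroecologists and biodiversity informaticians who work
with presence-only data (e.g. community-science records) on co-registered
environmental raster layers.  A fully synthetic study system with known
ground truth is built in, so every stage can be exercised and validated at
desk scale.

## The method

1. **Cleaning** — occurrences are split by month (June vs December), spatially
   thinned so no two records of a species lie within 1 km, and species with
   fewer than 10 records are dropped.
2. **Niche models** — for each species x season, the environment vectors at
   its occurrence cells are enclosed in a minimum-volume ellipsoid (MVE)
   covering a fraction τ = 0.75 of the points (trimming environmental
   outliers).  With centre μ, shape Σ and radius c, a cell with environment
   x is suitable when the squared Mahalanobis distance
   m²(x) = (x−μ)ᵀΣ⁻¹(x−μ) ≤ c; the continuous suitability surface is
   exp(−m²/2), max-rescaled.
3. **Two biogeographic modes** — *neutral* models keep all suitable habitat
   in the study domain; *constrained* models are clipped to the slope
   polygon(s) (Pacific / Caribbean sides of the dividing ridge) that actually
   contain the species' records — its accessible area.
4. **PAM** — binary maps are aggregated to a hexagonal array (~164.8 km² per
   cell) with a tiered coverage rule: a hexagon is "present" when ≥ 70% of
   its raster cells are present (≤ 10 cells), ≥ 50% (11–40 cells) or ≥ 30%
   (> 40 cells).
5. **Clustering and stability** — species are k-means-clustered by their
   hexagon occupancy rows, with K chosen by the gap statistic; June clusters
   are matched to December clusters and classified *stable* (best-match
   overlap > 2/3 of resident members), *split* (1/3–2/3), *diffuse* (≤ 1/3)
   or *unknown* (< 5 residents).  A UPGMA dendrogram is exported for
   inspection.
6. **Niche similarity** — per-species seasonal similarity is Schoener's
   D = 1 − ½Σᵢ|pᵢ − qᵢ| between the normalized June and December surfaces,
   compared against a null of random cross-season species pairings (Welch t),
   across stability categories (Wilcoxon rank-sum), against seasonal
   record-count differences (Spearman), and between a migrant-related species
   subset and 500 random same-size subsets (Fisher's exact test).
7. **Geographic motifs** — the site x species PAM is decomposed by an
   EM-fitted grade-of-membership (admixture) model for K = 2…14 motifs; each
   hexagon is a mixture of motifs, each motif a probability vector over
   species.

The core estimators follow the scikit-learn API (`EllipsoidNicheModel`,
`GapKMeans`, `GradeOfMembership`: `fit` / `predict` / `transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; module-level functions wrap them for pipeline use.

## Worked example

Run the full pipeline on the default synthetic study system (100x100 km,
9 environmental layers, 60 species around 3 latent motifs, 20% winter
migrants, 60% detection):

```bash
cooccur run --out runs/demo --seed 1
```

or stage by stage (`cooccur simulate|clean|enm|pam|cluster|overlap|gom|report
--out runs/demo`).  With seed 1 the run reports (from `summary.json`):

- 60 December species, of which 43 are year-round residents present in both
  seasonal datasets;
- gap-statistic cluster counts K = 10 (June) / 9 (December) for neutral
  models and 10 / 10 for constrained ones;
- June-cluster stability tallies (neutral): 2 stable, 2 split, 0 diffuse,
  6 unknown (constrained: 3 / 1 / 0 / 6);
- mean observed Schoener's D = 0.898 (neutral) vs a randomized-null mean of
  0.642, Welch t = 13.4, p ≈ 3e-19 — residents' seasonal niches are far more
  similar than random cross-species pairings, the signature of niche
  conservatism rather than community cohesion;
- Spearman ρ = −0.05 between D and seasonal record-count imbalance (no
  effort artefact), and Fisher p = 1.0 (neutral) / 0.53 (constrained) for
  the migrant-related subset vs random subsets: its category mix is
  indistinguishable from random, as expected since the synthetic flag is
  assigned at random.

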