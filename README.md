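# progniche

Ecological niche evolution analysis for the martin genus *Progne* — ellipsoid
niche models, background similarity tests, environmental clustering of taxa,
and bin-based ancestral niche reconstruction on a phylogeny, with a synthetic
study-system generator so the entire pipeline is testable without any data
downloads.

## The problem

*Progne* martins span the Americas, from continent-wide migrants (*P. subis*,
*P. chalybea*) to local endemics (*P. murphyi*, *P. modesta*). When such a
lineage diversifies, do descendant species evolve *new* environmental niches
(niche divergence), keep the ancestral niche unchanged (conservatism), or
split the ancestral niche among themselves (partitioning)? Answering this
requires (i) niche models per taxon calibrated only on environments each
taxon could actually reach (its accessible area, **M**), (ii) a statistical
test of whether two taxa's niches overlap more or less than expected from
their available environments alone, and (iii) a reconstruction of niche
occupancy on the phylogeny.

## The method

- **Ellipsoid niche models.** Each taxon's niche is the minimum volume
  ellipsoid (MVE) covering 90% of its occurrence points in environmental
  space — a robust envelope that discounts stray records. Suitability of a
  cell with environment *x* declines with the Mahalanobis distance
  *d(x) = sqrt((x−μ)ᵀ Σ⁻¹ (x−μ))* from the ellipsoid centroid. A Gaussian is
  fitted by maximum likelihood to the fitting points' distances, its
  percentiles at 75/85/90/95/99% give nested presence thresholds, and
  *s(x) = 1 − F(d(x))* is the continuous suitability surface.
- **Overlap and the similarity test.** Overlap between two projected models
  is Schoener's *D* = 1 − ½ Σ|p−q| over normalized surfaces (0 = disjoint,
  1 = identical). The observed *D* for taxa *A*, *B* is compared to two null
  distributions, each from 100 models fitted to random points in the *other*
  taxon's M. Against each null the observation scores +1 above the 97.5th
  percentile, −1 below the 2.5th, else 0; the marks sum to a score in
  {−2…+2}, where only −2 is significant niche divergence and +2 is extreme
  conservatism.
- **Ecospecies and ecopopulations.** Linear discriminant analysis tabulates
  how reliably individuals can be re-assigned to their taxon from environment
  alone; the gap statistic on *k*-means selects the supported number of
  environmental clusters.
- **Ancestral reconstruction.** Each environmental variable's pooled range is
  cut into 10 equal bins; each taxon is coded present/absent/uncertain per
  bin given what its M makes accessible, and Fitch parsimony reconstructs
  ancestral occupancy per bin over the phylogeny (missing tips can be
  inserted as sister to a named tip, e.g. halfway along its branch).
  Per-branch summaries count bins gained (niche expansion) and lost
  (contraction).

## Worked example

Simulate a 9-taxon study system, clean the records, fit a niche model, and
test one pair:

```bash
progniche simulate --out sim --seed 5
progniche prep --occurrences sim/occurrences.csv --m sim/ms.geojson --out prepped
progniche enm --occurrences prepped/sp1.csv --stack sim/env --seed 1 --out sp1_model.json
progniche compare --occurrences sim/occurrences.csv --m sim/ms.geojson \
    --stack sim/env --pair sp1 sp2 --reps 20 --seed 2 --out cmp.json
```

which prints

```
wrote 9 taxa to sim
sp1: 210 -> 145 records
fit on 145 points; cutoffs {75: 2.087, 85: 2.344, 90: 2.518, 95: 2.776, 99: 3.260}
sp1 vs sp2: D = 0.542, score = +1
```

Reading the output: cleaning (duplicate removal, breeding-season filter,
M-clipping, 20-km thinning) kept 145 of 210 simulated records for `sp1`; the
fitted Gaussian distance model places the 95% presence threshold at
Mahalanobis distance 2.78; and the sp1–sp2 overlap (D = 0.542) exceeded the
97.5th percentile of one of the two background null distributions (score +1)
— no evidence of niche divergence, consistent with the conserve-mode
simulation that generated both taxa. The same operations are available as
library functions (`progniche.fit_niche_model`, `progniche.similarity_test`,
`progniche.reconstruct`, ...), which are the primary interface.

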