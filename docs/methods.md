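# Methods

This note documents the models, the synthetic study systems, the numerical
choices, and the known limitations of the `progniche` pipeline.

## Ellipsoid niche models

A taxon's realized niche is modeled as an ellipsoid in the space of
continuous environmental variables. The estimator is the minimum volume
ellipsoid (MVE): among all ellipsoids covering h = ⌈0.9 n⌉ of the n fitting
points, the one of smallest volume. The fit uses the classical elemental-set
search: candidate ellipsoids are generated from (p+1)-point subsets (p =
number of variables), each inflated just enough to cover h points, and
scored by log-volume ½·log det C + (p/2)·log r²₍h₎. When the number of
elemental sets C(n, p+1) is at most 10,000 the search is exhaustive
(tests exploit this as a brute-force oracle); otherwise 10,000 seeded random
subsets are drawn (`n_trials`, configurable). The reported ellipsoid is the
mean and covariance of the winning h-point subset, the covariance rescaled
by the usual truncation-consistency factor α / F_{χ²(p+2)}(χ²_α(p)) with
α = 0.9 so that, for Gaussian data, it estimates the full covariance.
Near-singular candidate covariances are jittered by 1e-8 × mean diagonal;
the final covariance spectrum is floored at a scale-relative jitter so the
ellipsoid stays invertible even for degenerate inputs (e.g. every record in
one raster cell).

Suitability is a function of Mahalanobis distance d from the centroid. A
distance distribution (Gaussian by default; half-normal, lognormal and gamma
available) is fitted by maximum likelihood to the fitting points' distances.
Level-L cutoffs are the fitted distribution's L-th percentiles, floored at 0
(a Gaussian fitted to small distances can place mass below zero), giving
nested presence masks at 75/85/90/95/99%. The default Gaussian family
follows the source pipeline's stated choice even though empirical distance
distributions are right-skewed; the `family` flag preserves the
alternatives. The continuous surface s = 1 − F(d) is the monotone surface
consistent with those cutoffs and is what the overlap statistic consumes by
default (`surface="binary@L"` compares a single thresholded mask instead).

## Overlap and the background similarity test

Schoener's D = 1 − ½ Σ|p − q| over two surfaces normalized to sum to 1 on a
shared analysis extent. The extent for a pairwise comparison defaults to the
union of the two taxa's rasterized Ms — both realized contexts, and D stays
symmetric; intersection and full-grid extents are flags.

The similarity (background) test: the observed D between the real models of
A and B is ranked against two null distributions, each from `reps = 100`
niche models fitted to random background points drawn cell-uniform from the
other taxon's M (the per-model point count defaults to the focal taxon's
occurrence count, equalizing sampling effort). Per null distribution the
observation is marked +1 / 0 / −1 (above the 97.5th empirical percentile /
inside / below the 2.5th; percentiles by linear interpolation, exact ties
count 0), and the two marks sum to the score in {−2…+2}. Only −2 is read as
significant divergence; +2 is extreme conservatism. Null-model MVE fits use
2,000 elemental resamples per fit rather than the single-fit default of
10,000: each pairwise test performs 200 such fits, and in the n ≈ 200, p = 3
regime the objective is already stable at 2,000 vectorized trials
(`mve_trials`, configurable). Every rep draws its seeds from the master seed
via seed sequences, so results are independent of evaluation order and
reproducible bit-for-bit.

## Occurrence cleaning

Records are deduplicated on exact coordinates (first seen kept), filtered to
the hemisphere's breeding window (April–July north, October–January south;
per-taxon month sets can override; undated records are dropped by default),
clipped to the taxon's M (boundary points count inside — hand-drawn Ms
follow physical barriers, so exclusion at the line would be arbitrary;
removed records go to an outliers side-channel, and clip ∪ outliers is the
input), and spatially thinned so retained localities are ≥ 20 km apart by
haversine distance on a 6371-km sphere. Thinning is greedy in canonical
order (sorted by lon, lat): a record is kept iff it is far enough from every
already-kept record. Greedy thinning is deterministic and idempotent but not
retention-maximizing; the 20-km rule itself does not fix an algorithm, and
determinism is worth more here than a few extra points. Every filter appends
(step, n_in, n_out) to a provenance ledger.

## Clustering

LDA confusion tables report, per true taxon, the percent of its points the
fitted linear discriminant classifier assigns to each taxon, with priors
proportional to group sizes; resubstitution by default, leave-one-out by
flag. The gap statistic uses Gap(k) = mean_b log W*_kb − log W_k with W_k
the within-cluster dispersion of seeded k-means (25 restarts), B = 50
uniform range-box reference sets (Tibshirani's simplest reference; a
PCA-rotated box is deliberately out of scope), s_k = sd_b·√(1+1/B), and the
first-SE-max rule: the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}.

## Binned niche characters and reconstruction

For each variable the pooled range (all taxa's background samples, extended
by occurrence values so every record is classifiable) is cut into 10
equal-width bins (configurable; 10 balances resolution against per-bin
support). A taxon's occupied interval is the span between its occurrence
quantiles at 2.5% and 97.5% (`trim_percent = 5`, the conventional guard
against single stray records in bin-based niche coding); a bin is *present*
if it intersects that interval, *absent* if not but the taxon's M offers the
bin's conditions, *uncertain* if the bin is inaccessible from its M. A
discrete any-record-in-bin rule is available via `interval=False`.

Ancestral occupancy per bin is reconstructed by unweighted two-state
parsimony (Sankoff dynamic program, equivalent to Fitch counts for unit
costs); uncertain tips cost zero for both states. A node is reported
present/absent only when *every* minimum-change labeling agrees at that
node, otherwise ambiguous/uncertain. Branch lengths are not used — an ML
reconstruction would need a rate model the character coding does not
support; the parsimony choice keeps the method assumption-light and
oracle-testable by exhaustive enumeration. Per-branch change summaries
count absent→present bins (expansion) and present→absent (contraction),
excluding and separately tallying bins with an uncertain endpoint.

Missing tips are inserted by splitting the sister's terminal branch at a
fraction of its length (default 0.5, "halfway") and attaching the new tip
with the complementary length, preserving ultrametricity; pruning the new
tip restores the original tree exactly.

## Synthetic study systems

The generator emulates the data regime of a desk-scale comparative study:

- **Environment**: each variable is a quadratic polynomial trend in lon/lat
  with seeded coefficients plus iid Gaussian noise (sd 0.25 on a trend of
  order-1 amplitude), on a 40° × 40° grid at 1° resolution, with 2% of cells
  masked as nodata. Defaults: 3 variables.
- **Niches on a tree**: a 9-tip ultrametric tree (depth 1) with per-branch
  modes — *conserve* (child = parent), *partition* (covariance shrunk by
  0.5², centroid offset so the child 95% ellipsoid stays inside the
  parent's), *shift* (centroid moved to 1.6 × the parent's 95% Mahalanobis
  radius, covariance kept). The root niche defaults to the grid-median
  environment with diagonal covariance (0.6 × layer SD)², a broad but proper
  subset of availability.
- **Occurrences**: 200 records per tip, sampled over M's cells with weight
  exp(−d²/2) in niche Mahalanobis distance (the Gaussian kernel matches the
  ellipsoidal niche concept and produces the right-skewed distance
  distributions the thresholding stage consumes), jittered within cells
  (clamped inside M), with 5% out-of-M vagrants and 10% out-of-season dates
  to exercise cleaning. Dates are uniform within the hemisphere's breeding
  window — only window membership matters downstream.
- **Pair scenarios** for calibrating the similarity test: *conserve* (both
  tips share the root niche and an identical full-grid M — the null regime)
  and *shift* (disjoint west/east Ms; the shifted tip's centroid is placed at
  the mean environment of its own M, 2.5 × the root's 95% radius away, so the
  two 95% ellipsoids cannot intersect — constructed non-overlap, the power
  regime).

What the generator does **not** emulate: GBIF sampling bias (effort
gradients, uncertainty fields), dispersal or landcover structure, spatial
autocorrelation of records beyond the suitability kernel, and realistic
inter-variable correlation in the rasters. Passing tests therefore show the
pipeline's statistical machinery behaves as designed under its own model,
not that real-data inferences are unbiased.

## Problem sizes and verification

The test suite and the acceptance script run everything on freshly simulated
data: 50 random instances for the MVE-vs-brute-force oracle (n ≤ 15, p = 2),
20 seeds of 500-point samples for niche recovery (max centroid error
≈ 0.18 pooled SD, bound 0.25), 10,000 draws for the Gaussian quantile check
(95% cutoff within 0.05 of 6.645), 20 seeded replicates each for the
similarity test's false-divergence rate under conservatism (0/20 at −2;
bound ≤ 10%) and its power under constructed shifts (≥ half at −2), and
10-seed conserve-clade reconstructions for the recovery property.

## Known limitations

- Bin-edge flicker: with ~200 records per taxon the occupied-span endpoints
  are sample quantiles with standard error around a fifth of a bin width, so
  independent resampling across taxa occasionally moves one endpoint bin even
  under perfect conservatism — single-bin expansion/contraction counts on
  terminal branches are sampling noise, not signal. The conserve-clade
  recovery property is therefore stated per branch (no branch shows
  systematic change across seeds) rather than as exact genome-wide zeros in
  each replicate; single-bin changes in real reconstructions deserve the same
  skepticism.
- The MVE search is stochastic above the exhaustive regime; different seeds
  can yield slightly different ellipsoids for the same data (volume
  differences are at the resampling-noise level).
- Blank cells in a pairwise score matrix are written only for untested
  pairs; a computed score of 0 is written as 0.
- The gap statistic's reference distribution and the LDA's resubstitution
  default are the simplest defensible forms; both are switchable, and
  cross-validated confusion tables will generally be less optimistic.
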