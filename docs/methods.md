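# Methods

## Survey preparation

Raw records are tuples (site_id, x, y, year, method, species, quantity)
with quantities in g m⁻² biomass or percent cover. The filter chain is:

1. **Replicate averaging.** Quantities of replicate samples of the same
   (site, year, method, species) are averaged. Because any positive
   mean binarizes to presence, the order of averaging and binarization
   is immaterial for the occurrence matrix; the averaged table is still
   exposed for users who need it.
2. **Binarization.** quantity > 0 ⇒ 1, else 0, irrespective of
   magnitude or method.
3. **Temporal de-duplication.** Only each site's most recent sampling
   year is retained, so the matrix reflects a geographic snapshot
   rather than a visitation-weighted record.
4. **Spatial de-duplication.** Sites are binned on an axis-aligned
   square grid (default 25 m) in projected meters; cell intervals are
   half-open `[x0 + i·cell, x0 + (i+1)·cell)`, with the grid origin
   defaulting to the floor of the minimum coordinates (configurable —
   there is no canonical anchor). Within a cell the latest-year site
   wins; same-year ties are broken by a seeded uniform draw so thinning
   is reproducible.
5. **Rarity filter.** Species present at fewer than 100 sites (strict
   `<`; exactly 100 is kept) are dropped. Sites are kept even if every
   remaining species is absent there, because absences are information
   for the distribution models.

The chain is idempotent, and no step ever alters quantities other than
the 0/1 mapping.

Predictor extraction is nearest-cell lookup under the same half-open
convention (a point on a shared edge belongs to the higher-index cell);
sites outside the raster extent or touching nodata in any layer are
dropped with a warning and counted.

## Distribution models

Each species is modelled independently from the environmental layers
with random forests in two flavours: a **regression forest** on the 0/1
response, whose averaged-tree output in [0, 1] is read as an occurrence
probability, and a **classification forest** predicting the class. The
defaults are 1000 trees, mtry = ⌊p/3⌋ (regression) or ⌊√p⌋
(classification), and permutation importance over 10 shuffles; forests
are fitted with scikit-learn, seeded. 1000 trees is far past the point
of stabilisation for these data sizes; tests and the demo configuration
use 30–150 trees, which is already stable at their sample sizes.

**Thresholding.** Probabilities convert to presence/absence by the
sensitivity–specificity difference minimizer: over candidate thresholds
(the unique score values, presence when score ≥ t — inclusive, stated
explicitly since the convention is often left implicit) pick the t
minimizing |sensitivity − specificity|, ties toward the smallest t. The
comparison is done in integer arithmetic (counts cross-multiplied by
the class sizes) so exact ties are not scrambled by floating-point
rounding. During cross-validation the threshold is learned on the
held-out fold's own score distribution, since the minimizer operates on
the evaluation set; the threshold used for maps is instead learned on
the full-data out-of-bag scores, so maps never threshold resubstitution
scores. Both choices are available.

**Evaluation.** Stratified tenfold cross-validation (sampling without
replacement, fold assignment seeded per species) gives 90/10
train/validation splits preserving prevalence within one record per
stratum. The regression kind reports AUC (tie-aware rank form, so
all-equal scores give exactly 0.5) and Cohen's κ after per-fold
thresholding; the classification kind reports κ. κ is computed from the
marginals as (p_o − p_e)/(1 − p_e); in the degenerate case p_e = 1
(both vectors constant) it is returned as 0 with a warning. Final
models for mapping are refit on all data.

**Prediction grids** are equispaced points (default 100 m) covering the
raster extent; points with incomplete predictors are flagged invalid —
no-prediction, distinct from predicted absence — and never counted in
areas.

## Overlap and co-occurrence

**Schoener's D** between species A and B uses site-normalized
occurrence proportions p_Xs = occ_Xs/n_X: D = 1 − ½ Σ|p_As − p_Bs|.
For binary vectors this reduces to a closed form in the shared-site
count k, which the implementation assembles in integer arithmetic so
the landmark values are exact: disjoint ⇒ 0, identical ⇒ 1, and the
nested 2:1 configuration ⇒ exactly 0.5. This variant is adopted
precisely because it reproduces that nested benchmark (D = 0.5 with
100%/50% directional overlaps); equal prevalences reduce D to
shared/total.

**Directional overlap** O(A→B) = 100·|A∩B|/n_A quantifies the asymmetry
D hides; O(A→A) = 100.

**Permutation null.** Each pair's D is tested against the null obtained
by uniformly shuffling one species' site labels with both prevalences
and the site set fixed. Under such a shuffle D depends on the permuted
vector only through k, and k is exactly Hypergeometric(n, n_B, n_A), so
the default path samples k directly from the hypergeometric
distribution — mathematically identical in distribution to explicit
shuffling (verified by a χ² equivalence test in the suite) and cheap
enough that the default 100,000 permutations per pair are trivial. An
explicit-shuffle path is retained (`exact_shuffle=True`). The p-value
is two-sided with add-one smoothing,
p = min(1, 2·min((1+#{D*≥D})/(N+1), (1+#{D*≤D})/(N+1))), which matches
a 2.5–97.5 percentile decision at α = 0.05 and never returns 0.
Shuffling A or B is equivalent in distribution; one-vector shuffling is
used. Benjamini–Hochberg step-up correction spans exactly the C(S,2)
raw p-values. Per-pair seeds are spawned from the plan seed so the
whole pair table is reproducible.

**Group comparison.** Pairwise D values are classed within-charophyte /
within-angiosperm / between and compared with Kruskal–Wallis H
(χ², df = 2). Pairs sharing a species are not independent; the test
treats them as exchangeable observations, as is conventional for this
summary, and the output carries that caveat. All-identical D values are
reported as H = 0, p = 1 (the mid-rank-tie limit, where scipy instead
raises).

**Richness profiles** are binned means (equal-width bins over the
gradient) of per-group row sums with normal-approximation 95% CIs,
after excluding sites deeper than 10 m when the depth filter is on;
the CIs are descriptive. Smoothed (GAM-style) curves are deliberately
out of scope.

## Area summaries

Binary maps share one grid and one valid-data mask (NaN = no data,
never counted as absence). Distribution area is presence-cell count ×
cell²/10⁶ km². The alone/co-occurring split partitions each species'
presence cells by whether any other studied species co-occurs in the
cell; the total is computed as the sum of the two parts so the
partition identity is exact in floating point. The co-habitation
breakdown classifies each occupied cell as both-groups /
angiosperm-only / charophyte-only; the default denominator is the
occupied area (the three fractions then partition to 1), with the
full-valid-area denominator behind a flag, and the choice is recorded
in the output.

## Synthetic seascapes

The generator emulates the structure of a large coastal macrophyte
database without reproducing any real coastline:

- **Environment.** 14 named layers from the familiar predictor families
  (depth, soft-sediment share, slope, salinity, wave exposure,
  temperatures, ice, Secchi, chlorophyll, currents, nutrients, oxygen),
  each a Gaussian-kernel-smoothed white-noise field (kernel scale =
  autocorrelation range, default 500 m) min-max rescaled into a
  realistic value range. Kernel smoothing is an O(n) stand-in for exact
  Gaussian-process sampling; its correlation length tracks the kernel
  scale, which is what the downstream tests rely on. Depth additionally
  carries a monotone cross-grid ramp (70% trend weight) so a genuine
  on/offshore gradient exists and "depth dominates" recovery tests are
  meaningful.
- **Species.** Gaussian niche responses per layer with a logistic link:
  p = detection · logistic(baseline − Σ w((e−opt)/width)²), maximal at
  the joint optimum and non-increasing in each standardized squared
  distance. The default community holds 6 angiosperms and 5
  charophytes, all depth-dominated (weight 3 on depth), with
  charophytes confined to the shallow 5–30% of the depth range and
  given narrower tolerances — so they are rarer and shallower, and a
  depth-binned richness profile declines for them. A single
  detection_prob per species stands in for method differences among
  grab, diver and video sampling, which are not modelled.
- **Survey.** Default 10,000 sites drawn around 60 cluster centres
  (σ = 300 m) inside the extent, sampled in years 2005–2022 with
  revisit probability 0.15 (the revisit lands in a different year);
  presence is an independent Bernoulli per visit and species; present
  species get a positive lognormal biomass (or uniform cover), absent
  species exactly 0, making binarization exactly invertible. The true
  per-site probabilities are returned with the table as the oracle for
  recovery tests.

What passing tests on these seascapes do **not** show: performance
under real spatial sampling bias, method-dependent detectability,
interactions between species (occurrences are conditionally independent
given the environment), or temporal change — the generator holds niches
fixed over years.

## Problem sizes and numerical choices

Tests and the shipped demo run scaled-down versions of the analysis:
grids of 50–150 cells per side at 50 m, surveys of 400–3000 sites
(recovery tests use 2000), forests of 30–150 trees, permutation tests
of 500–5000 draws (calibration: 200 replicate 500-site datasets at
2000 permutations). These sizes were chosen as the smallest at which
each property is stable; the package defaults remain the full-scale
settings (1000 trees, 100,000 permutations, 10 folds, 25 m thinning,
100-site rarity threshold, 100 m prediction step).

Other numerical conventions: seeded tie-breaks everywhere randomness
enters (spatial thinning, fold assignment, permutation draws), one
master seed fanned out per stage via a CRC32-keyed SeedSequence;
rasters stored as plain-text ESRI ASCII grids with `repr`-precision
floats so round-trips are bit-exact; empty species are excluded from
pairwise overlap with a warning rather than poisoning the pair table.

## Known limitations

- No spatial blocking in cross-validation: with autocorrelated
  environments, random folds can be optimistic relative to spatially
  independent evaluation.
- The permutation null fixes prevalences of the tested pair only; joint
  structure across all species (fixed site richness) is not preserved.
- Only random forests are implemented; no abundance modelling.
- Planar metric coordinates are assumed throughout; no reprojection.
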