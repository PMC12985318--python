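# Methods

This note documents the models and procedures implemented in `occtool`,
the parameters that matter, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Problem setting

The package reconstructs, as a reusable pipeline, a national-scale
spatial conservation analysis for georeferenced wildlife occurrence
records (the motivating case is non-human primates in a humid tropical
country): where are records concentrated, how has the dominant habitat
class changed over three decades, and does the protected-area (PA)
network capture more records than chance would predict?

All coordinates are WGS 84 decimal degrees. Grids are north-up with
row 0 at the top; cells are half-open (a point on a cell's west or north
edge belongs to it; the grid's east and south outer edges are outside).
Points on polygon boundaries count as inside (covers predicate) — a
measure-zero convention that only matters for constructed test cases.

## Geodesy

Areas and distances use a sphere of authalic radius R = 6,371.0072 km.
The area of a cell in latitude row r is

    A(r) = R^2 · Δλ · (sin φ_top − sin φ_bottom),

exact on the sphere, constant along rows, symmetric about the equator.
The spherical model keeps every quantity closed-form and testable while
staying within ~0.3% of ellipsoidal values; all class areas and
transition fluxes are sums of these per-cell areas, never cell counts
times a nominal resolution. Distances are great-circle (haversine).

## Occurrence quality control

Three steps, each logged with before/after counts in an append-only
provenance trail:

1. **Deduplication** — among records of one species, coordinates equal
   after rounding to 6 decimals (~0.1 m, effectively exact matching)
   keep only the first in input order. Co-located records of different
   species are all retained.
2. **Plausibility** — drop missing/non-numeric coordinates, coordinates
   outside [−180, 180] × [−90, 90], and records outside the national
   boundary polygon.
3. **Spatial thinning** — greedy sequential retention in input order: a
   record is kept iff it is ≥ `min_km` (default 1 km) from every
   already-kept record of its thinning group. Thinning is per-species by
   default (co-located records of different taxa are biologically
   independent observations); a global mode and a seeded random-order
   mode (for quantifying order sensitivity) are available. The greedy
   rule is deterministic given the order, idempotent, and guarantees the
   pairwise distance floor among retained records of a group.

## Land-cover change accounting

Two co-registered categorical rasters (FAO-LCCS-style integer codes;
nearest-neighbour resampling onto the reference grid when geometries
differ) are compared cell-by-cell over the joint validity mask. The
transition matrix T[a][b] accumulates geodesic cell areas over (date-1
class, date-2 class) pairs; its marginals reproduce the per-date class
area tables exactly (asserted at runtime to 1e-9 relative error).

For a focal class c (evergreen broadleaved forest, code 50, in the
motivating analysis): persistence = T[c][c]; gross losses = off-diagonal
row entries by destination; gross gains = off-diagonal column entries by
source; net = gains − losses. Percentages of losses/gains are shares of
the gross totals; persistence is a share of the date-1 extent.

`ClassChangeDecomposition.from_reported` rebuilds a decomposition from a
*published* flux table. Published tables sometimes state totals that
disagree with the sum of their itemised fluxes; the stated totals are
then honoured as the percentage denominators (reproducing the published
percentages exactly) and the residual is preserved in a
`flux_imbalance` field rather than silently redistributed — surfacing,
not resolving, source inconsistencies.

**Driver test.** Cells losing the focal class are assigned to outcome
categories (default: agriculture = {10, 11, 30}, urban = {190}, other =
remainder) and the observed pixel counts are compared by a chi-square
goodness-of-fit test with expected counts proportional to each
category's availability in the date-2 landscape. Availability is
ambiguous in principle, so both readings are implemented and recorded in
the result: `nonfocal_2022` (default — shares among date-2 cells not
coded focal, since a loss pixel cannot end up focal) and `all_2022`
(shares among all valid date-2 cells, persisting focal cells counting as
"other"). Standardized residuals (obs − exp)/√exp sign the over/under-
representation. A zero expected count is rejected with guidance to merge
categories.

## Hotspot analysis

**KDE.** Isotropic Gaussian kernel in degree space, fixed bandwidth
(default 0.2°, ~22 km at the equator), evaluated at the centres of a
fine grid (default 500×500 over the boundary's bounding box) and masked
to the boundary afterwards; no edge correction, so mass near the
boundary is attributed outside it — adequate for ranking and percentile
summaries, not for absolute density at the coast. Percentile thresholds
use linear interpolation and a strict ">" rule, so a constant surface
has zero hotspot area. Contiguous hotspot patches use 8-connectivity.

**Gi\*.** Occurrence counts on a coarser analysis grid (default 0.05°,
~5.5 km; queen-neighbour centroid distance ≤ 0.05·√2 ≈ 0.0707°). The
self-inclusive Getis–Ord statistic with binary queen weights:

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S · √[(n W_i − W_i²)/(n − 1)]),

with x̄ and S the mean and population standard deviation of counts over
the analysis-cell universe (all cells inside the national mask, not only
occupied ones — a recorded config choice), W_i the focal cell plus its
in-grid, in-mask queen neighbours (edge cells have fewer; no
wrap-around). A constant count field, or a neighbourhood spanning the
whole universe, yields z = 0 with a warning. Raw p-values are two-sided
normal; Benjamini–Hochberg adjustment (via statsmodels) runs over all
analysis cells. Classification requires *both* thresholds: hot99 for
z ≥ 2.58 and q ≤ 0.01, hot95 for z ≥ 1.96 and q ≤ 0.05, mirrored with
negative z for coldspots — using the adjusted q in the conjunction is
the stricter, FDR-respecting reading.

Known limitation: the normal approximation for z is conservative at
sparse counts. In a CSR calibration experiment the pre-FDR |z| ≥ 1.96
rate reaches its nominal ~5% only at high mean counts per cell; the
package's calibration test therefore runs in that dense regime (mean 50
counts/cell), where the approximation is valid. At occupancy levels
typical of occurrence data the test is slightly conservative, which
errs on the safe side for hotspot claims.

## Protected-area enrichment

Observed statistic: the proportion of records inside the union of PA
polygons (overlaps counted once). Null: complete spatial randomness —
per iteration (default 10,000), n cells are sampled uniformly with
replacement from the valid (non-nodata) cells of the land-cover mask and
each simulated point is placed uniformly at random *within* its cell
(avoiding lattice artifacts at polygon edges). The p-value is the plain
proportion of simulations with inside-proportion ≥ observed, reported as
"< 1/N" when no simulation reaches it; the (1+x)/(1+N) permutation
correction is available but not the default. The enrichment ratio is
observed proportion / null mean. Cells are sampled unweighted by default
(at low-latitude national extents the area bias is < 0.1%); an
area-weighted mode exists for high-latitude generality. The CSR null is
deliberately conservative: it ignores habitat and accessibility
heterogeneity, so inhomogeneous nulls would sharpen — not overturn — a
strong enrichment signal.

## Synthetic scenarios

The generator produces the full input suite with known ground truth:

* **Landscape** — date-1 classes from Gaussian-smoothed noise (σ = 3
  cells) thresholded at the mixture quantiles, giving spatially coherent
  patches with exact areal shares; date-2 by independent per-cell draws
  from the planted conversion rows. Defaults: 200×200 cells of 0.01°
  near the equator; mixture 86% forest (50), 4% croplands (10/11/30),
  9% mosaic vegetation (40), 1% urban (190); forest row 98%
  persistence with losses dominated by cropland — the order of magnitude
  of the motivating national study.
* **Protected areas** — random rectangles inside the boundary, jointly
  rescaled until the clipped union is within 2% of the target coverage
  (default f = 0.185), categories alternating official/OECM.
* **Occurrences** — Thomas-style parent–offspring clustering (default 5
  parents per species, 8 km dispersal; 0 parents gives the CSR limiting
  case used for calibration tests), with proposals accepted in
  proportion to a per-class weight (default forest 1.0, others 0.85,
  which reproduces the mild forest enrichment of the real records
  relative to forest availability) times a planted inside-PA multiplier
  ρ (default 2.96, chosen so the implied inside share ρf/(ρf+1−f) ≈ 40%
  at f = 0.185). Six taxa with quotas totalling 481 records mirror the
  observation-frequency profile of the motivating dataset.

What the synthetic tests show: correctness of the accounting (exact
conservation), statistical calibration of the CSR test, recovery of
planted conversion rates and enrichment within Monte Carlo error, and
detection of planted clusters. What they do not show: robustness to the
sampling biases of real occurrence data (accessibility, effort
clustering near roads and research sites), to misclassification in real
land-cover products, or to real PA geometries; the generator's
landscape has no rivers, elevation, or realistic patch-size
distribution.

With the planted clustering, the realized inside-PA share of a single
scenario draw scatters widely around its expectation (clusters land
inside or outside PAs wholesale), so single-run enrichment ratios vary
between seeds; parameter-recovery tests therefore use the cluster-free
mode where the binomial standard error applies.

## Problem sizes and tolerances

Default test and acceptance runs use 200×200 landscapes, ~480 points,
1,000-iteration nulls, and 200-replicate calibration experiments —
sizes at which every stochastic check has adequate power while the
whole suite runs in well under a minute of compute per experiment.
Stochastic assertions use 3-standard-error bands from the relevant
binomial or replicate variance; exact accounting identities are asserted
to 1e-9 relative error; percentage comparisons against published
2-decimal values use 0.01 absolute tolerance.
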