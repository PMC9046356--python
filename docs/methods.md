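# Methods

## Scope and data model

The pipeline treats one specimen as a calibrated 2-D section of a cortical
strip about 2000 µm wide, with laminar boundaries (pial surface, L1/L2, …,
L6/white matter) supplied as annotations — polylines or flat depths in µm.
Cells enter either from image segmentation or as pre-measured tables; all
downstream statistics operate on per-specimen, per-layer median descriptors.
Layers are always analyzed as separate test families.

## Synthetic generator

The generator emulates the *statistical* structure the inference assumes,
not histological appearance.

* **Point pattern.** Within each laminar band, cells are a hard-core
  thinning of a Poisson process (dart throwing, at most 50 candidate draws
  per target cell): sections are thin enough that somata do not overlap, so
  inter-centroid distance is kept ≥ the sum of the two semi-minor axes —
  enforced across bands within a specimen, not only within one band.
  Overfull layers raise an explicit error naming the layer rather than
  silently densifying.
* **Cells.** Each cell is an ellipse: area lognormal (per-layer median and
  log-sd), minor/major ratio normal clipped to (0, 1], orientation uniform
  or von Mises around the radial axis. The default six-layer table follows
  the canonical laminar pattern of a sensory cortex — dense small granule
  cells in L2/L4 (800 /mm², ~50–55 µm² median), sparse large somata in L5
  (400 /mm², ~150 µm²), total thickness 1.5 mm. These magnitudes are
  generator conventions chosen to be realistic for Nissl material; no
  published per-layer numbers are encoded.
* **Effects.** Group effects multiply density and size per layer and may
  inflate dispersion (scale effect); specimen effects are lognormal
  multipliers (sd 0.05 by default) shared across a specimen's layers. With
  identity group effects specimens are exchangeable across groups, which is
  exactly the null hypothesis of the inference — the basis of the null
  calibration tests.
* **Rendering.** Dark ellipses (90) on a brighter background (200), additive
  linear illumination along depth, additive Gaussian noise (sd 6 by
  default). Contrast is depth-invariant while the absolute intensities are
  not, which is what defeats any single global threshold. A calibration too
  coarse to resolve the median cell (< 3 px diameter) is an error.
* **What it does not emulate:** staining texture, glia/neuron distinction,
  curvature of the laminar bands, section artefacts (folds, tears),
  anisotropic shrinkage. Passing tests demonstrate correctness of the
  measurement and inference chain under the stated model, not robustness to
  every property of real slides.

## Segmentation

Cells are darker than background (thionine polarity; invert upstream if
needed — this is documented, not auto-detected).

1. **Space-varying threshold:** per-pixel threshold = local window mean −
   offset (window radius 30 µm, offset 25 intensity units by default).
   Windows are clipped at borders, never padded; a window covering the
   whole image degenerates to the global mean with a warning. The
   mean-minus-offset form is the simplest monotone local rule and is
   validated on the illumination-gradient fixture where a global threshold
   fails.
2. **Labeling:** strict `image < threshold`, 8-connected components (thin
   diagonal boundaries survive 8-connectivity).
3. **Centre detection:** Gaussian smoothing of the foreground indicator
   (σ = bandwidth/2) with non-maximum suppression at minimum separation =
   bandwidth (default 4 µm ≈ median expected cell radius); centres off
   foreground are discarded.
4. **Cluster splitting:** objects holding ≥ 2 centres are partitioned by
   multi-source BFS — each pixel joins its geodesically nearest centre
   (8-connected chessboard metric inside the object); ties go to the centre
   first in (row, col) order, making the operation deterministic. Foreground
   pixels are conserved exactly. Objects with no centre are kept and
   flagged.
5. **Filtering:** area within [12, 2000] µm², eccentricity ≤ 0.97, solidity
   ≥ 0.5 by default. Border-touching objects are kept for density counting
   but flagged; their size/shape descriptors are censored from the layer
   summaries because their footprints are clipped.

## Morphometry

* area = pixel count × pixel_size²; perimeter by the Crofton formula over
  4 directions. The simpler boundary-step estimator (√2 weight on
  diagonals) overestimates disc perimeters by ~3%, pushing circularity
  ~5% low at r = 20 px; Crofton keeps the bias ≈ 1% across r = 10–40 px and
  was adopted for that reason.
* circularity = 4π·area/perimeter²; solidity = area / pixelised convex-hull
  area; extent = area / bounding-box area; inverse aspect ratio =
  minor/major axis of the second-moment ellipse (the definition adopted for
  "InvAR", recorded as an assumption); eccentricity from the same ellipse.
  Footprints under 3 px are rejected.
* **Surface density** = number of *other* centroids within 50 µm
  (cKDTree; integer, exact). Self-exclusion makes the isolated-cell value
  0, the natural zero; a constant offset would not affect group contrasts.
  No edge correction, matching the raw 2-D count convention: censoring near
  strip borders is a documented bias applied consistently across groups.
* **Layer assignment** is half-open in depth: a centroid exactly on a
  boundary goes to the deeper layer; outside all bands → "unassigned",
  excluded downstream.
* **Cortical thickness** is measured along the local normal of the pial
  polyline to the deepest boundary, at ≥ 5 sites, reported in mm. For a
  tilted deep boundary this yields the separation along the pial normal
  (not the perpendicular distance to the deep line) — the convention of a
  perpendicular dropped from the pial surface. Sites whose normal misses
  the deep boundary are skipped with a warning; fewer than 5 valid sites is
  an error.
* **Summaries:** per layer, median and (25th, 75th) percentiles per
  descriptor. Empty layers are missing, not zero.

## Inference

* **Statistic.** Location partial: Σ_j n_j (mean_j − grand mean)²; scale
  partial: the same quadratic form on within-group mean absolute
  deviations. The variable-level statistic Fisher-combines the two on the
  shared permutations, since both τ_j and σ²_j may differ under the
  alternative. The exact partial statistic inside the original framework is
  not fixed by any published formula; location+scale is recorded as an
  assumption with `statistic="location"` as the switch for a pure location
  test.
* **NPC tower.** Attained partial p-values per permutation are rank-based
  with ties counted (values in [1/M, 1]); Fisher combination gives a
  per-permutation statistic reusable at the next level: variables → domain,
  domains → global. Synchronization (same permutations everywhere within a
  layer) is enforced structurally — one scheme per layer — and combining
  vectors of different lengths raises.
* **p-values.** Add-one `(1 + #{T* ≥ T})/(B+1)`; exhaustive enumeration of
  all distinct relabelings whenever their count ≤ B (then exact, with floor
  1/M). Default B = 4999; the CLI default of 999 keeps the demo fast.
  Note that for two equal-sized groups each relabeling and its mirror give
  identical statistics, so the attainable floor is 2/M.
* **Pairwise tests** restrict permutations to the two groups' rows and are
  identical to running the two-sample test alone. **Shaffer correction**:
  multipliers t_i = max achievable number of simultaneously true pairwise
  equality nulls after i−1 rejections, derived by enumerating the block
  partitions of the k groups (k = 3 → (3,1,1); k = 4 → (6,3,3,3,2,1));
  step-down with monotone enforcement, capped at 1. No additional
  correction is applied across layers or variables beyond the per-family
  Shaffer — this mirrors per-layer reporting conventions in comparative
  cytoarchitecture and is a documented choice, not a claim of optimality.
* **Eye position.** Orbital-plane angle → frontal-eyed (≤ 60°), wide-field
  (60°–150°], lateral-eyed (> 150°). The source ranges (~20°, 100–150°,
  150–180°) leave gaps; the cuts interpolate them at 60° and 150° and are
  configurable.
* **Determinism.** All randomness descends from one seed through spawned
  generators keyed by sorted layer order and pair order; rows are
  canonicalized by specimen id, so input row order cannot change any
  p-value.

## Problem sizes used in validation

Null calibration uses 2000 replicates of n = 10/10 at B = 999; null
uniformity of the global p uses 300 small two-layer studies; the planted
density-deficit recovery uses 100 studies of 3 groups × 5 specimens on the
default six-layer table via the truth-table bypass (the bypass computes
descriptors in closed form from the generating ellipses — what a perfect
segmentation would measure); segmentation scoring uses two rendered
2000 × 1500 µm strips at 1 µm/px with illumination gradient 20 /mm. These
sizes were chosen to give stable rates at desk scale.

## Known limitations

* 2-D section counts only; no stereological volume correction (volume
  density from thin sections overestimates neuron counts and is
  deliberately out of scope).
* Segmentation defaults are tuned for the synthetic contrast regime
  (Δ ≈ 110 intensity units, noise sd 6); real slides need per-batch
  parameter review, especially the threshold offset.
* The hard-core constraint uses semi-minor axes, so highly elongated
  aligned ellipses can still graze; at the default axis ratios (~0.75)
  this is negligible.
* Phylogenetically corrected inference (e.g. PGLS) is explicitly a
  non-goal; groups are treated as exchangeable units under the null.
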