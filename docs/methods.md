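# Methods

This note documents the models, parameters, and design decisions behind
`isletpath`, and what the synthetic-data experiments do and do not show.

## Coordinate and unit conventions

Pixel indices are 0-based; the physical position of pixel `(row, col)` is
`((col + 0.5)·mpp, (row + 0.5)·mpp)` µm (pixel-center convention), so areas
and distances are unambiguous. Everything downstream of I/O is expressed in
µm and mm²; `mpp` (microns per pixel) is mandatory — a TIFF without
resolution metadata is rejected unless an override is given. CSV output is
UTF-8, comma-separated, `.` decimal, no thousands separators; units are
encoded in column names (e.g. `CD45+/mm^2`).

## Tissue detection

The tissue mask is `gaussian(mean over all channels, σ = 4 µm) > threshold`,
followed by removal of components smaller than `min_artifact_area`
(default 10⁴ µm², the headless replacement for manual artifact checking) and
hole filling. The mean is unweighted and includes the nuclear channel. The
intensity threshold is inherently acquisition-specific; the default (5, in
renderer units) is calibrated to the synthetic background (10) and must be
re-tuned for real scanners. Compartment areas satisfy
`tissue = exocrine + endocrine` exactly in pixel counts; the three reported
mm² values share a single float conversion factor, so the identity holds to
1 ulp in float.

## Cell detection

Nuclear segmentation: median filter (radius 1 µm) → Gaussian (σ = 1 µm) →
intensity threshold (default 30) → distance-transform watershed. Watershed
seeds are local maxima of the distance transform with 2 µm minimum
separation, ordered by (row, col) for determinism. Nuclei outside
[8, 150] µm² are rejected; surviving nuclei are expanded by 5 µm with mutual
clipping (`expand_labels`, the overlap-free territory convention), clipped to
the tissue mask. Intensities are measured on the **raw** channels — filtering
affects segmentation only. Cytoplasm = cell − nucleus; a zero-pixel cytoplasm
(expansion 0) falls back to the nucleus mean and is flagged.

*Caveat*: raising the nucleus threshold shrinks the segmented foreground
monotonically, but the final **count** can jitter by ~1% non-monotonically,
because eroding the foreground can split a merged blob into two countable
nuclei or bring an oversized component into the accepted area window. The
test suite asserts exact monotonicity of the foreground and count
monotonicity with a 2% allowance.

Smoothed features: for each intensity feature, a Gaussian-weighted mean over
neighbors within 25 µm, `w = exp(−d²/(2σ²))` with σ = radius/2, self
included. This is shift-invariant and matches an O(n²) brute-force oracle to
1e−9 in the tests.

## Islet segmentation

Per-pixel features are the raw intensity plus Gaussian-smoothed intensity at
scales {1, 2, 4, 8} µm for each endocrine-relevant channel (hormone markers +
Hoechst by default) — scales spanning nucleus-to-islet structure. The
classifier is a 100-tree random forest (depth ≤ 12, seeded, single-thread),
the same family interactive tools default to; training pixels come from a
small labeled ROI (in synthetic runs, the bounding box of the largest islet
plus 60 µm, standing in for the analyst's annotation), subsampled to ≤ 20k
per class. Predicted islet pixels are grouped into 8-connected components,
holes are filled **before** the cell-count filter (matching the workflow
order), components are polygonized from their 0.5-level contour, detected
cells attach by centroid, and only components with ≥ 10 cells become islets.
This filter is what keeps scattered single endocrine cells and small
artifacts out of every downstream statistic. The endocrine compartment is
defined as the pixel-exact union of retained components, so compartment
accounting and islet statistics can never disagree.

## Cell classification

Two routes, as in practice:

* **Single-measurement classifier** — `feature > threshold`, feature
  typically `"<marker>: Cell mean"`. Positive counts are exactly
  non-increasing in the threshold.
* **Object classifier** — a seeded 100-tree random forest on the full
  feature vector (three compartment means per marker plus their smoothed
  versions; smoothed features are included because they are added before
  classification in the reference workflow). It is trained from point
  annotations of one positive class and an `ignore` class; fewer than 100
  points per class triggers a warning, since accuracy measurably improves
  beyond that. When training points are derived from synthetic ground truth,
  the ignore class is enriched (50%) with *hard negatives* — marker-negative
  cells of the same lineage, e.g. CD45⁺CD3⁻ leucocytes when training CD3 —
  mirroring how an analyst actually annotates.

Composites are set intersections: beta = INS⁺ ∧ PI⁺ (and beta ∧ enzyme for
PC1/3, PC2, CPE), alpha = GCG⁺, pan-endocrine = CHGA⁺. Marker labels are
independent sets, and composition percentages are reported per marker set —
they are not forced to partition (beta% + alpha% need not equal 100).
T cells are gated in two stages: the CD8 model is evaluated only on CD3⁺
cells, so CD3⁺ = CD3⁺CD8⁺ ∪ CD3⁺CD8⁻ is an exact partition and CD4 counts
are CD3 − CD8 in every stratum by construction. The manual correction of
threshold over-detection used interactively is out of scope; the ML route is
the supported remedy.

## Spatial analysis

Distance is Euclidean from the **cell centroid** to the nearest islet
polygon, 0 for interior centroids (whether the reference tool measured from
centroid or boundary is unstated; centroid is the documented choice here).
The five canonical bands are [0, 1), [1, 50], (50, 200], (200, 500],
(500, ∞) µm. As printed, the scheme leaves exactly d = 1 unassigned; the
1–50 band is closed at 1 so the partition is total. Band 0 is intra-islet;
band 1 (≈ 3–5 acinar cell diameters) is the peri-islet area. Heatmaps render
cells colored by distance clipped to [0, 250] µm on the perceptually ordered
`turbo` map with islet outlines overlaid; the raster is `extent/mpp` pixels
and deterministic.

"Within or immediately adjacent" (for infiltration and insulitis) is
quantified as distance ≤ `adjacency_radius` (default 15 µm, configurable —
the consensus definition never gives a number). Strict-interior counts are
reported alongside adjacency-inclusive ones, since published compartment
counts are ambiguous between the two.

## Quantification

Per-islet composition percentages are `100·count/n_cells`; per-lineage enzyme
percentages use the lineage count as denominator. PI/INS is a per-islet count
ratio, undefined (excluded from medians) when the islet has no INS⁺ cells.
Densities are `count/area_mm2`. Cross-slide aggregation uses the
**population** SD (ddof = 0) — deliberately nonstandard, forced by
recomputation of the published six-section summary row (the printed islet
count SD 67.6 matches ddof = 0; ddof = 1 gives 74.0) — with nullable columns
(markers absent from a staining combination) excluded pairwise from both
mean and SD. Report tables round areas, densities and percentages to one
decimal; internal arithmetic is full precision.

Insulitis: positive iff at least `min_qualifying_islets = 3` islets with
equivalent diameter ≥ 150 µm (2·√(area/π)) carry ≥ 15 CD45⁺ **or** ≥ 6 CD3⁺
cells within/adjacent, **and** at least one pseudoatrophic islet (0 INS⁺
among ≥ 10 cells) exists. Missing markers yield "not assessable", never a
silent negative.

## The synthetic slide generator

The generator emulates a tail-of-pancreas section at reduced physical scale:

* **Tissue** — one connected, elongated (2.6:1 by default) star-convex blob
  scaled to `tissue_fraction` (default 0.55) of the frame; background 10,
  noise σ = 2 (a.u.), zero-clipped.
* **Islets** — `n_islets` clusters placed with margins inside the tissue;
  per-islet cell counts are log-uniform on [5, 300] by default (the printed
  size histograms constrain only that most islets hold 10–100 cells; the
  log-uniform family is a modeling choice, not a claim). Cells sit on a
  jittered phyllotaxis layout at 9.5 µm spacing; the truth polygon is the
  convex hull of member cells dilated by the cell radius — the same footprint
  the stained area presents to the pixel classifier. Per-cell class is
  sampled i.i.d.: beta 0.65, alpha 0.30 (the physiological 50–70% / 20–40%
  range), rest CHGA-only; enzyme positivity per lineage follows the published
  positivity means (e.g. PC1/3 0.68/0.49 in beta/alpha).
* **Exocrine** — acinar nuclei on a jittered 18 µm grid (≈ 3000/mm², a
  scaled-down density chosen for watershed-resolvable packing) plus scattered
  single endocrine cells at 8/mm².
* **Immune cells** — deterministic counts `round(density · exocrine mm²)`
  (CD45 210/mm², CD3 115/mm², CD8 = 45% of CD3, the measured whole-section
  values), so recovered-density errors measure detection fidelity rather than
  placement shot noise. Each cell samples a distance band from
  `immune_distance_weights` and is rejection-placed so its true
  nearest-islet distance falls in that band; band realization is therefore
  multinomial in the weights, and the recovery tests check binomial 99% CIs
  per band. The default weights follow the printed whole-section T-cell
  distribution (most cells 200–500 µm from an islet). **Scaled-down frames
  cannot realize the > 500 µm band** at realistic islet densities (a ~1–2 mm²
  field is everywhere within ~300 µm of an islet), so the small test and
  acceptance specs put zero weight there; the generator raises rather than
  silently misplacing cells in an infeasible band.
* **Rendering** — every cell is an isotropic Gaussian nuclear blob
  (σ = radius/2, clipped at 3σ, peak 120) in Hoechst; positive endocrine
  markers are cytoplasmic disks (σ = cell radius/2, peak 100); membrane
  immune markers are a ring at 0.8·cell radius plus a 35% fill, so the
  centroid of a positive cell still clears background + 3·noise σ while
  preserving the cytoplasm/nucleus contrast that full-feature classifiers
  exploit. Negative same-lineage channels receive a faint (2 a.u.)
  nonspecific blob. An optional dim mode (`dim_immune_fraction`, intensity
  ×0.25) creates the bimodal immune staining used in the
  thresholding-vs-ML comparison. A single seed drives per-stage substreams;
  generation is bit-reproducible.

**What passing recovery tests show** — that the pipeline's geometry,
segmentation, classification and spatial arithmetic are correct and
internally consistent under a smooth-blob image model with known truth. They
do **not** establish performance on real acquisitions: the renderer has no
point-spread function, autofluorescence spectra, channel bleed-through,
staining gradients, overlapping 3D nuclei, or debris, and the default
thresholds are calibrated to its intensity scale.

## Problem sizes and runtime

The committed experiments run on one CPU: the test suite uses 0.16–1.44 mm²
frames (400²–1200² px at 1 µm/px, the larger one exercising the 200–500 µm
band), and the acceptance script a 2.56 mm² frame (1600² px, ~4600 cells,
14 islets) — sizes chosen so each driver completes in seconds to a couple of
minutes while every statistic keeps enough objects to be meaningful (≈ 500
islet cells, ≈ 280 CD45⁺ cells per slide). The pipeline itself is
resolution-independent — all physics is in µm — and scales linearly in pixels
(feature extraction and forest prediction dominate).

## Known limitations

* Proprietary WSI formats (.czi, .svs), tiled/lazy reading, brightfield
  stains, 3D reconstruction and deep-learning segmentation are out of scope.
* The pixel classifier is retrained per slide from a labeled ROI; no
  transfer across staining combinations is attempted.
* Statistical output is descriptive (mean ± SD, medians); no inference
  across donors.
* Real-image thresholds (tissue, nucleus, marker positivity) ship as
  synthetic-calibrated defaults and must be optimized per acquisition, as
  interactive workflows also require.
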