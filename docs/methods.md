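# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and resolution

All geometry lives in real-valued microns with the origin at the image
top-left, x rightward, y downward; pixel (i, j) has its center at
((j+0.5)·mpp, (i+0.5)·mpp). Analysis runs at exactly 1 µm/px; other
resolutions are bilinearly resampled first. Working in microns makes every
feature resolution-independent by construction.

Missing values are NaN sentinels (degenerate regions — fewer than 3
glands, no sub-graph edges, a zero 95th percentile — must not crash the
pipeline); downstream statistics exclude them pairwise, and model training
drops all-NaN columns.

## Lumen segmentation

The reference pipelines in this area use a trained neural segmenter; this
package substitutes a classical baseline behind a pluggable interface
(any function producing a label mask, or precomputed masks, can be
swapped in). Gland lumens are unstained and near-white on H&E, so the
baseline thresholds *low-stain* (chroma below in-region Otsu) and
*high-luminance* (above in-region Otsu) pixels, then applies
opening-by-reconstruction (a radius-2 disk opening removes speckle; the
reconstruction restores the surviving components' original boundaries,
which matters because a plain opening corrupts high-harmonic Fourier
descriptors), hole filling, a 40 µm² minimum-area filter (no maximum),
and centroid-in-polygon region membership. A lumen-free region is
detected by requiring the unstained chroma class to be separated from the
stroma by at least 0.08 (chroma units in [0, 1]).

Vectorization contours the Gaussian-smoothed (σ = 0.8 px) component
indicator at its half level, giving sub-pixel boundaries without
marching-squares staircase; only the outer contour is traced (holes are
filled upstream).

## The 242-feature catalog

The catalog order is fixed: shape (96) + graph (52) + sub-graph (68) +
Haralick (26). The morphology/architecture sub-total is 216.

**Shape (24 descriptors × 4 statistics).** Boundaries are resampled to
N = 128 equal-arclength points (power of two for the DFT; resolves lumens
of 30–300 µm), oriented counterclockwise. Fourier descriptors use the
centroid-distance signal r(t), FD_k = |F_k|/|F_0| for k = 1..10 — the
DC normalization gives scale invariance and the magnitudes give rotation
and starting-point invariance; descriptor indices are 1-based (the first
non-DC harmonic is FD1). Hu moments are computed from *exact* polygon
moments via Green's theorem rather than a rasterization: the exact route
is rotation-invariant to float precision, which a raster grid is not at
the catalog's tolerance for the small high-order moments. They are
signed-log compressed, m → sign(m)·log10(1+|m|·10⁶)/6, switchable off.
The remaining descriptors are the mean/max radius ratio, SD/mean radius
ratio, solidity, convex-hull/polygon perimeter ratio, a local boundary
smoothness statistic, the box-counting dimension of the boundary
(measured in a canonical centroid/principal-axis frame so it is pose-
invariant; the principal-axis rotation is skipped for isotropic shapes,
where the angle is numerical noise), and circularity 4πA/P². The
descriptor list is normative for this package; circularity completes the
24-descriptor count that the 96-feature block requires. Statistics are
mean, sample SD (n−1; 0 for n = 1), median and the p5/p95 ratio with
linearly interpolated percentiles (a p95 of 0 yields the sentinel; a
p95−p5 range variant is configurable).

**Graph (52).** Voronoi cells are clipped to the annotation polygon
(unbounded cells are otherwise undefined); cell area, perimeter and mean
vertex-pair chord, Delaunay edge lengths and triangle areas, Euclidean
MST edge lengths, and 1st/3rd/5th nearest-neighbor distances are each
aggregated with the four statistics above. The local-density family adds
per-gland neighbor counts in 50 and 100 µm disks and the local lumen-area
fraction in the 100 µm disk (each × 4 statistics), plus four scalars:
gland count, glands/mm², mean gland area, and whole-region gland-area
fraction.

**Sub-graph (68).** An ε-neighborhood graph joins centroids closer than
ε = 2.0 × the median 1-NN distance (config-exposed; the data-adaptive
radius keeps the graph scale-free across gland densities). Seventeen
metrics are aggregated by {mean, SD, skewness, excess kurtosis}: the
pooled edge-length distribution (so `subgraph:kurtosis:edge_length` is
the Fisher excess kurtosis of all edge lengths, sample-moment estimator,
defined as 0 for zero-variance input) and sixteen per-component metrics
(node/edge counts, edge-length summaries, density, degrees, hop
diameter/radius/eccentricity, clustering coefficient, mean path length,
hull area, spatial extent).

**Haralick (26).** Luminance inside the annotation is min–max quantized
to 32 gray levels; symmetric, normalized co-occurrence matrices at
distance 1 px along 0°/45°/90°/135° (pairs must have both pixels inside
the region, so the GLCM is computed directly rather than through a
library routine that cannot mask); the 13 classical statistics (natural
logarithms, 0·log 0 = 0, correlation and IMC1 defined as 0 for a single-
level region) are summarized by their mean and range across the four
angles. Regions smaller than 64 × 64 µm² yield sentinels.

## Stability filtering and the batch audit

The stability step runs on features of *benign* regions: for each feature
the two-sample Kolmogorov–Smirnov statistic is computed for every pair of
sites with at least 10 regions, and the feature is dropped when the
maximum pairwise KS exceeds τ = 0.4 (config-exposed). KS is rank-based —
the filter is invariant to monotone per-feature rescaling — and the
fixed-statistic rule (rather than p-values) is sample-size robust. The
29 image-quality metrics are a pinned normative list covering brightness
(5), RGB channels (6), HSV color distribution with circular hue
statistics (6), stain deconvolution channels (7), and structure/quality
(5). The UMAP audit (15 neighbors, min_dist 0.1, Euclidean, seeded)
reports the mean silhouette of site labels in the 2-D embedding: high
values mean sites cluster (batch effect), near-zero means good mixing.

## Survival model

BCR labeling from a PSA series: event at the *second* test strictly
> 0.2 ng/mL (the two tests need not be consecutive), otherwise censored
at the last test; patients without a test ≥ 30 days post-surgery are
excluded.

The risk model is Cox partial likelihood with penalty
λ[α‖β‖₁ + (1−α)‖β‖₂²/2], α = 0.5. The λ path comes from the coordinate-
descent solver (scikit-survival); λ is chosen by 10-fold cross-validated
partial-likelihood deviance in the Verweij–van Houwelingen form
−2[ll_full(β_k) − ll_train(β_k)] with seeded fold assignment, and the
winner is refit on the full training set. Ties use the Breslow
approximation (standard with penalized fitting). Features are z-scored
with *training* means/SDs (σ = 0 columns flagged and excluded), so
e^{β_x} is the hazard ratio per SD.

The continuous score is logistic(β·z): the score scale is otherwise
unspecified in this problem, and the logistic map is monotone, bounded in
[0, 1], and makes "per 0.1" covariate scaling meaningful. The threshold
maximizes the two-group logrank χ² over candidate cuts at the observed
training scores between the 10th and 90th percentiles, ties resolving to
the lower cut (a median-split alternative is config-exposed); a score
exactly at the threshold is low-risk. The published six-feature model is
constructed from its per-SD hazard ratios (β = ln HR); its training-
cohort normalization is not recoverable, so µ/σ must be supplied from a
reference cohort before scoring. The combined clinical model
("Histotyping+") refits the elastic net over {score, log₂ PSA,
grade-group dummies 2–5 vs. 1}, complete cases only.

## Evaluation conventions

Harrell's c-index follows the original comparability rule — a pair is
comparable iff the smaller observed time is an event (for tied times,
iff exactly one is an event) — with score ties counting 0.5 and the
orientation higher score = higher risk. Model comparison uses a paired
patient-level bootstrap (default B = 1000): percentile 95% CIs, the
fraction of iterations model A wins (ties 0.5, so identical models score
exactly 0.5), and a two-tailed one-sample t-test on the per-iteration
c-index differences (p = 1 for identical scores). Multivariable Cox is
unpenalized (lifelines), complete-case, with rank-deficiency detected
up front and reported by column. Subgroup analysis flags logrank p below
0.05/k (reported to 4 decimals; k = 15 gives 0.0033). Genomic-classifier
categories use cuts < 0.45 (low) and > 0.60 (high) with both endpoints
inclusive to intermediate — the literal reading of the published
"0.45–0.60" interval — and a merged mode pools low + intermediate.

## Boundary erosion

"Removing the outer layer of glands" is operationalized on centroids: a
gland is outer if its centroid is a vertex of (or lies on the boundary
of) the convex hull of centroids, or its Voronoi cell is unbounded
before clipping — the standard computational-geometry reading, chosen
over geometric annotation erosion because it is oracle-testable. A
tolerance on hull-boundary membership handles the degenerate case of
collinear hull points, whose Voronoi cells can be technically bounded
but astronomically large. After removal the annotation becomes the hull
of the remaining centroids dilated by the median lumen radius, so
region-level texture is recomputed on a correspondingly smaller region.
Patients whose region empties carry their last valid score forward,
flagged. Removal is set-based, hence deterministic and order-independent,
and zero layers is a strict no-op.

## Synthetic-data generator

The generator emulates: lumen shape mixtures (disks, equal-area ellipses
with axis ratio `aspect`, crescents with a notch of `notch_depth`
diameters), broadband radial boundary noise (harmonics 2–12 with 1/k
rolloff — noise confined to low harmonics would leave the catalog's
high-order Fourier descriptors degenerately zero), gland centers from an
inhomogeneous Poisson process with a log-Gaussian intensity field
(`density_heterogeneity` scales the log-field SD) under a hard minimum
spacing of 1.2 × the mean lumen diameter, sampled from the region eroded
by ~a lumen radius so ground-truth lumens lie wholly inside the
annotation; pseudo-H&E rendering (near-white lumens on pink textured
stroma, stain presets perturbing hue/brightness/noise per site); and
Weibull proportional-hazards outcomes, T = scale·(−ln U/e^η)^{1/shape}
with η = Σ w_i z_i over standardized per-patient knob values, censored
administratively at C ~ Uniform(0, t_max) with t_max calibrated by
bisection to the requested censoring rate. A synthetic `decipher` column
is a noisy logistic transform of η. Defaults: 1024 µm canvas at 1 µm/px,
12–30 glands per region (≥ 10 by contract), 40 µm mean lumen diameter,
disk fraction 0.5, boundary noise 0.05, density heterogeneity 0.5, risk
weight +1 on `disk_fraction` (higher disk fraction → higher risk,
mirroring the direction reported for real tumors), Weibull(1.5, 8 y),
30% censoring.

What the generator does **not** emulate: nuclei and epithelium,
photorealistic stain variation, touching/overlapping glands, annotation
errors, multifocal tumors, or any real correlation structure between
morphology and outcome beyond the planted knobs. Passing tests therefore
demonstrate internal correctness and recoverability of planted effects at
desk scale — not clinical performance; the headline cohort statistics of
real studies (c-indices near 0.68, hazard ratios near 2.8) live on
private whole-slide cohorts and are out of scope here.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical behaviors are stable: 50-region
sweeps for knob monotonicity and segmentation agreement, 25 seeds for
support/hazard-ratio recovery, a 400-patient planted cohort (200/200
train/validation split) and a 200-patient null cohort for the end-to-end
loop, 50 seeds for stability drop rates, a 140-patient cohort (100 train,
40 eroded) with 3 erosion layers, and 30 rendered images across two stain
presets for the batch audit.

## Known limitations

* The classical segmenter is adequate for synthetic and clean real tiles
  but is not a substitute for a trained model on hard H&E; the interface
  accepts any segmenter.
* The 24-descriptor shape list, the 17 sub-graph metrics, the 29 image
  metrics and the sub-graph ε rule are normative reconstructions pinned
  for testability; other published pipelines use different supplements.
* p5/p95 ratio features are undefined (sentinel) when the 95th percentile
  is exactly zero, which occurs for noise-free symmetric shapes.
* The erosion experiment's flip fractions depend strongly on glands per
  region; with desk-scale regions (~20 glands) three layers already
  remove most of the region, so flip fractions at deep layers saturate.
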