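# Methods

This note records the models, parameter choices, numerical details, and
known limitations of the package, in the order of the processing chain.

## Coordinate and data conventions

All physical coordinates are continuous micrometres with the origin at the
top-left pixel corner, x rightward and y downward; the centre of pixel
(r, c) is ((c+0.5)·s, (r+0.5)·s) for pixel size s. This single convention
drives every mask↔point conversion, centroid, and distance in the package.
Images are plain multi-page TIFF plus a channel-manifest CSV; pyramidal
containers must be converted upstream. Tables are UTF-8 comma-separated
CSV with headers; numeric fields round-trip at 6 significant digits.
Positivity flags are always exactly `score > threshold` under the active
threshold set, so re-applying thresholds is idempotent.

## Spectral unmixing

Model: per pixel, `c = M·a + b` with `M ≥ 0` column-normalized
(channels × sources), `a ≥ 0` the fluorophore abundances, and `b` a
constant per-channel background. Estimation from a single-stain library:
`b` is the per-channel median of the unstained image; column f is the
per-channel median over the `top_fraction` (default 0.01) brightest pixels
of stain f's primary channel, background-subtracted, clipped at zero and
normalized to unit sum. The autofluorescence column is estimated the same
way from the brightest unstained pixels (ranked by total intensity); when
the unstained image is flat, there is no autofluorescence structure beyond
background and the source is dropped instead of keeping a zero column that
cannot be normalized. Median statistics and the top-fraction selection make
the estimate robust to outlier pixels; both are configurable.

Unmixing solves per-pixel non-negative least squares
`min_{a≥0} ‖(c − b) − M a‖₂` (active-set, `scipy.optimize.nnls`). NNLS was
chosen over a matrix inverse to keep abundances physical; pixels are
independent, so the result cannot depend on processing order. Identical
pixel vectors are solved once and cached, which makes synthetic images with
few distinct levels cheap. A rank-deficient `M` is rejected with its
condition number. Whether the original interactive implementation uses
NNLS, ordinary least squares, or direct subtraction is not documented;
the NNLS contract here is this package's own, stated choice.

## Nuclear segmentation

Adaptive local-mean threshold (square window, default 51 μm, odd pixel
count enforced) minus an offset (default 0), hole filling, removal of
objects below 8 μm², Euclidean distance transform, peak seeds at least
4 μm apart, and watershed of the negated distance map restricted to the
foreground (8-connected objects, 4-connected watershed flooding). Two
numerical guards beyond the textbook recipe:

- the distance map is lightly Gaussian-smoothed (σ = max(1 px, sep/4))
  *only for seed detection* — ragged object boundaries otherwise seed
  spurious watershed basins; the flooding itself uses the raw map;
- foreground pixels must additionally exceed `min_intensity_frac`
  (default 0.02) of the image's 99.9th intensity percentile. An adaptive
  mean alone marks numerically faint halos as foreground wherever the
  background is essentially empty, because any tiny value beats an even
  tinier local mean.

Window, offset, minimum area and peak separation are exposed in config;
the defaults assume nuclei of roughly 6–10 μm.

## Cell expansion and cytoplasm

Every nucleus grows by up to 5 μm (default) or until it meets a
neighbouring nucleus' territory: a background pixel joins the nucleus with
the smallest pixel-centre Euclidean set distance iff that distance is
≤ 5 μm, ties going to the smaller label id for determinism. The
implementation computes one exact distance transform per label and takes
the argmin, which matches a brute-force per-pixel oracle exactly (tested on
images up to 128²) at O(n_labels · H · W) cost — acceptable at fixture
scale and easily replaced by a tiled variant for large slides. Cytoplasm is
the per-label set difference cell \ nucleus; the three masks share labels by
construction and this invariant is validated on construction.

## Mask matching

For all intersecting label pairs between two masks the Szymkiewicz–Simpson
coefficient |A∩B|/min(|A|,|B|) is computed; pairs with coefficient
strictly greater than 0.5 enter a bipartite graph whose connected
components are classified by side cardinalities (1-1, 1-many, many-1,
many-many — the last requiring ≥ 2 on both sides); labels without a
retained partner are "1 - missing" / "missing - 1". Equality at 0.5 is
excluded, per the strict inequality of the rule.

## Quantification, thresholds, phenotypes

Scores are mean/median/75th/90th-percentile statistics per marker over
nucleus, cytoplasm and whole-cell regions; an empty cytoplasm yields a
missing value, never zero. Positivity is strict (`score > threshold`);
the classifier "unknown" rule is strict the other way (maximum class
probability < 30% → unknown, equality keeps the label). Phenotype keys are
ordered rules over {+, −, any} patterns; among multiple matching rules the
one whose required-positive marker ranks highest in the priority order
wins. This reproduces the canonical double-positive example
(CD3⁺CD163⁺ → T when CD3 outranks CD163) and generalizes
deterministically; a full priority order over all key markers is assumed.
Key completeness is verified at load time by enumerating all 2^M
combinations (M ≤ 12) and failing on any unresolved ambiguity. The
classifier itself is pluggable — anything with scikit-learn's
fit/predict_proba surface; the package supplies the 80:20 split
(deterministic per seed, stratifiable), the unknown rule, and the
evaluation metrics (per-class TPR/FPR, accuracy, macro-F1 over classes
present in the truth).

## Tissue segmentation

Naive labelling (tumor iff CK⁺), then one simultaneous reassignment pass on
the naive labels: a same-compartment connected group of fewer than 5 cells
with at least one graph edge to an opposite group of more than 10 cells
switches compartment. Inequalities are strict exactly as printed, and all
decisions are evaluated before any is applied; on the fixtures used in
tests a second pass changes nothing.

## Density, alpha shapes, TLS, patches

Local density is a disk count: (neighbours within 50 μm, excluding self,
plus one) / (π·r²), reported in cells/mm². The rule names only the
threshold (2000 cells/mm²), not the estimator; the disk count is this
package's choice, with the radius exposed in config. TLS detection keeps
B cells with density strictly above threshold, outlines them with an alpha
shape (Delaunay triangles with circumradius ≤ α, default α = the density
radius, 50 μm), and keeps each connected polygon with ≥ 40 member cells.
No expansion is applied to TLS patches. Collinear or < 3-point inputs fall
back to a convex hull buffered by α/10. Note that the disk-count estimator
evaluated on a regular lattice *at exactly the threshold intensity*
overshoots the continuum value (discrete counts within a 50 μm disk on a
22.4 μm lattice give ≈ 2670 cells/mm² at a true 2000), so uniform fields at
the printed threshold are detected; detection-threshold checks therefore use
intensities with at least a 2× margin on either side.

Graph patches (IMC style): cores are connected components of the
neighbourhood graph restricted to member phenotypes with ≥ 25 cells; every
cell whose centroid lies within the expansion distance (inclusive) of the
nearest core-member centroid joins — 10 μm for CD20 patches, 25 μm for
tumor patches. Distances are centroid-to-centroid because only centroids
are guaranteed present in IMC tables. Membership is monotone in the
expansion radius. The mask-expansion adjacency rule ("touch after each
boundary grows d") is implemented as minimum pixel-centre set distance
≤ 2·d.

## Spatial concordance

Landmark alignment uses the closed-form least-squares similarity fit
(SVD of the centred cross-covariance, Umeyama); reflection is refused
unless explicitly allowed, the residual RMSE is reported, and at least 2
pairs are required mathematically (4+ recommended, and enforced by the
pipeline driver). The cross K function uses the translation edge
correction e(u,v) = |W| / |W ∩ W_{v−u}| — exact and simulation-free on
rectangular windows — with `correction="none"` as the config alternative;
which correction the original analysis used is not stated. Radii default
to 512 steps from 0 to a quarter of the shorter window side; L̂ = √(K̂/π).
The pairwise computation sorts all inter-type distances once and reads
cumulative weights per radius, matching the naive double sum to 1e-9.

The MAD test statistic is max_r |L̂(r) − r| against the *theoretical* CSR
expectation (a config flag could substitute the simulation mean; the
theoretical reference is the default and the documented assumption). The
null is conditional CSR: binomial patterns with the observed per-type
counts in the same window, 99 simulations by default, rank p-value
(1 + #{T_sim ≥ T_obs}) / (nsim + 1), so 0.01 is the smallest attainable p.
Co-localization requires area > 0 AND p ≤ 0.01. All simulations take a
single integer seed.

## Batch QC

Coefficients of variation use the sample standard deviation (ddof = 1; the
estimator is not specified by the rule, so the unbiased-variance form is
this package's choice) and are reported as fractions, rendered as percent
in user-facing output. Marker CVs are computed per (cell type, marker)
across batches, restricted to markers declared relevant for the cell type
(to avoid scoring pure noise), then averaged per marker over its relevant
cell types. Sample QC: missing/folded fraction > 0.5 fails, (0, 0.5]
warns — exactly 50% is a warning because failure requires *more than* 50%;
one missing-signal marker warns, more than one fails; a fully necrotic
sample fails. Marker-signal failure detection is operator-supplied, not
automated.

## Synthetic fixtures

The tissue generator places nucleus centres by rejection sampling with a
minimum separation (default 14 μm ≳ 2–3 nucleus radii, guaranteeing
disjoint disks), renders DAPI as Gaussian-blurred disks (σ = 1 μm,
level 200) and paints each marker at its phenotype's on/off level
(default 100/0) on the ground-truth cell regions, with optional additive
Gaussian noise truncated at zero. Defaults — 60-cell, 400×400 μm images at
1 μm/px with three phenotypes — keep every test in milliseconds-to-seconds
while leaving nuclei dense enough to exercise the Voronoi expansion.
Packing that fails 5000 consecutive placement attempts raises rather than
looping. The generator emulates well-separated cells with crisp
expression; it does not model optics, marker spill-over between adjacent
cells, staining gradients, or tissue texture, so passing recovery tests
demonstrates correctness of the algorithms, not robustness to real
staining artefacts.

Point patterns: CSR (fixed-count binomial or Poisson), square grids
(intensity 1/spacing²), and Thomas cluster processes. The mixing-scenario
generator forward-simulates `c = M·a + b` with sparse constant-amplitude
blob abundances for the single-stain library (so the top-fraction median
estimator recovers `M` exactly in the noiseless case) and a dense random
abundance field for the mixed image. The batch-series generator draws
multinomial counts and log-normal multiplicative batch factors
exp(σ·z) for marker means — log-normal keeps means positive and has
CV = √(exp(σ²) − 1) ≈ σ for small σ, which is what the recovery tests
check (within 20%, averaging over 24 relevant cell-type/marker pairs and
11 batches to tame the CV estimator's own sampling noise).

## Problem sizes used in tests

Monte-Carlo suites are sized for a laptop-class single CPU: MAD-test
calibration uses 200 CSR replicates of 30+30 points with 19 null
simulations each (the rank test is exact at α = 0.05 for any nsim with
(nsim+1)·α integral); L-area centring uses 100 replicates of 50+50 points;
TLS intensity discrimination uses 25 replicates per intensity in 0.36 mm²
windows; oracle equivalences use ≤ 128² images and ≤ 500-point patterns.

## Known limitations

- Per-label distance transforms make expansion and mask-expansion
  adjacency O(n_labels · H · W); whole-slide scale would need tiling.
- The alpha-shape polygon is a union of triangles; patch areas are the
  areas of those unions, with no hole-filling beyond what the alpha
  complex produces.
- The translation correction assumes rectangular windows; irregular
  observation windows are not supported.
- Third-party segmenters are consumed only through their masks (the
  matching report); none are re-implemented here.
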