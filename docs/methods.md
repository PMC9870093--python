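# Methods

## Droplet cell calling

Barcodes are ranked by total UMI count (descending; ties broken by
barcode identifier for determinism) and truncated to `max_barcodes`
(default 5000, the conventional core-barcode export size). On the
cumulative-read-fraction curve the unit-spacing forward difference at
rank *i* is barcode *i*'s fraction of the considered total, so the mean
slope over *N* barcodes is exactly 1/*N*; this identity is asserted in
the tests. A barcode is called a cell when its slope is **at or above**
the mean. Ties at the mean are labelled cell: the rule's source text
only assigns strictly-above and strictly-below, and the inclusive
convention keeps a perfectly uniform library whole instead of empty.
The label set is algebraically identical to "total ≥ mean total among
the barcodes considered", which serves as the independent oracle in a
1000-matrix property test.

Whether the mean slope should be taken over the full raw library or
only the exported core barcodes is not recoverable; `max_barcodes` is
exposed and both the classifier and the benchmarks use the considered
set consistently.

## Ambient background subtraction

For each gene, the threshold is the nearest-rank (type-1) quantile at
level 0.95 of its counts across background barcodes: the order
statistic at position ⌈0.95·n⌉. Nearest-rank is used deliberately —
thresholds must be integers to subtract from UMI counts, and
interpolating quantile rules would produce fractional thresholds the
subtraction arithmetic cannot use. Subtraction is floored at zero and
applied to all barcodes before restricting to called cells; the result
is identical to restricting first (asserted by test). Correction is
elementwise monotone and leaves genes absent from the background
untouched.

## Expression analytics

Normalization is ln(1 + 10⁴·c/C) per entry (scale factor and log1p are
the de-facto defaults of the single-cell toolkits this pipeline
interoperates with; both configurable). Cells with zero total counts
are an error naming the barcode, not silently dropped.

Marker detection is one-vs-rest per cluster: a gene is tested when it
is detected in ≥ `min_fraction` (0.1) of cells on its higher-detection
side and its log fold-change toward the cluster is ≥ `min_logfc`
(0.25), where logFC = ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)) so
the quantity is consistent under log1p normalization. Passing genes get
a two-sided Wilcoxon rank-sum test. **Bonferroni uses the total number
of genes in the matrix as the family** (recorded in
`result.attrs["bonferroni_m"]`), not just the tests performed: the
prefilter preferentially selects genes with small p-values, so a
post-selection family does not control the family-wise error — in
permutation-null simulations it produced false markers in most
replicates, while the all-genes family (the convention of the standard
`FindAllMarkers` implementation) keeps the measured family-wise rate at
the nominal level. Retained markers additionally require a positive
mean difference (positive-only reporting) and p_adj < 0.05.

Cluster identity needs ≥ 3 of a cell type's panel genes among a
cluster's retained markers; a cluster reaching that bar for two types
raises an error — ambiguity is surfaced, never auto-resolved. Cluster
pairs with zero head-to-head differential genes (same prefilters,
either direction) are merged; the indistinct relation is closed
transitively and each component collapses to its smallest label.

Cell states concatenate timepoint and cell type (`2dpa.BEC`); parsing
splits on the first dot, so timepoint labels must not contain dots.
State heatmaps average normalized expression per state and scale each
gene row by (x − min)/(max − min); constant rows map to all zeros by
convention. Cross-species heatmaps resolve an ortholog table per
species and drop unresolvable rows with a warning. Column orders are
taken as given (mock → 0 → 1 → 2 → 3 → 7 dpa within a branch); no
algorithmic branch assignment is attempted.

## Image quantification

The cellular mask is the union of per-channel global-Otsu foregrounds
of the GFP and mCherry reporter planes, hole-filled, with objects under
50 px² removed and 8-connected labelling; the nuclear mask does the
same on DAPI with a 10 px² floor. Otsu is a stand-in for the original
(unpublished) thresholding operators; a fixed-threshold override exists
for reproducibility. A nucleus belongs to the cell label under its
centroid pixel. Cells must have exactly one nucleus to be measured
further; removals are logged with their counts. Touching objects are
not split (no watershed — the measurement pipeline being reproduced has
no declared splitting step), and cells whose mask touches the image
border are excluded and logged, since their shape is truncated.

Morphology: area is the mask pixel count (px²; no physical
calibration), eccentricity √(1 − λ₂/λ₁) of the ellipse with matching
normalized second central moments, centroid in 0-based (row, col)
pixel-centred coordinates. Lineage calls require one reporter above its
threshold and the other at or below; anything else is `ambiguous`. The
biliary-derived fraction is the share of CFP-positive cells
(hepatocyte identity) carrying the mCherry lineage; it is undefined
(error) with zero CFP-positive cells.

Percent-positive-nuclei time courses pool each animal's nuclei across
its images before dividing; group statistics are then computed over
animal values, not nuclei. The marker-positivity threshold is Otsu over
the candidate nuclei's mean intensities per animal by default, or a
fixed configured value. Per timepoint the comparison against mock is a
two-sided rank-sum test, Bonferroni-corrected over the number of
timepoint-vs-mock comparisons (per marker, not global across markers).

## Statistical primitives

The rank-sum statistic W is the sum of pooled midranks of the first
sample. With pooled n ≤ 12 and no ties the permutation distribution is
enumerated exactly and the two-sided p doubles the smaller tail (capped
at 1); otherwise a normal approximation with tie-corrected variance and
a 0.5 continuity correction is used (continuity on by default,
configurable). Bonferroni is min(1, p·m); SEM is the n−1 sample
standard deviation over √n, undefined (NaN) below two values.

## Synthetic data generators

The generators define the reference conditions under which the
pipeline is validated:

- **Droplets**: 50 true cells at Poisson(2000) UMIs with 20% of each
  cell's transcripts drawn from the shared ambient profile, over 2000
  empty barcodes at Poisson(20) pure-ambient UMIs; gene draws are
  multinomial. Profiles are sparse Dirichlet(0.3) draws over 100 genes
  so a handful of genes dominate, as in real ambient soup. This
  reproduces the knee-shaped barcode-rank curve; it does not model
  doublets, UMI collisions or barcode errors.
- **State expression**: negative-binomial counts (size = dispersion θ,
  variance m + m²/θ, default θ = 2 — typical droplet overdispersion;
  θ → ∞ recovers Poisson) with per-state means set by named gene
  programs. Marker benchmarks use an 8-fold shift (means 8 vs 1) with
  100 cells per cluster over a 200-gene matrix.
- **Images**: cells are filled ellipses with analytic truth
  (area = πab, eccentricity = √(1 − (b/a)²)); nuclei are disks along
  the major axis in the DAPI channel. Rasterisation thresholds
  subpixel coverage (8×8 grid) at one half, then corrects the pixel
  count toward round(πab) by flipping marginal boundary pixels in
  pairs chosen to cancel the traceless part of their second-moment
  perturbation — binary masks of small shapes are otherwise biased by
  several percent in area, and a single asymmetric boundary pixel on a
  disk already shifts measured eccentricity by ≈ √(4/area) ≈ 0.1.
  Shed pixels must keep a 4-connected path to the outside so no
  fillable holes appear. Random fields snap cell centres to integer
  pixels: at arbitrary subpixel centres any binary raster of a small
  circle is intrinsically anisotropic, so near-zero eccentricities are
  only meaningful on grid-aligned centres. Overlapping cells are
  rejected rather than resolved, mirroring the no-splitting
  measurement pipeline. Noise is i.i.d. Gaussian per channel; no PSF,
  shading or 3-D structure is modelled.
- **Time courses**: per-animal positive fractions are Binomial(200, p)
  draws with mock p = 0.02 and injured p = 0.40, 9 animals per group —
  a typical cohort size for these experiments.

All randomness flows from one explicit seed per call; identical specs
and seeds give byte-identical outputs, and the end-to-end demo pipeline
writes byte-identical CSVs under a fixed seed.

Passing benchmarks on these generators shows the computations recover
known truth under their stated noise models; it does not certify
performance on real images with uneven illumination, touching cells or
out-of-focus nuclei, nor on libraries whose ambient profile differs
from the cell population more subtly than simulated.

## Problem sizes

Benchmarks use 20 seeds for droplet recovery and marker calibration,
100 fields (≈600 cells) for image-metric recovery, and 50 replicates
for time-course power; these sizes give Monte-Carlo standard errors
comfortably below the margins being asserted while keeping the full
suite fast.
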