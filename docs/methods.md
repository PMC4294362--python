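# Methods

`stromascreen` analyses single-channel fluorescence images of primary
acute lymphoblastic leukemia (ALL) cells co-cultured on a mesenchymal
stromal cell (MSC) feeder layer, and turns per-well viable-cell counts
into per-gene hit calls for arrayed RNAi screens in the stromal
compartment.  This note records the models, the parameters that matter,
and the choices made where the design was genuinely open.

## The synthetic co-culture microscope

Because both compartments share one fluorescence channel, every
downstream stage is validated against a simulator that renders wells
with known ground truth (`stromascreen.simulate`).

**Scene model.**  Cells are placed uniformly at random in a disk-shaped
well; a square grid of contiguous camera fields (default 3×3 fields of
512×512 px) is centred on the well and, with the default geometry,
covers ~75% of the well area (the acquisition design point is >50%
coverage).  Three object classes are rendered as PSF-blurred disks:

| class        | radius (px)    | peak intensity (counts) | structure |
|--------------|----------------|--------------------------|-----------|
| viable ALL   | N(3, 0.5)      | N(12000, 1500)           | smooth    |
| dead ALL     | 0.6 × viable   | 0.4 × viable             | smooth    |
| MSC          | N(15, 3)       | N(6000, 1000)            | speckled  |

MSC "structure" is multiplicative band-limited speckle: smoothed
(σ = 2 px) unit-variance Gaussian noise, scaled by an amplitude of 0.5
around a mean of 1 and clipped positive.  This gives the within-nucleus
texture that Haralick features separate; no claim is made that it
reproduces real chromatin texture.

**Optics and noise.**  Painted scenes are convolved with a Gaussian PSF
(σ = 1 px), offset by a uniform background (500 counts), modulated by a
planar illumination gradient (±10%, random orientation per field), and
read out as Poisson(signal × g)/g shot noise at gain g = 0.05 plus
Gaussian read noise (σ = 30), clipped to the 16-bit range.  At these
settings a viable ALL nucleus has peak SNR ≈ 100 and a dead nucleus
≈ 40 — a clean, high-SNR regime by design, so that detector failures
indicate algorithmic bugs rather than photon statistics.

**Density.**  The wet assay seeds 25 000 ALL on 2 500 MSC per well.  At
that confluency nuclei touch, and no detector without a splitting stage
can resolve them; the package's defaults therefore scale the density
down (300 viable / 60 dead / 30 MSC per well) while preserving the
10:1 ALL:MSC seeding ratio, and `SimulationConfig.high_density()`
exposes the full plate density for count-level work.  Two placement
constraints keep ground truth matchable at default density: ALL–ALL
centres are at least 1.5 nuclear diameters apart (9 px) and MSC–MSC
centres at least 2.2 mean radii apart (33 px); both are disabled or
relaxed at plate density, where merging is the physically correct
outcome.

**Screens.**  A screen is a plate layout (wells → sample, target gene,
role) plus an effect model: per-(sample, target) viability multipliers.
Realized viable counts are Poisson(baseline × multiplier); cells killed
by an effective knockdown reappear in the dead-cell expectation;
scrambled controls always have multiplier 1 and toxic controls
(stroma-killing siRNA) multiplier 0 with the MSC count depleted to 20%.
All draws are keyed on (seed, well id), so outputs are bit-identical
under a fixed seed and invariant to well order.

## Spot detection

The à trous (undecimated) wavelet transform uses the separable
B3-spline kernel [1/16, 1/4, 3/8, 1/4, 1/16], dilated at scale i by
inserting 2^(i−1)−1 zeros between taps, with mirror boundary handling.
Wavelet planes W_i = A_{i−1} − A_i satisfy the exact reconstruction
A_0 = A_J + ΣW_i, which the tests verify to 1e−6 relative (measured:
~1e−16) together with agreement against a brute-force dilated-kernel
convolution oracle.

Detection thresholds each selected plane at k·σ_i with k = 3 and σ_i
the plain median absolute deviation over all pixels divided by 0.67449
(zeros are *not* excluded from the MAD; this is deliberate and keeps
the estimator simple and scale-equivariant, at the price of a slight
over-estimate on object-dense fields).  The pixelwise product of the
thresholded planes over scales {2, 3} — matched to nuclei a few pixels
across — is taken, and 8-connected components of the positive product
with area in [4, 250] px become spot candidates.  Centroids are
intensity-weighted on the original image.  Components within 4 px of
the field border are discarded (partial objects).  Because σ_i scales
linearly with the image, the detected spot set is invariant to global
positive rescaling.

Nuclei far above the spot band (MSC) are segmented by thresholding the
coarsest smooth plane A_J at max(Otsu, median + k·MAD/0.67449); the
robust floor prevents Otsu from splitting pure background noise on
empty wells.  Components larger than 250 px become LARGE_OBJECT
candidates; pixels already claimed by spots are removed first, so masks
are disjoint.  **No touching-object splitting is implemented** — a
known limitation; the simulator's separation constraints make it
unnecessary at default density, and at plate density merged objects are
expected.

## Object features

55 named features per candidate, in a fixed, versioned order
(`FEATURE_NAMES`, schema version 1):

* 12 intensity statistics on the pixel mask (mean, median, sd, MAD,
  min, max, integrated, 10/25/75/90th percentiles, mass displacement);
* 16 shape descriptors (area; perimeter as skimage's weighted
  border-step count, diagonal steps √2 — this pins form factor
  4πA/P² down bit-exactly; eccentricity; solidity; extent; equivalent
  diameter; major/minor axis; Hu moments 1–7);
* 26 texture features: the 13 classic Haralick GLCM statistics (ASM,
  contrast, correlation, variance, inverse difference moment, sum
  average/variance/entropy, entropy, difference variance/entropy, and
  both information measures of correlation) at offsets 1 and 2 px,
  averaged over the four principal directions (which makes them exactly
  invariant to 90° rotations);
* local background contrast (mean inside − mean in a 2-px ring).

GLCM patches are quantized to 16 grey levels on the per-object min–max
range; out-of-mask pixels are assigned a reserved level whose GLCM
row/column is dropped before normalization.  A constant patch is
defined to have contrast 0, homogeneity 1, entropies 0 and correlation
1.  Degenerate masks (down to one pixel) receive defined fallbacks and
no feature is ever NaN; natural logarithms are used in all entropies.

## Classification

A random forest (300 trees, scikit-learn defaults otherwise,
`class_weight="balanced"` for inverse-frequency class weighting)
assigns candidates to VIABLE_ALL / DEAD_ALL / MSC / ARTIFACT.  Training
labels come from simulator ground truth: each candidate takes the class
of the nearest true object whose acceptance radius
(max(2.5 px, 1.0 × true radius)) it falls inside — several detections
may legitimately share one large stromal nucleus — and unmatched
candidates become ARTIFACT.  There is deliberately no interactive
annotation interface; labels can also be supplied as a CSV.  A
stratified 5-fold cross-validated accuracy is computed before the final
fit and stored on the model, together with a hash of the feature schema
so a model cannot be applied to a different feature layout.  Training
wells are rendered class-balanced (default 150/150/60 per well) because
the screen-density class mix would starve the MSC class.

## Screen statistics

Per-well viable counts are normalized per sample to the mean of that
sample's scrambled negative-control wells (M = mean of target
replicates / control mean; a zero control mean is flagged and reported
missing, never infinite).  Each (sample, target) is tested against the
control counts with a two-sided Mann-Whitney U test: exact by full
enumeration of all C(n1+n2, n1) assignments when the smaller group has
≤ 8 observations, the pooled data are tie-free and the enumeration is
≤ 20 000 (the screen's standard 3-vs-6 comparison enumerates 84
assignments; the smallest attainable two-sided p is 2/84 ≈ 0.024);
otherwise the normal approximation with tie and continuity corrections.
A hit is p < 0.05 **and** M < 1; significant increases are flagged
separately; a consensus roll-up marks targets hit in ≥ k samples
(default 2).  No multiple-testing correction is applied by default —
hit calling is on raw p-values — but Benjamini–Hochberg q-values can be
added as an extra column.  Normalization is per sample (layouts
generated by the package put each sample on its own plate); no B-score
or spatial correction is attempted.

With 3 replicates vs 6 controls the exact test is conservative: over
1000 simulated null screens (Poisson counts, baseline 300) the measured
decrease-hit rate is ~0.02–0.03 at nominal 0.05, and planted knockdowns
at multiplier 0.4 are recovered in ~100% of 500 simulated screens —
both recomputed by `scripts/acceptance.py`.

## Problem sizes and what passing tests show

The test suite and acceptance script use scaled-down wells (256-px
fields, 25–150 cells per well, 3–4 training wells, a 90-well demo
screen) chosen so the full simulate-to-heatmap chain runs in minutes on
one CPU; all sizes are ordinary config values and scale up unchanged.
Passing tests show that the pipeline is *internally* correct and
well-calibrated on the simulator's assumptions — resolvable nuclei,
Gaussian PSF, planar illumination, Poisson+read noise, Poisson
replicate counts.  They do not show robustness to real-data phenomena
the simulator omits: touching/overlapping nuclei at confluency, focus
drift, debris and staining artifacts with structured texture, vignetting
beyond a planar gradient, or plate-edge effects.  On real images the
classifier should be retrained from a labelled CSV rather than from
simulated wells.

## Numerical and degenerate-input conventions

* Determinism: every stochastic step draws from a generator keyed on
  (user seed, stream name, well id); equal configs and seeds give
  byte-identical CSV outputs.
* Blank or constant images: no spots, no large objects, no errors.
* Empty candidate sets propagate as header-only tables; empty feature
  tables predict to empty label vectors.
* Ties in the U test fall through to the corrected normal
  approximation; identical pooled samples return p = 1 exactly.
* p-values are clamped to (0, 1]; survival ratios to [0, ∞).
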