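# Methods

This note documents the models, parameter choices and numerical
conventions behind `dynscreen`, in the spirit of a statistical-methods
appendix: what is assumed, what is configurable, and what the synthetic
validation does and does not demonstrate about real screening data.

## Generative model of a synthetic screen

The generator (`dynscreen.synth`) emulates the statistical structure an
arrayed dynein-cargo screen presents to its analysis, not the optics of
any particular microscope.

**Plate layout.** 16 × 24 wells per plate. The default control design is
38 NTC (non-targeting control), 13 crLIS1 (positive control: cargo
dispersion with partial viability loss) and 13 crPLK1 (editing control:
near-total loss of viable cells) wells per plate, dispersed across the
plate by a seeded permutation; the remaining 320 wells carry library
crRNA pools, each gene occupying a configurable number of replicate
wells. Each well owns an independent RNG stream keyed by
`(seed, plate, row, column)`, so any well can be regenerated in
isolation and layout order never perturbs the draws.

**Cell populations.** Per well, the cell count is
Poisson(μ_cells · v · ε_w), where v is the viability multiplier of the
planted effect (1 for no effect, 0.70 for crLIS1, 0.05 for
lethal/crPLK1 — the lethal class leaves ≤ 10 % of the NTC count by
construction) and ε_w a log-normal well random effect. The default
μ_cells is 1,500, matching a typical seeding density for this assay
format; tests and the acceptance script run at 150–250 cells per well,
which preserves every distributional property while keeping runtimes in
seconds. A configurable fraction of cells (default 8 %) carries
apoptotic/mitotic-like nuclear morphology (small, dense, very round
nuclei) for the viability gate to remove.

**Spots.** Per cell and channel, spot counts are negative binomial with
mean m = 30 and shape k = 8 (variance m + m²/k), a standard
overdispersed count model for organelle numbers. Each spot's distance
from the nuclear boundary follows the mixture

    d ~ π_c · Exponential(λ)  +  (1 − π_c) · AreaUniform(cytoplasm),

with clustered fraction π_c = 0.70 and decay length λ = 4 µm (the
exponential is truncated at the cytoplasm edge and renormalized; the
uniform component is uniform over annulus *area*). This two-knob model
reproduces the perinuclear-clustered vs dispersed states the assay
measures: dispersion effects scale π_c by (1 − s), hyperclustering
pushes π_c toward 1, and s ∈ [0, 1] is the dimensionless effect size.
Geometry defaults: nucleus radius 8 µm, cytoplasm radius 35 µm — an
adherent osteosarcoma-like cell at 20× with 2 × 2 binning
(0.65 µm/pixel). A per-well Gaussian shift on logit(π_c) (σ = 0.10)
and a log-normal factor on the spot mean (σ = 0.05) create realistic
well-to-well variation beyond counting noise.

For feature tables, band counts are drawn directly from the closed-form
band probabilities of this mixture (distribution-identical to sampling
individual positions, and much faster); the image renderer samples
explicit coordinates from the same mixture.

**Other phenotypes.** Micronucleus counts are Poisson (rate 0.04 per
cell at baseline, +0.45·s under the micronucleus class). MTOC counts
are categorical over {0, 1, ≥2} with baseline (0.08, 0.87, 0.05); the
loss and gain classes mix the baseline toward (0.75, 0.20, 0.05) and
(0.05, 0.25, 0.70) respectively. Reporter intensities are bimodal
log-normal with a 90 % positive fraction and negatives at 5 % of the
positive intensity.

**Calibrated effect sizes.** Hit-recovery experiments are specified in
assay-relevant units: "a 4·SD shift" means the planted gene shifts the
well endpoint (log of the well-mean localization ratio) by four
NTC well-to-well standard deviations. `calibrate_dispersion_effect`
estimates the NTC endpoint mean and SD by simulation under the given
configuration, then solves for the π_c effect size by bisection on the
expected endpoint (common random numbers, no well-level noise). The
calibration is part of the experimental design, performed before any
analysis of the screen it parameterizes.

**Image rendering.** Cells are placed on a jittered grid so cell bodies
never overlap (a density cap raises an error otherwise — overlapping
cells would make segmentation untestable). Nuclei and cytoplasm are
soft (sigmoid-edged) discs; spots are 2-D Gaussians (σ = 0.8 µm) with
±20 % amplitude jitter; micronuclei are small bright discs in the
Hoechst channel; MTOC puncta sit 0.5–2 µm outside the nuclear boundary.
Spots of one channel are kept ≥ 2.6 µm apart (resampling the angle,
keeping the radial distance) so the ground truth is well-posed: two
emitters below the optical merge distance are a single spot to any
detector. The noise model is Poisson shot noise (configurable photon
budget) plus additive Gaussian read noise; the "noisy" validation
condition uses 2,000 photons at unit intensity and σ_read = 0.02.
Rendering is a pure function of the RNG state: fixed seed, identical
bytes.

## Image quantification

**Nucleus segmentation.** Gaussian smoothing (σ = 0.8 µm), a
half-maximum threshold (three-class Otsu identifies the cytoplasmic
background and nuclear levels; the threshold is their midpoint, which
recovers the true boundary radius of a smooth edge profile — plain Otsu
sits too low on background-dominated Hoechst histograms), hole filling,
small-object removal, then marker-controlled watershed on the distance
transform to split touching nuclei. Labels are renumbered in raster
order of centroids, making labelling a deterministic function of the
image.

**Cytoplasm segmentation.** Seeded watershed from the nucleus labels
over the smoothed context channel (α-Tubulin when present, otherwise
the weak Hoechst cytoplasmic background), restricted to the Otsu
foreground; a nucleus with no surrounding signal falls back to a
dilated copy of itself (logged). Cells touching the image edge are
flagged and excluded from feature extraction by default.

**Spot detection.** Multi-scale Laplacian of Gaussian over the
configured radius range (r = σ√2), thresholded on the scale-normalized
response ("detection sensitivity", default 0.1), followed by greedy
non-maximum suppression at the "splitting coefficient" distance
(default 1.3 µm): of two peaks closer than this, the stronger survives.
The minimum LoG scale is clamped to one pixel — sub-pixel scales
respond mainly to single-pixel noise spikes. The RFP channel
conventionally adds rolling-window (top-hat) background subtraction
with radius 3× the maximum spot radius. Detection defaults were
calibrated on the package's own rendered images; applying the pipeline
to real screens requires re-tuning sensitivity and splitting on control
wells, exactly as commercial spot finders are tuned.

**Ring geometry.** Spots are assigned to bands by signed distance from
the nuclear boundary (negative inside the nucleus), computed by
Euclidean distance transform: perinuclear [−7, +7] µm — the band
reaches inside the boundary because the MTOC sits at the nuclear
periphery — intermediate (7, 14] µm, outer (14, 35] µm; anything else
is out-of-range. Upper edges are inclusive, lower edges exclusive, so
assignment at an exact boundary is deterministic, and counts over the
four categories are conserved exactly. A two-zone scheme (inner region
= nucleus + perinuclear zone holding a configured fraction of cell
area, default 50 %) is available for endosome-style readouts.

**Localization ratio.** inner/peripheral spot counts; when the
denominator is zero, a pseudocount of 1 is added to both terms, which
keeps the ratio finite and monotone and reduces to (inner + 1) at zero
peripheral count. Ratios are log-transformed *after* well-level
averaging: per-cell ratios can be zero, but the well mean over any
realistic population is strictly positive, and the log symmetrizes the
endpoint distribution.

**Micronuclei.** Connected cytoplasmic components (outside a 3 µm
clearance around the nucleus) whose mean Hoechst intensity is ≥ 2× the
median cytoplasmic background and whose area lies in [0.8 µm²,
25 % of the nucleus area); larger blobs are rejected as second nuclei
and logged. These constants were chosen on synthetic data; they are
exposed as parameters because real chromatin intensity distributions
will differ.

**Viability gate.** Median ± 3.5 · (1.4826 · MAD) envelope per gated
feature (nuclear area, roundness, integrated Hoechst intensity),
calibrated from ≥ 50 NTC cells of the same batch. The robust envelope
is used instead of a plain quantile envelope because the NTC reference
population itself contains a few percent of dying cells; quantiles at
the 0.5 %/99.5 % level sit inside that contaminating mode and let it
through, while the MAD envelope stays anchored to the healthy
population (the quantile variant remains available as an option).

**Reporter gate.** Otsu on log10 intensity of NTC cells, accepted only
if the two classes are separated by ≥ 4 pooled within-class SDs
(otherwise the distribution is treated as unimodal and a configured
absolute threshold is used, with a warning). Cells must pass on both
GFP and RFP.

**Roundness.** 4π·area/perimeter², with the perimeter measured on the
marching-squares subpixel contour smoothed by a short circular moving
average — digital perimeter estimators (pixel count, Crofton) are
biased by several percent on smooth boundaries, which would make a
perfect disc score visibly below 1.

## Plate statistics and hit calling

Normalization is strictly plate-local, since controls are replicated on
every plate. The rZ score uses median/MAD with the 1.4826 normal-
consistency constant; the robust Z′ window is
1 − 3(1.4826·MAD_pos + 1.4826·MAD_neg)/|Δmedian|; two-point scores map
the NTC median to 0 and the positive-control median to a signed target
(−100 for crLIS1-referenced cargo endpoints, +100 for crPLK1-referenced
lethality). Wells with fewer than 50 gated cells are excluded from
control statistics but still scored, carrying a QC flag. Zero NTC MAD
raises an error naming the feature and plate rather than propagating
infinities.

LDA composite endpoints first filter candidates to features with
single-feature rZ′ ≥ 0.1 between the control classes, then compute
Fisher weights w ∝ (S_w + εI)⁻¹(μ_pos − μ_neg) with ridge
ε = 10⁻⁶·tr(S_w)/p for invertibility, and affinely rescale the
projection to the two-point convention. Endpoint definitions serialize
to JSON for reuse across runs.

Gene-level scores are medians over a pool's replicate wells. Threshold
rules are mean ± k·SD envelopes of a declared reference group (NTC,
crLIS1, or their pooled union for the confound exclusions), closed at
the boundary (a score exactly at k·SD is a hit — the convention must be
fixed somewhere, and closed thresholds make hit flags monotone in
|score|). Each rule declares its scale (raw/rZ/two-point) explicitly
because different endpoints live on different scales. Exclusion
precedes cargo calling: an excluded gene never carries a cargo label.
Replicate concordance is the R² of the least-squares fit between runs;
endpoints under R² = 0.2 are flagged unusable for hit calling.

## Profiling

Fingerprints are per-gene median rZ vectors over a shared feature
registry. Reduction drops features with SD ≥ 3 across the
plate-scattered crLIS1 replicate profiles, then scans survivors in
registry order and drops any feature with R² ≥ 0.8 against an
already-retained one (first kept wins — the scan order is a convention,
recorded per drop, and the operation is idempotent). Hierarchical
clustering min–max scales each retained feature to [0, 1] across genes,
uses distance 1 − Pearson r and complete linkage, sorts genes
lexicographically first so tie-breaking is deterministic, and places
zero-variance fingerprints (undefined correlation) as flagged
singletons. K-means (Lloyd's, 10 restarts, fixed seed, K = 14 by
default for cargo-signature grouping, exposed as config) operates on
Euclidean distance over mean cargo-effect vectors. UMAP runs on the
reduced, scaled fingerprints with a fixed seed and is used for
visualization only; with fewer than four genes it degrades to raw
coordinates rather than failing.

## Pipeline

A run directory holds CSV tables only (diff-able; images as multi-page
TIFF with a JSON channel-map sidecar). The global seed fans out to
per-well streams and per-stage substreams, so stages are independently
reproducible; two runs with identical config and seed are byte-identical
(fixed CSV float format, no timestamps in tables). Stages cache on
content hashes of their parameters and inputs; a cached stage is
skipped only when its recorded outputs are intact, so caching cannot
change results. The image path (render → quantify) is exercised by the
pipeline's quantify mode; the feature-table path is the canonical
analysis surface.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that every stage implements its stated
contract and that the full pipeline recovers planted truth under the
generative model above: ≥ 90 % sensitivity at ≤ 2 % false-positive rate
for dispersion genes planted at a 4·SD endpoint shift (4 wells/pool,
k = 2.5), ≥ 95 % exclusion of lethal genes, ≥ 0.99 spot precision and
recall on noise-free renders (≥ 0.9 under the configured noise), and
ARI ≥ 0.9 module recovery at 3:1 signal-to-noise separation.

The generator deliberately omits several properties of real screens:
optical crowding and out-of-focus light, segmentation errors on
irregular or touching cells, spatial plate effects (edge gradients,
dispenser striping — no B-score/median-polish detrending is
implemented), guide-level variability in editing efficiency,
cell-cycle structure, and feature correlations beyond those induced by
π_c. Performance numbers on synthetic screens are therefore upper
bounds; on real data the detection parameters, gate envelopes and
micronucleus constants must be re-calibrated on control wells, and the
assay window (rZ′) should be verified per plate before any hit calling.

## Problem sizes used in tests and acceptance

Simulated screens in the test suite and acceptance script use 1–2
plates, 40–160 genes at 4 wells per pool, and 100–250 cells per well;
rendered wells use 6 cells at 12 spots per channel. These sizes were
chosen so the full validation runs in about a minute while every
statistical margin above retains a comfortable buffer (at these sizes
the planted-effect z-margins exceed the thresholds by > 2 pooled
standard errors).
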