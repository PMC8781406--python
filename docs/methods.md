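# Methods

This note documents the models, parameter choices and numerical rules
behind `irifkit`, and what the synthetic-data tests do and do not
establish about real microscopy data.

## Conventions

Image axis order is `(z, y, x)`; image-space units are micrometres and
localization-space units nanometres, fixed at the I/O boundary
(`stack_io`) to prevent silent 1000× unit errors. Voxel indexing is
0-based with the physical origin at the corner of voxel `(0, 0, 0)`.
Default stack geometry is 50 optical sections at 0.3 µm z-spacing with
0.065 µm xy pitch — the acquisition layout this pipeline targets — so the
z-spacing is ~4.6× the xy pitch and every distance-based step must be
anisotropy-aware.

## Synthetic image model

Nuclei are homogeneous ellipsoids (counterstain ≈ 400 counts, signal-
channel background 40 counts); repair foci are additive 3D Gaussian blobs
(in-plane σ = 0.25 µm, axial σ = 0.35 µm, amplitude 200 counts in each
signal channel); noise is Poisson shot noise plus Gaussian read noise
(σ = 3 counts). At these defaults the focus peak stands ~20 noise SDs
above the intra-nuclear background, comfortably above the SNR ≥ 5 regime
the detector guarantees are stated for. The blob rendering is exactly
linear in amplitude, which the test suite exploits (regression of
integrated intensity on amplitude).

Colocalization is a controllable dial: each focus renders its channel-B
blob displaced by `channel_offset_um` along x; offset 0 is perfect
colocalization and the per-nucleus Pearson correlation decreases
monotonically as the offset grows to 2σ.

Cell populations mix G1 and G2 phases. Per-cell focus counts are Poisson
with mean `background + dose × rate`, doubled for G2 cells, whose nuclei
are enlarged 1.3× linearly in xy — G2 cells have twice the DNA content,
roughly twice the radiation-induced focus count, and visibly larger
nuclei; any factor > 1 would serve, 1.3 is a realistic choice. The
foci-per-Gy rate (default 5/Gy for G1) and the background rate (0.5) are
free simulation parameters, not estimates of any measured cell line.

What the model deliberately omits: optics-accurate PSFs, depth-dependent
aberrations, fluorophore photokinetics, chromatin texture inside nuclei,
and camera-specific noise. Passing tests therefore show that the
algorithms are correct and well-calibrated on data with the stated
structure — not that the defaults are optimal for any particular
microscope.

## Nucleus segmentation

The contract is "binary mask in, instances out". The built-in binarizer is
classical — Gaussian smoothing (σ = 0.2 µm per axis), Otsu threshold, 3D
hole filling, removal of components below 5 µm³ — and any externally
produced mask (e.g. from a trained network) can be fed directly to
`split_instances`. Instance splitting uses the Euclidean distance
transform with physical voxel sampling, light smoothing, h-maxima seeds at
depth 10% of the distance maximum, and a watershed on the negated distance
map. The h-fraction is the one genuinely free parameter; 10% separates
nuclei overlapping by up to roughly a third of their radius without
fragmenting single nuclei. Nuclei touching the xy border are flagged and
excluded by default (their volumes and counts would be truncated).

## Focus detection

Raw fluorescence intensities are not comparable across samples, so each
signal channel is min–max normalized within every nucleus before the
channels are multiplied into the colocalization image; the product is then
scale-free and the same MSER/seed thresholds apply to every nucleus.

MSER runs on the full 3D component tree (foci are 3D objects) of the
8-bit-quantized colocalization volume, implemented on `skimage`'s max-tree.
Definition: a distinct superlevel-set component `C` first appearing at
threshold `a` has variation `(|C_{a−Δ}| − |C|)/|C|`; it is maximally
stable when its variation is a local minimum along its branch (no larger
than its parent's or any child's), subject to `min_size` = 5 voxels,
`max_size` = 20 000 voxels and `max_variation` = 0.5, with Δ = 5 gray
levels. The brute-force threshold-sweep oracle in the test suite applies
the same definition by explicit enumeration and must agree
voxel-for-voxel.

Seed proposal replaces interactive expert curation with an explicit rule:
local maxima (26-connectivity, plateaus collapsed to their
lexicographically first voxel for determinism) on the MSER foreground,
gated to lie inside a nucleus, retained only if they rise ≥ 0.1 above the
nucleus's median colocalization value, then non-maximum suppression at
0.5 µm keeping the brighter of any close pair. Detection is fully
automatic and 3D; the thresholds are configuration values, not claims
about any expert's criteria.

Segmentation floods the negated colocalization image from the seeds inside
the MSER foreground (seeded watershed), so there is exactly one label per
seed, always.

On the synthetic benchmark (foci ≥ 1 µm apart, SNR well above 5) the full
chain recovers per-nucleus counts within ±1 for ≥ 90% of nuclei and seed
positions within 0.5 µm of the true centres. Foci closer than the 0.5 µm
suppression radius merge by construction — the population generator's
0.4 µm minimum spacing produces occasional undercounts, which is the
intended behaviour of the suppression rule, not a defect.

## Morphometry

Per focus: volume (voxel count × voxel volume) and mean normalized
intensity, defined as the focus-mean of `channel / 99th percentile of the
channel over the whole nucleus` (linear-interpolation percentile, fixed
for determinism; invariant to channel rescaling). Per nucleus: focus
count, nucleus volume, % volume occupied by foci, and the Pearson
correlation of the two channels over the union of that nucleus's focus
voxels ("inner pixels" = all segmented focus voxels, no erosion).
Undefined correlations (fewer than two focus voxels, or zero variance)
propagate as missing values, never as 0, and are removed from downstream
PCA by listwise deletion with a logged count. PCA standardizes features to
unit variance by default because the feature set mixes counts, volumes,
percentages and correlations; the flag is exposed since either convention
is defensible.

## Cohort statistics

Two-sample comparisons follow the normality-gated protocol: Shapiro–Wilk
on each sample at α = 0.05; both normal → Levene at α = 0.05 chooses
Student vs Welch t; otherwise Mann–Whitney; all two-tailed. The gates and
their α levels are this package's explicit choices. Under a normal null
the empirical type-I error is 0.05 ± 0.01 (checked at 10 000 replicates).
Stars: p ≤ 0.001/0.01/0.05 → ***/**/*, thresholds inclusive. Quartiles
use linear (type-7) interpolation; 1.5×IQR fences are clamped to the data
range. No multiple-testing correction is applied by default (comparisons
are reported pair by pair); Holm adjustment is available.

The G1/G2 subpopulation structure of focus counts is resolved by a
two-component Poisson mixture fitted by EM, deterministically initialized
from the lower/upper halves of the sorted counts. At n = 500 cells with a
30% G2 fraction the estimated component-mean ratio lands within ~10% of
the construction value 2. The fit runs on per-cell counts; detector
accuracy is established separately on the rendered benchmark, and chaining
the two would only add detection noise to the ratio estimate at
population scale.

## SMLM distance-frequency analysis

Analysis is 2D within each 500-nm optical section; z never enters the
pairwise distances. Blinking events are merged into molecules by
single-linkage grouping with a per-pair threshold equal to the mean of the
two localization precisions, replacing groups by precision-weighted
centroids and iterating to a fixed point (hence idempotent). In dense
clusters this also merges genuinely distinct molecules closer than the
~10 nm precision — an unavoidable property of the criterion, shared with
the acquisition it models.

The distance-frequency curve is the raw histogram of all unordered
pairwise distances (default 10-nm bins to match the ±10 nm localization
precision, r_max = 1 µm). **No edge correction is applied**: the object of
interest is the raw frequency envelope, not the variance-normalized
Ripley K/L estimator. Classical Ripley's K would divide by intensity and
correct boundary effects to make the statistic unbiased for the reduced
second moment; the envelope reading used here instead interprets the curve
directly — linear rise ⇒ randomness, small-r peak ⇒ clustering (width ≈
cluster diameter, area ≈ relative in-cluster density), a second broader
peak ⇒ neighbouring-cluster spacing.

Peak calling is made explicit because envelope reading is otherwise
qualitative: an OLS line is fitted to the counts over 400–800 nm (a range
dominated by the random component at the cluster scales of interest) and a
bin is significant when its excess over the line exceeds 3× the Poisson
counting SD of the baseline prediction at that bin; a peak requires at
least 2 consecutive significant bins, and the scan stops at the end of the
baseline range (beyond it the line is an unchecked extrapolation). The
margin is per-bin counting noise rather than the residual SD of the
baseline fit: in strongly clustered patterns the 400–800 nm window
contains structured inter-cluster variation, and a residual-SD margin
inflates with that structure until it can mask the genuine intra-cluster
peak, while the run-length requirement keeps the CSR false-call rate low
(a real cluster peak spans several bins; isolated exceedances are noise).
Measured behaviour: the intra-cluster peak is detected in every clustered
replicate tried (including adversarial seeds), CSR patterns produce no
peak in ≥ 95% of replicates, and the median detected width recovers the
closed-form FWHM of the intra-cluster Rayleigh distance law within 30%.

The intra-cluster pairwise-distance law for Gaussian clusters of scatter σ
is Rayleigh with scale σ√2; for σ = 25 nm its mode is ≈ 35 nm, which is
where the detected peak sits — below the 150 nm scale characteristic of
repair-protein nanoclusters.

## Clonogenic survival

PE = colonies/seeded × 100; SF = colonies_ir/(seeded × PE/100) × 100, the
reading under which the unirradiated reference is exactly 100%. Colony
counts exceeding seeded cells warn (merged-colony miscount) rather than
error. Replicate aggregation reports mean ± sample SD (n − 1); a single
replicate reports its SD as missing.

## Problem sizes

The test suite and analysis scripts run at desk scale by design: 50
rendered cells of 128×128×50 voxels for the detection benchmark, 500
cells for the mixture fit, 20 replicates of 1200-point patterns for the
nanoscale checks, 10 000 replicates for the type-I calibration. These
sizes make every statistical band in the tests meaningful while keeping a
full run in minutes on one CPU.

## Known limitations

* The MSER stability parameters and seed-prominence threshold are stated
  defaults, tuned to the synthetic image model, not fitted to any
  microscope's data.
* The binarizer is intensity-threshold based and will undersegment dim or
  overlapping nuclei that a trained network would separate; the plug-in
  mask interface exists for exactly that case.
* Distance-frequency curves carry uncorrected edge effects; comparisons
  are therefore only valid between patterns observed in identical regions.
* The Poisson mixture assumes exactly two count components; S-phase cells,
  which interpolate between 2N and 4N, are not modelled.
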