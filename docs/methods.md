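# Methods

## Problem and model

A fragment of a beetle elytron is an RGB raster crop of a microscope image.
The identification model is a two-stage pattern-recognition pipeline:
hand-crafted appearance descriptors (global, summarizing the whole
fragment; local, averaged over interest-point windows) followed by a
shallow feed-forward neural network over the z-scored descriptor vector.
The unit of classification is the fragment; the unit of generalization is
the specimen, which is why cross-validation holds out whole specimens.

## Preprocessing

* Gaussian low-pass: the "variance = 2" parameter is interpreted as
  σ² = 2 (σ = √2).  The 10×10 window has no centre pixel; the kernel is
  sampled at half-integer offsets (−4.5 … +4.5) and normalized to sum 1,
  preserving symmetry at the stated even size.  Integer images are rounded
  back to their dtype, so direct-convolution comparisons are exact to one
  intensity level.
* Adaptive equalization: CLAHE (`skimage.exposure.equalize_adapthist`) on
  the luminance channel with an 8×8 tile grid and clip limit 0.01 (both
  config-exposed; no values are prescribed for them).  The luminance gain
  is transferred back to RGB multiplicatively so chrominance ratios are
  preserved and downstream colour descriptors see unequalized chroma.
  Colour-vs-luminance equalization is a genuinely open choice; per-channel
  equalization would distort the colour histograms that carry species
  signal.
* Order: smooth, then equalize.

## Segmentation

The histogram mask smooths the 256-bin intensity histogram with a 1-D
Gaussian whose *variance* equals the mean spacing of adjacent strict local
maxima of the raw histogram, then thresholds at the minimum valley between
the two highest smoothed peaks.  Two guards handle degenerate cases: the
second peak must lie at least 2σ bins from the first (otherwise twin
sub-peaks of one noisy mode would masquerade as the two modes), and a
unimodal smoothed histogram falls back to Otsu with a warning.  Which side
of the threshold is foreground is decided by whichever peak is closer to
the centre-ROI reference intensity, since the elytron is centred by
acquisition.

The colour mask accepts pixels within Euclidean RGB distance 60 (of
255·√3 ≈ 442 maximum; config-exposed) of a reference vector computed as
the 10-bin bin-weighted mean of the centred (2 % × 2 %) region of interest.
Masks are cleaned by hole filling and opening with a disk of radius 5
(config-exposed) and intersected.  One robustness guard is ours: if the
intersection keeps less than half of the cleaned histogram mask, the
centred ROI almost surely sampled a dark pattern object instead of the
cuticle base colour, and the histogram mask alone is used (with a
warning).  This failure mode occurs on real renders whenever a hole or
groove covers the image centre.

Fragment simulation draws widths and heights uniformly on 300–2500 px
(clipped to the image dimensions, logged) and accepts a rectangle when at
least 80 % of its pixels are foreground; whether the original protocol
required full containment is unknowable from its description, and a curved
elytron admits no large fully-contained rectangles.  Rejection sampling is
capped at 10,000 tries per fragment.

## Global descriptors (210)

* Statistical (13): mean and standard deviation on the raw [0, 255] scale;
  uniformity Σp², entropy −Σp·log₂p (bits), smoothness 1 − 1/(1 + σ²_z)
  and third moment Σ(z − m)³p computed from the 256-bin normalized
  histogram with intensities rescaled to [0, 1] (the standard
  texture-analysis convention); 7 Hu moment invariants of the intensity
  image.
* Radial spectra (80): fragments are bilinearly resampled to 256×256 so
  that radii are commensurate across fragment sizes — radii on raw-size
  fragments would conflate scale with frequency content, and the cap at
  r = 80 presumes a fixed grid.  The centred FFT magnitude is summed over
  integer-rounded radii 1…80; the dc term is excluded.
* Colour (30): 10 bins per channel over [0, 256), each channel normalized
  to sum 1.
* Gabor (19): complex kernels with λ = 8 px, σ = 4, γ = 0.5, ψ = 0 on a
  31×31 grid (none of these are prescribed; all config-exposed), six
  orientations 0°…150° in 30° steps with x′ along image columns, so θ = 0
  responds to vertical stripes.  Convolution is FFT-based with
  reflect padding (one image transform per fragment, one kernel transform
  per orientation).  Sum, mean and standard deviation are taken on the
  response *magnitude* — the signed real part oscillates around zero and
  its sum is uninformative — plus the angle of maximal summed response.
* Key objects (68): DoG with σ₁² = 100, σ₂² = 1, kernels truncated at 3σ.
  Both polarities (small-minus-large blur and the reverse) are min–max
  rescaled to [0, 255] so that Otsu thresholds of the DoG image and of the
  grayscale original are commensurate; the binarization threshold is their
  mean.  Connected components use 8-connectivity without border exclusion;
  object size is the component pixel count.  Per polarity: 30-bin RGB
  histogram over object pixels, number density (objects per pixel), area
  density, mean and median object size; all 34 entries zero when no
  objects are found.

## Local descriptors (415)

Harris corners (k = 0.04) are thresholded at 10⁻⁴ of the maximum response.
A relative threshold of 10⁻² keeps essentially nothing on textured
fragments — the Harris response scales like the fourth power of the local
gradient, so one strong corner suppresses all pattern corners — while
10⁻⁴ yields the few-hundred pre-refinement detections the method expects.

Refinement applies two stated rules in sequence, which we reconcile as
follows.  First, density rejection: per-tile (101×101) point counts are
collected over *occupied* tiles and points in tiles exceeding 2× the 25 %
truncated mean are dropped (an upper cap only — the rejection motive is
dense false corners in peak-noise areas).  Counting empty tiles would
drive the truncated mean to zero on sparse images and reject everything.
Second, merging: survivors are dilated with a disk of radius 4, connected
components are reduced to centroids, and centroids are agglomeratively
merged (closest pair first, replaced by their mean) until every pair is at
least 15 px apart.  The dilation rule alone merges only ≤ 9-px gaps and
the 15-px rule alone ignores component structure; applying both honours
each stated parameter.

Each window is 101×101 on the colour-gradient edge image (per-channel
Sobel derivatives; magnitude is the Euclidean norm over the six channel
derivatives, rescaled to [0, 255]).  The 5×20 = 100 < 101 mismatch is
resolved by describing the central 100×100 (the window's last row and
column are dropped), keeping cells exactly 20×20.  Per cell: mean,
population variance, and the row-sum and column-sum profiles (sums, not
means) linearly interpolated at 7 equally spaced nodes (positions 19i/6,
i = 0…6, of the 20-sample profile).  Projections are computed on edge
magnitudes, since the window is constructed from the edge image.  The
window's RGB histogram uses 5 bins per channel.  Windows overhanging the
fragment border are reflect-padded (a `skip` mode is available); small
fragments would otherwise lose all their points.  The fragment vector is
the unweighted mean over points, with the point count recorded; zero
refined points yields a zero vector and a warning.

## Classification

Normalization is z-scoring (min–max available), fitted on training rows
only; zero-variance columns are flagged and mapped to 0.  The network is
`sklearn` MLP with hidden layers (50, 50), logistic activation, softmax
output and cross-entropy loss, trained by adam with
`learning_rate_init = 0.01` (config-exposed; the faster rate shortens
training without hurting the recovered accuracy).  The 70:20:10 division
is realized as a held-out 10 % monitored subset (scored into
`monitor_accuracy_`), a 20 % validation set and a 70 % gradient set.

Early stopping monitors the validation cross-entropy **loss**, one epoch
at a time, halting after 6 epochs (config-exposed) without an improvement
larger than 10⁻⁴ and restoring the weights of the strict validation-loss
minimum.  The distinction from accuracy-based stopping is not cosmetic:
validation rows are fragments of *training* specimens, so validation
accuracy saturates within a handful of epochs while the loss — and
generalization to unseen specimens — keeps improving; stopping on the
accuracy plateau leaves the network undertrained (on a hard synthetic
collection, 0.67 LOSO accuracy versus 0.91 for a fully converged linear
model, recovered to 0.87 by loss-monitored stopping).

Ties in the argmax prediction break toward the lowest class index.
Accuracy is fragment-level.  LOSO-CV draws one specimen per species per
round (independently across rounds), asserts train/test specimen
disjointness every round, and reports across-round sample standard
deviations.

## Feature selection

mRMR discretizes features ternary at ±1σ (the classic convention;
equal-frequency binning available), ranks greedily by
I(f; c) − mean I(f; fᵢ) (MID) or I(f; c) / max(ε, mean I(f; fᵢ)) (MIQ,
ε = 10⁻¹²), with ties broken by column index.  Mutual information is
computed exactly from the joint empirical histogram, in bits.  CFS uses
symmetric uncertainty for both feature–class and feature–feature
correlation and best-first search with a stale limit of 5 non-improving
expansions; note that backward search from very wide matrices is
quadratic per expansion and is intended for subsets of at most a few
hundred features.

## Synthetic data

The generator renders what the pipeline consumes: an elliptical elytron on
a plain background, species-specific base colour with smooth colour
jitter, objects of the four pattern categories drawn as anti-aliased
primitives (hairs: short oriented segments; holes: filled darker disks;
lines: long grooves; unit shapes: period-snapped squares and disks),
defocus increasing from the elytron centre to its border (curvature blur),
salt noise (default rate 0.002) and a per-image contrast gain drawn from
0.9–1.1.  It does **not** model grinding damage beyond random cropping,
specular highlights, 3-D perspective, or photorealistic cuticle
microstructure; passing tests therefore demonstrate that the pipeline
recovers the constructed species signal under realistic noise, not that it
attains any particular accuracy on real microscope collections.

The four-species recovery benchmark instantiates one species per pattern
category at a 480×640 canvas, 3 specimens per species and 20 fragments per
specimen, with species parameters chosen once so that between-species
contrasts (base-colour distance, key-object statistics) clearly exceed the
generator's within-species variation — the benchmark is a separability-
by-construction recovery test.  Accuracy still varies across rendered
collections (0.86–0.99 over collection seeds): with only three specimens
per species, an unlucky draw of per-specimen contrast gains can push two
species' equalized appearances together, which is precisely the
specimen-scarcity regime the method operates in.  Species 1 (hairs) and 2 (holes) share a
base colour and differ only in key objects, providing the pair on which
local features are compared against global features without the
key-object block.  The 15-species reference-scale collection used for the
dataset-assembly checks is rendered at 600×800 (fragment sizes clip to
the canvas per the stated clipping rule); its per-species pattern
parameters are deterministic illustrative stand-ins, as no quantitative
per-species parameters exist to calibrate against.

## Numerical notes and limitations

* All randomness flows through `numpy` `SeedSequence` children of a single
  root seed; rendering, fragment sampling, training and CV are bit-stable
  for a fixed seed.
* Radial binning rounds √(u² + v²) to the nearest integer on the centred
  frequency grid.
* Discrete morphology is not exactly idempotent on rasterized shapes:
  opening an ellipse with a disk may flip a thin boundary band.
* The density-rejection tile grid is anchored at the image origin; points
  near tile borders can change tiles under small translations.
* Real-collection accuracies cannot be reproduced here: the original
  microscope images are not distributed, and the synthetic generator is
  not calibrated to them.
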