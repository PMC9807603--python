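# Methods

## The segmentation problem

A day-5/6 human blastocyst photographed at its equatorial focal plane shows
five regions: the culture-medium background (BG), the zona pellucida (ZP, a
thin bright semi-transparent annulus), the trophectoderm (TE, a granular cell
ring), the blastocoel (BC, a smooth dark cavity) and, when visible, the inner
cell mass (ICM, a granular blob attached to the inside of the TE).  As the
embryo develops it expands within the ZP, then herniates through a breach
(hatching, the "figure-of-eight" silhouette), and finally leaves the ZP
remnant entirely (hatched).  `blastoseg` assigns every pixel of a grayscale
micrograph to exactly one of the five regions across all three stages.

## Pipeline

1. **Localisation and crop.** The embryo is found as the largest connected
   high-texture component: a 7×7 local-variance map is thresholded with
   Otsu's method, morphologically closed (disk radius 5, which merges the
   TE ring with the high-gradient rings along the ZP borders), and the
   largest component's bounding box plus a 5 % margin is cropped.  Boxes are
   0-based and half-open.  A degenerate (zero-variance) image falls back to
   the full-image box with a warning.  Externally supplied boxes (from a
   manifest or any learned detector) can be passed through a hook, so the
   classical detector is swappable.
2. **Physical scale.** The crop is resampled bilinearly by
   `alpha = pixel_size_um / 1.0` so that one pixel corresponds to one
   micrometre; this makes embryos from different magnifications commensurate.
3. **Brightness standardisation.** On intensities scaled to [0, 1], while
   the image median lies outside [0.45, 0.75] the image is raised to the
   power `gamma = 1.25 * median + 0.375`, for at most three transformations.
   For a median below the band, `gamma < 0.9375 < 1`, so one transform
   strictly brightens any non-constant image; above the band,
   `gamma > 1.3125` darkens it.  The loop therefore drives the median
   monotonically towards the band and always terminates.
4. **Min–max normalisation** to [0, 255] (a constant image maps to zeros
   with a warning rather than an error, so batch runs never abort).

   The published protocol fixes gamma-before-min-max; it does not say whether
   rescaling precedes gamma correction.  Rescaling is placed first so the
   median is computed at the standard scale, consistent with the robustness
   protocol in which geometric perturbations act after interpolation.
5. **Texture features.** 21 filter operations × 41 5×5 texture kernels give
   an 861-component descriptor per pixel (true convolution, reflected
   borders).  The filter bank spans the canonical texture operators
   (identity, local entropy, Gaussian blurs σ ∈ {1, 2, 4},
   difference-of-Gaussians, Laplacian, Laplacian-of-Gaussian, Sobel-x/y/
   magnitude, Scharr magnitude, medians 3×3/5×5, local standard deviation,
   local range, unsharp mask, top-/bottom-hat, CLAHE); the kernel set is the
   25 Laws texture-energy kernels plus the averaging kernel, 8 oriented step
   kernels and 7 centre-surround ring kernels.  The exact operator lists
   behind the published counts are not public, so both registries are
   explicit, versioned stand-ins; checkpoints record the registry versions
   and refuse to run against different ones.
6. **Per-pixel classification.** For training, at most 50 pixels per present
   region are sampled per micrograph, uniformly without replacement (absent
   regions contribute nothing, so class balance follows region presence).
   Features are z-scored with training-set statistics.  The classifier is a
   fully connected network — three hidden layers of 400 rectified-linear
   units, softmax over five classes — trained with Adam on categorical
   cross-entropy, a 10 % validation split, learning-rate reduction on a
   validation-loss plateau (factor 0.5, patience 25) and early stopping
   (patience 60, min delta 0.001), epoch cap 500.  Hidden activation and the
   z-scoring are this package's choices where the published description is
   silent.
7. **Refinement.** The five hard binary maps from the arg-max of the
   classifier are fed to a convolutional encoder–decoder (three 3×3
   conv + max-pool stages with widths 16/32/64, then four conv with three
   nearest-neighbour up-samplings, sigmoid output) trained with mean squared
   error and RMSprop against the one-hot ground truth, 10 % validation
   split, epoch cap 100, with the same callback settings transferred from
   the classifier (the callbacks are named for this stage but their settings
   are not published).  Channel widths, kernel sizes and activations are
   likewise documented stand-ins: only the layer counts, loss and optimiser
   are fixed by the protocol.  Inputs are reflect-padded, centred, to a
   multiple of 8 (training pads all pairs to the batch maximum so they share
   a grid) and cropped back, so refinement never changes spatial size.
   Arg-max ties are broken by the fixed priority BG > ZP > TE > BC > ICM
   (outermost to innermost), which coincides with ascending label code.

Both networks run on a compact in-package NumPy backend (`_nn.py`: dense and
3×3 convolution layers, 2×2 max-pool, nearest up-sampling, Adam, RMSprop,
Keras-style early-stopping/LR-reduction callbacks), sized so the whole
pipeline trains in minutes on a single CPU and is bit-reproducible under a
seed.

## Evaluation

The Dice similarity coefficient `DSC = 2|A∩B| / (|A|+|B|)` is computed per
region one-vs-rest.  When ground truth and prediction are both empty the DSC
is defined as 1 (agreement on absence; configurable) — the opposite case
(ICM predicted where none was marked) scores 0, which is what depresses the
ICM column on ICM-free images.  The "All" statistic is the micro-average:
the five-way label-agreement fraction over all pixels.  `stage_report`
aggregates mean ± SD per region × stage group and adds an ICM2 row
restricted to images with a marked ICM.  Confusion-derived metrics
(sensitivity, specificity, precision, accuracy) report `None` rather than 0
when a denominator vanishes.

The robustness analysis segments fourteen variants of each image — rotations
90/180/270°, flips H/V/HV, additive brightness ±25/±50/±75/±100 — and
compares each variant's segmentation with the unperturbed one.  Geometric
variants are applied to the pre-processed image and inverted exactly
(right-angle rotations and flips are grid bijections that commute with the
pixelwise brightness standardisation); brightness deltas are added to the
cropped image and then flow through rescaling, gamma and min–max, so the
standardisation loop absorbs part of the perturbation — which is precisely
the mechanism being audited.

## The phantom generator

Phantoms give the pipeline exact, free ground truth.  Geometry: a jittered
circular embryo (TE ring of configurable thickness inside a ZP annulus, BC
interior, optional ICM blob attached to the inner TE wall); hatching adds an
angular ZP breach with a herniated lobe whose radius is bisected so a
requested fraction of cell mass lies outside the ZP (capped by the field of
view); hatched renders an emptied ZP remnant plus a displaced embryo body
whose offset is bisected the same way (fraction ≥ 0.5 by definition of the
stage).  Intensity: base levels BG 70 < BC 95 < TE 135 ≈ ICM 145 ≈ ZP 150
(8-bit), per-region granular texture (low-pass-filtered noise, amplitudes
35/30 for TE/ICM), a semi-transparent ZP (α = 0.8 blend with the local
background), a linear illumination gradient, an optics blur of σ = 0.7 px
and Gaussian sensor noise of SD 8.  TE, ICM and ZP overlap in mean intensity
on purpose: only texture separates them, so the per-pixel classifier makes
realistic mistakes and the refiner has genuine structure to restore.

`generate_dataset` reproduces the shape of a clinical collection: stage mix
63/34/3 % (expansion/hatching/hatched), 18 % of images without a marked ICM,
a 90/10 train/test split, deterministic under one seed.

What phantoms do **not** model: pipette and debris artifacts, collapsed
embryos, defocus of the ICM, vignetting, multiple embryos per frame, or the
full optical texture of real cells.  Passing the phantom benchmark therefore
demonstrates that the pipeline's machinery (standardisation, features,
classifier, refiner, metrics) works end to end and that refinement adds
accuracy on this family of images; it does not certify clinical performance.

## Benchmark sizes and numerical choices

The standard benchmark (`blastoseg.benchmark.run_phantom_benchmark`) trains
on 40 phantoms and evaluates on 12 held-out phantoms at 128 px with the
classifier capped at 60 epochs and the refiner at 30, and runs the
robustness analysis on 3 held-out images — sizes chosen so a full run takes
a few minutes on one CPU while exercising every stage; the augmentation
multiplier is 1 there because phantom variability is already controlled by
the generator.  Typical results at these sizes: all-region mean DSC ≈ 0.83
before refinement and ≈ 0.93 after; ICM is the weakest region, and
large brightness shifts degrade the segmentation more than small ones.

Other numerical choices: float32 network arithmetic; He initialisation;
validation splits are taken from a seeded permutation; early stopping
restores the best-validation weights; the refiner's learning rate is 1e-3 by
default; z-scoring guards against zero variance by substituting unit scale;
`minmax_normalize` clips at [0, 255] against floating-point overshoot.

## Known limitations

- The 21-filter and 41-kernel registries are canonical stand-ins, not the
  original (unpublished) operator lists; absolute DSC values on real data
  will depend on them.
- The classical variance-based detector assumes one embryo and a plain
  background; frames with instruments or multiple embryos need an external
  box.
- The refiner has no skip connections (by design), so its boundary precision
  is limited by the 8× bottleneck.
- Collapsed-embryo morphology is not generated and not tested.
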