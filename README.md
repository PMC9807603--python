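# blastoseg

Automatic segmentation of human blastocyst micrographs into their five
regions — background (BG), zona pellucida (ZP), trophectoderm (TE),
blastocoel (BC) and inner cell mass (ICM) — across the expansion, hatching
and hatched developmental stages.

Morphological grading of blastocysts for IVF embryo selection is subjective
and observer-dependent.  Per-region segmentation turns a micrograph into
quantitative, explainable measurements, but is hard because the regions'
appearance changes drastically as the embryo expands, breaches the zona
pellucida and finally leaves it.  `blastoseg` implements a two-stage hybrid
pipeline for this problem, plus the evaluation and robustness protocols that
go with it, and a synthetic phantom generator that makes everything
trainable and testable without any clinical data.

## Method

1. **Pre-processing.**  The embryo is localised (local-variance detector,
   bounding box + 5 % margin), cropped, resampled bilinearly so one pixel is
   one micrometre, brightness-standardised by a median-driven gamma loop —
   while the median m of the [0, 1]-scaled image is outside [0.45, 0.75],
   apply out = in^γ with γ = 1.25·m + 0.375, at most three times — and
   min–max normalised to [0, 255].
2. **Per-pixel texture classification.**  Each pixel gets an 861-dimensional
   descriptor (21 filter operations × 41 5×5 texture kernels, Laws-style),
   classified into the five regions by a fully connected network (3 × 400
   ReLU units, softmax; Adam, categorical cross-entropy, early stopping and
   LR reduction on validation loss).  Training samples 50 pixels per present
   region per image.
3. **Refinement.**  The five binary maps S from the classifier's arg-max are
   mapped to refined region maps by a convolutional encoder–decoder
   (3 conv + 3 max-pool / 4 conv + 3 up-sampling; MSE loss, RMSprop), which
   injects the embryo's topology (ZP outermost, TE between ZP and BC/ICM,
   ICM inside the cavity) and removes scattered misclassifications.

Evaluation uses the Dice similarity coefficient,
DSC(A, B) = 2·|A∩B| / (|A| + |B|), per region and micro-averaged over all
pixels ("All"), aggregated per developmental stage; robustness is assessed
by re-segmenting fourteen standard perturbations of each image (rotations,
flips, brightness ±25…±100) and comparing against the unperturbed result.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from blastoseg.benchmark import run_phantom_benchmark

res = run_phantom_benchmark(seed=1)   # ~2 minutes on one CPU
print(f"all-region mean DSC before refinement: {res.mean_all_dsc_before:.3f}")
print(f"all-region mean DSC after refinement:  {res.mean_all_dsc_after:.3f}")
print(res.sensitivity.loc[["25B", "-25B", "100B", "-100B"], "All"].round(3))
```

This generates 52 phantoms (40 train / 12 held out, 128 px, with the
clinical stage imbalance and 18 % ICM-free images), trains both models and
prints:

```
all-region mean DSC before refinement: 0.832
all-region mean DSC after refinement:  0.932
25B     0.922
-25B    0.967
100B    0.814
-100B   0.819
```

Refinement lifts the mean all-region DSC (here 0.832 → 0.932): the
encoder–decoder restores the ring topology that a purely local texture
classifier cannot see.  The robustness rows show mild brightness shifts
(±25) costing almost nothing while extreme shifts (±100) degrade the overlap
— the gamma loop absorbs small perturbations but clipping at ±100 destroys
texture.  ICM is consistently the hardest region, as expected for a
structure that texture alone barely distinguishes from the TE.

The same workflow is available from the shell:

```bash
blastoseg phantom --out data/ --n 52 --seed 1 --image-size 128
blastoseg train --manifest data/manifest.csv --out run/ --seed 1 \
    --epochs-classifier 60 --epochs-refiner 30
blastoseg segment --manifest data/manifest.csv --model-dir run/ --out seg/
blastoseg sensitivity --manifest data/manifest.csv --model-dir run/ \
    --out sens.csv --n-images 3
```

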