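"""Micrograph pre-processing: localisation, crop, brightness and scale
standardisation.

The pipeline is: detect the bounding box of the embryo, crop, resample to a
common physical scale of one micrometre per pixel (bilinear), run the
median-driven gamma-correction loop on intensities scaled to [0, 1], and
finally min–max normalise back to [0, 255].

The gamma loop adjusts overall image brightness so that the median intensity
lands in [0.45, 0.75]: while the median is outside that band, the image is
raised to the power ``gamma = 1.25 * median + 0.375`` (a median below the band
gives gamma < 1 and brightens; above the band gives gamma > 1 and darkens),
for at most three transformations.

The embryo detector is classical: a local-variance map is thresholded with
Otsu's method, closed morphologically, and the largest connected component's
bounding box (plus a configurable margin, default 5 %) is returned.  A hook
accepts externally supplied boxes so a learned detector can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.transform import resize

__all__ = [
    "Micrograph",
    "BoundingBox",
    "GammaLoopResult",
    "detect_bounding_box",
    "crop",
    "gamma_correct",
    "minmax_normalize",
    "rescale_to_physical",
    "preprocess_pipeline",
    "preprocess_mask",
]

GAMMA_MEDIAN_LOW = 0.45
GAMMA_MEDIAN_HIGH = 0.75
GAMMA_MAX_TRANSFORMS = 3
MIN_IMAGE_SIZE = 32


@dataclass(frozen=True)
class Micrograph:
    """A grayscale micrograph with physical pixel size and optional stage."""

    intensities: np.ndarray          # 2-D, 8-bit range [0, 255]
    pixel_size_um: float = 1.0
    stage: str | None = None

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        if min(arr.shape) < MIN_IMAGE_SIZE:
            raise ValueError(f"micrograph must be at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open axis-aligned box [x1, x2) x [y1, y2)."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box: ({self.x1},{self.y1})-({self.x2},{self.y2})")

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for name, value, limit in (("x1", self.x1, w), ("x2", self.x2, w),
                                   ("y1", self.y1, h), ("y2", self.y2, h)):
            lo = 0
            hi = limit if name in ("x2", "y2") else limit - 1
            if not (lo <= value <= hi):
                raise ValueError(f"box coordinate {name}={value} outside image of shape {shape}")


@dataclass(frozen=True)
class GammaLoopResult:
    image: np.ndarray                # corrected intensities in [0, 1]
    n_transforms: int
    gammas_applied: tuple[float, ...]
    final_median: float


def detect_bounding_box(image: np.ndarray, *, margin: float = 0.05,
                        window: int = 7, closing_radius: int = 5) -> BoundingBox:
    """Locate the embryo as the largest connected high-texture component.

    Falls back to the full-image box (with a warning) when the image has no
    intensity variance.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    mean = ndi.uniform_filter(img, window)
    sq_mean = ndi.uniform_filter(img * img, window)
    variance = np.clip(sq_mean - mean * mean, 0.0, None)
    if variance.max() <= 1e-12:
        warnings.warn("image has no intensity variance; returning full-image box")
        return BoundingBox(0, 0, img.shape[1], img.shape[0])

    thresh = threshold_otsu(variance)
    binary = ndi.binary_closing(variance > thresh, structure=disk(closing_radius))
    lab, n = ndi.label(binary)
    if n == 0:
        warnings.warn("no textured component found; returning full-image box")
        return BoundingBox(0, 0, img.shape[1], img.shape[0])
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    ys, xs = np.nonzero(lab == largest)
    y1, y2 = int(ys.min()), int(ys.max()) + 1
    x1, x2 = int(xs.min()), int(xs.max()) + 1
    my = int(round(margin * (y2 - y1)))
    mx = int(round(margin * (x2 - x1)))
    return BoundingBox(max(0, x1 - mx), max(0, y1 - my),
                       min(img.shape[1], x2 + mx), min(img.shape[0], y2 + my))


def crop(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop to the half-open box; pixel values are untouched."""
    image = np.asarray(image)
    box.validate_for(image.shape[:2])
    return image[box.y1:box.y2, box.x1:box.x2].copy()


def gamma_correct(image: np.ndarray) -> GammaLoopResult:
    """Median-driven gamma-correction loop on intensities in [0, 1].

    (i) compute the median of all pixels; (ii) stop if it lies in
    [0.45, 0.75]; (iii) otherwise apply ``out = in ** (1.25 * median + 0.375)``;
    (iv) recompute the median and repeat — capped at three transformations.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("gamma_correct expects intensities in [0, 1]; pre-normalise first")
    gammas: list[float] = []
    median = float(np.median(img))
    while not (GAMMA_MEDIAN_LOW <= median <= GAMMA_MEDIAN_HIGH) \
            and len(gammas) < GAMMA_MAX_TRANSFORMS:
        gamma = 1.25 * median + 0.375
        img = np.power(img, gamma)
        gammas.append(gamma)
        median = float(np.median(img))
    return GammaLoopResult(image=img, n_transforms=len(gammas),
                           gammas_applied=tuple(gammas), final_median=median)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Linearly map the intensity range onto [0, 255].

    A constant image maps to all zeros (with a warning) so batch runs never
    abort on degenerate inputs.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        warnings.warn("constant image: min-max normalization returns all zeros")
        return np.zeros_like(img)
    return np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def rescale_to_physical(image: np.ndarray, pixel_size_um: float, *,
                        order: int = 1) -> np.ndarray:
    """Bilinearly resample so that one pixel corresponds to one micrometre.

    The scale factor is ``alpha = pixel_size_um / 1.0``; output dimensions are
    ``round(input * alpha)``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(image, dtype=np.float64)
    alpha = pixel_size_um / 1.0
    out_shape = (int(round(img.shape[0] * alpha)), int(round(img.shape[1] * alpha)))
    if min(out_shape) < MIN_IMAGE_SIZE:
        raise ValueError(
            f"physical rescaling would produce {out_shape}, below the "
            f"{MIN_IMAGE_SIZE}-pixel minimum")
    if out_shape == img.shape:
        return img.copy()
    return resize(img, out_shape, order=order, anti_aliasing=False,
                  preserve_range=True)


def preprocess_pipeline(m: Micrograph, *, box: BoundingBox | None = None
                        ) -> tuple[np.ndarray, dict]:
    """Run detect → crop → rescale → gamma-correct → min–max normalise.

    Returns the pre-processed intensity grid in [0, 255] (float) and a
    provenance record with the box, scale factor, gamma-loop diagnostics and
    output shape.  ``box`` overrides the built-in detector (hook for
    externally supplied boxes, e.g. from a manifest or a learned detector).
    """
    img = np.asarray(m.intensities, dtype=np.float64)
    if box is None:
        box = detect_bounding_box(img)
    cropped = crop(img, box)
    scaled = rescale_to_physical(cropped, m.pixel_size_um)
    gamma = gamma_correct(np.clip(scaled / 255.0, 0.0, 1.0))
    out = minmax_normalize(gamma.image)
    provenance = {
        "box": [box.x1, box.y1, box.x2, box.y2],
        "alpha": m.pixel_size_um / 1.0,
        "n_gamma_transforms": gamma.n_transforms,
        "gammas_applied": list(gamma.gammas_applied),
        "final_median": gamma.final_median,
        "output_shape": list(out.shape),
    }
    return out, provenance


def preprocess_mask(labels: np.ndarray, box: BoundingBox, pixel_size_um: float
                    ) -> np.ndarray:
    """Apply the geometric part of the pipeline (crop + rescale) to a label
    map with nearest-neighbour interpolation, keeping codes intact."""
    cropped = crop(np.asarray(labels), box)
    alpha = pixel_size_um / 1.0
    out_shape = (int(round(cropped.shape[0] * alpha)), int(round(cropped.shape[1] * alpha)))
    if out_shape == cropped.shape:
        return cropped.astype(np.uint8)
    out = resize(cropped.astype(np.float64), out_shape, order=0,
                 anti_aliasing=False, preserve_range=True)
    return np.round(out).astype(np.uint8)
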