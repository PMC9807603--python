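"""Training-set augmentation and the fourteen-variant sensitivity transforms.

Two distinct brightness regimes exist on purpose: training augmentation uses
multiplicative factors {0.8, 0.9, 1.0, 1.1, 1.2}, while the robustness
(sensitivity) analysis uses additive deltas {±25, ±50, ±75, ±100} on the
8-bit scale.  Geometric transforms (right-angle rotations and flips) are exact
bijections on the pixel grid and are applied identically to image and mask;
brightness changes affect the image only and saturate at [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransformSpec",
    "ROTATIONS",
    "FLIPS",
    "SENSITIVITY_DELTAS",
    "TRAINING_BRIGHTNESS_FACTORS",
    "apply_geometric",
    "invert_geometric",
    "apply_brightness_delta",
    "augment_training_set",
    "sensitivity_transforms",
]

ROTATIONS = (90, 180, 270)
FLIPS = ("H", "V", "HV")
SENSITIVITY_DELTAS = (-100, -75, -50, -25, 25, 50, 75, 100)
TRAINING_BRIGHTNESS_FACTORS = (0.8, 0.9, 1.0, 1.1, 1.2)


@dataclass(frozen=True)
class TransformSpec:
    """One elementary transform: exactly one kind is active."""

    kind: str                          # 'rotation' | 'flip' | 'brightness'
    rotation_deg: int = 0
    flip: str | None = None
    brightness_delta: int = 0          # additive, sensitivity regime
    brightness_factor: float = 1.0     # multiplicative, training regime

    def __post_init__(self):
        if self.kind not in ("rotation", "flip", "brightness"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rotation" and self.rotation_deg not in (0, 90, 180, 270):
            raise ValueError("rotation_deg must be one of 0, 90, 180, 270")
        if self.kind == "flip" and self.flip not in FLIPS:
            raise ValueError(f"flip must be one of {FLIPS}")


def _rotate(arr: np.ndarray, deg: int) -> np.ndarray:
    return np.rot90(arr, k=(deg // 90) % 4)


def _flip(arr: np.ndarray, mode: str) -> np.ndarray:
    if mode == "H":
        return np.fliplr(arr)
    if mode == "V":
        return np.flipud(arr)
    if mode == "HV":
        return np.flipud(np.fliplr(arr))
    raise ValueError(f"unknown flip mode {mode!r}")


def apply_geometric(label: str, arr: np.ndarray) -> np.ndarray:
    """Apply the geometric transform named by a sensitivity label
    ('90D', '180D', '270D', 'H-', 'V-', 'HV-')."""
    if label.endswith("D"):
        return _rotate(arr, int(label[:-1]))
    if label.endswith("-"):
        return _flip(arr, label[:-1])
    raise ValueError(f"not a geometric transform label: {label!r}")


def invert_geometric(label: str, arr: np.ndarray) -> np.ndarray:
    """Map a transformed grid back into the reference frame (exact inverse)."""
    if label.endswith("D"):
        return np.rot90(arr, k=-(int(label[:-1]) // 90) % 4)
    if label.endswith("-"):
        return _flip(arr, label[:-1])       # flips are involutions
    raise ValueError(f"not a geometric transform label: {label!r}")


def apply_brightness_delta(image: np.ndarray, delta: float) -> np.ndarray:
    """Additive brightness change on the 8-bit scale, saturating at [0, 255]."""
    return np.clip(np.asarray(image, dtype=np.float64) + delta, 0.0, 255.0)


def apply_brightness_factor(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness change, saturating at [0, 255]."""
    return np.clip(np.asarray(image, dtype=np.float64) * factor, 0.0, 255.0)


def augment_training_set(images: list[np.ndarray], masks: list[np.ndarray],
                         k_per_image: int, seed: int = 0
                         ) -> tuple[list[np.ndarray], list[np.ndarray], list[dict]]:
    """Create ``k_per_image`` random variants of each image/mask pair.

    Each variant is a uniformly sampled combination of a brightness factor, a
    flip (or none) and a right-angle rotation, the geometric part applied
    identically to image and mask.  The identity combination
    ``(1.0, none, 0°)`` is a legitimate draw.  Returns augmented images, masks
    and a lineage record per output.
    """
    if k_per_image < 1:
        raise ValueError("k_per_image must be >= 1")
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired")
    rng = np.random.default_rng(seed)
    out_images, out_masks, lineage = [], [], []
    flip_choices = (None, "H", "V", "HV")
    for idx, (img, mask) in enumerate(zip(images, masks)):
        for _ in range(k_per_image):
            factor = TRAINING_BRIGHTNESS_FACTORS[rng.integers(len(TRAINING_BRIGHTNESS_FACTORS))]
            flip = flip_choices[rng.integers(len(flip_choices))]
            rot = int(rng.integers(4)) * 90
            a_img = apply_brightness_factor(img, factor)
            a_img = _rotate(a_img, rot)
            a_mask = _rotate(np.asarray(mask), rot)
            if flip is not None:
                a_img = _flip(a_img, flip)
                a_mask = _flip(a_mask, flip)
            out_images.append(a_img)
            out_masks.append(a_mask.copy())
            lineage.append({"source_index": idx, "brightness_factor": float(factor),
                            "flip": flip, "rotation_deg": rot})
    return out_images, out_masks, lineage


def sensitivity_transforms(image: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """The fourteen labelled robustness variants of one pre-processed image:
    three rotations, three flips and eight additive brightness changes."""
    image = np.asarray(image)
    variants: list[tuple[str, np.ndarray]] = []
    for deg in ROTATIONS:
        variants.append((f"{deg}D", _rotate(image, deg)))
    for mode in FLIPS:
        variants.append((f"{mode}-", _flip(image, mode)))
    for delta in SENSITIVITY_DELTAS:
        variants.append((f"{delta}B", apply_brightness_delta(image, delta)))
    return variants
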