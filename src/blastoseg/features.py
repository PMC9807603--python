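"""Per-pixel texture descriptors: 21 filter operations x 41 texture kernels.

Each pre-processed image is passed through a versioned bank of 21 image
filters (identity, local entropy, Gaussian blurs, difference-of-Gaussians,
Laplacian, Laplacian-of-Gaussian, Sobel/Scharr derivatives, medians, local
standard deviation and range, unsharp mask, morphological top-/bottom-hat and
local histogram equalisation).  Every filtered image is then convolved with a
versioned set of 41 two-dimensional 5x5 texture kernels — the 25 Laws
texture-energy kernels (outer products of the level/edge/spot/wave/ripple
vectors), the averaging kernel, 8 oriented step kernels and 7 centre-surround
ring kernels — yielding a feature vector of 21 x 41 = 861 components per
pixel.  All convolutions use reflected borders, and the whole extraction is
pure: no randomness, no state, stable channel order.

Both registries are explicit, versioned stand-ins: the exact operator lists
behind the published counts are not public, so the bank and kernel set are
config-level registries that can be swapped without touching the rest of the
pipeline (checkpoints record the versions they were trained under).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.filters import scharr
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import disk

__all__ = [
    "FilterBank",
    "KernelSet",
    "FeatureStack",
    "build_filter_bank",
    "build_kernel_set",
    "extract_features",
    "N_FILTERS",
    "N_KERNELS",
    "N_FEATURES",
]

N_FILTERS = 21
N_KERNELS = 41
N_FEATURES = N_FILTERS * N_KERNELS

FILTER_BANK_VERSION = "fb-1"
KERNEL_SET_VERSION = "ks-1"


@dataclass(frozen=True)
class FilterBank:
    names: tuple[str, ...]
    filters: tuple[Callable[[np.ndarray], np.ndarray], ...]
    version: str = FILTER_BANK_VERSION

    def __post_init__(self):
        if len(self.names) != len(self.filters):
            raise ValueError("names and filters must align")
        if len(self.filters) != N_FILTERS:
            raise ValueError(f"filter bank must hold exactly {N_FILTERS} filters")


@dataclass(frozen=True)
class KernelSet:
    names: tuple[str, ...]
    kernels: np.ndarray                  # (41, 5, 5)
    version: str = KERNEL_SET_VERSION

    def __post_init__(self):
        if self.kernels.shape != (N_KERNELS, 5, 5):
            raise ValueError(f"kernel set must be {N_KERNELS} kernels of size 5x5")
        if len(self.names) != N_KERNELS:
            raise ValueError("names and kernels must align")


@dataclass(frozen=True)
class FeatureStack:
    values: np.ndarray                   # (H, W, 861) float32
    feature_names: tuple[str, ...]
    bank_version: str
    kernel_version: str

    @property
    def depth(self) -> int:
        return self.values.shape[-1]


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

def _local_std(img: np.ndarray, size: int = 5) -> np.ndarray:
    mean = ndi.uniform_filter(img, size)
    sq = ndi.uniform_filter(img * img, size)
    return np.sqrt(np.clip(sq - mean * mean, 0.0, None))


def _local_range(img: np.ndarray, size: int = 5) -> np.ndarray:
    return ndi.maximum_filter(img, size) - ndi.minimum_filter(img, size)


def _entropy(img: np.ndarray) -> np.ndarray:
    as_u8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return rank_entropy(as_u8, disk(5)).astype(np.float64)


def _clahe(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img, dtype=np.float64)
    scaled = (img - lo) / (hi - lo)
    return exposure.equalize_adapthist(scaled, clip_limit=0.02) * 255.0


def build_filter_bank() -> FilterBank:
    """The default, versioned 21-filter registry."""
    g = ndi.gaussian_filter
    entries: list[tuple[str, Callable[[np.ndarray], np.ndarray]]] = [
        ("identity", lambda im: im.copy()),
        ("entropy_disk5", _entropy),
        ("gaussian_s1", lambda im: g(im, 1.0)),
        ("gaussian_s2", lambda im: g(im, 2.0)),
        ("gaussian_s4", lambda im: g(im, 4.0)),
        ("dog_1_2", lambda im: g(im, 1.0) - g(im, 2.0)),
        ("dog_2_4", lambda im: g(im, 2.0) - g(im, 4.0)),
        ("laplacian", ndi.laplace),
        ("log_s2", lambda im: ndi.gaussian_laplace(im, 2.0)),
        ("sobel_x", lambda im: ndi.sobel(im, axis=1)),
        ("sobel_y", lambda im: ndi.sobel(im, axis=0)),
        ("sobel_mag", lambda im: np.hypot(ndi.sobel(im, axis=1), ndi.sobel(im, axis=0))),
        ("scharr_mag", lambda im: scharr(im)),
        ("median_3", lambda im: ndi.median_filter(im, 3)),
        ("median_5", lambda im: ndi.median_filter(im, 5)),
        ("local_std_5", _local_std),
        ("local_range_5", _local_range),
        ("unsharp", lambda im: im + (im - g(im, 2.0))),
        ("tophat_disk5", lambda im: ndi.white_tophat(im, footprint=disk(5))),
        ("bottomhat_disk5", lambda im: ndi.black_tophat(im, footprint=disk(5))),
        ("clahe", _clahe),
    ]
    names, filters = zip(*entries)
    return FilterBank(names=names, filters=filters)


# ---------------------------------------------------------------------------
# kernel set
# ---------------------------------------------------------------------------

_LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),       # level
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),     # edge
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),     # spot
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),     # wave
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),     # ripple
}


def _oriented_step_kernels() -> list[tuple[str, np.ndarray]]:
    ii, jj = np.mgrid[0:5, 0:5]
    bases = {
        "step_0": np.sign(jj - 2.0),                  # left/right halves
        "step_90": np.sign(ii - 2.0),                 # top/bottom halves
        "step_45": np.sign((ii + jj) - 4.0),
        "step_135": np.sign((ii - jj) + 0.0),
    }
    out = []
    for name, k in bases.items():
        k = k / np.count_nonzero(k)
        out.append((f"{name}_p", k))
        out.append((f"{name}_n", -k))
    return out


def _ring_kernels() -> list[tuple[str, np.ndarray]]:
    r = np.hypot(*(np.mgrid[0:5, 0:5] - 2.0))
    center = (r < 0.5).astype(float)                  # 1 pixel
    ring1 = ((r >= 0.5) & (r < 1.9)).astype(float)    # 8 pixels
    ring2 = (r >= 1.9).astype(float)                  # 16 pixels
    c, r1, r2 = center, ring1 / 8.0, ring2 / 16.0
    kernels = [
        ("cs_center_ring1", c - r1),
        ("cs_center_ring2", c - r2),
        ("cs_ring1_ring2", r1 - r2),
        ("cs_inner_outer", (center + ring1) / 9.0 - r2),
        ("cs_center_all", c - (ring1 + ring2) / 24.0),
        ("cs_ring2_ring1", r2 - r1),
        ("cs_ring1_center", r1 - c),
    ]
    return kernels


def build_kernel_set() -> KernelSet:
    """The default, versioned 41-kernel registry (Laws energy kernels plus
    averaging, oriented step and centre-surround complements)."""
    entries: list[tuple[str, np.ndarray]] = []
    for a, va in _LAWS_VECTORS.items():
        for b, vb in _LAWS_VECTORS.items():
            entries.append((f"laws_{a}{b}", np.outer(va, vb)))
    entries.append(("average_5", np.full((5, 5), 1.0 / 25.0)))
    entries.extend(_oriented_step_kernels())
    entries.extend(_ring_kernels())
    names, kernels = zip(*entries)
    return KernelSet(names=names, kernels=np.stack(kernels).astype(np.float64))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_features(image: np.ndarray, bank: FilterBank | None = None,
                     kernels: KernelSet | None = None) -> FeatureStack:
    """Compute the (H, W, 861) texture feature stack of a pre-processed image.

    Channel ``(i-1) * 41 + (j-1)`` holds ``F_i(I) * k_j`` (true convolution,
    reflected borders).  Deterministic and stateless.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity grid")
    if min(img.shape) < 5:
        raise ValueError("image must be at least 5x5 for 5x5 texture kernels")
    bank = bank or build_filter_bank()
    kernels = kernels or build_kernel_set()

    h, w = img.shape
    values = np.empty((h, w, N_FEATURES), dtype=np.float32)
    names: list[str] = []
    ch = 0
    for fname, f in zip(bank.names, bank.filters):
        filtered = np.asarray(f(img), dtype=np.float64)
        for kname, k in zip(kernels.names, kernels.kernels):
            values[:, :, ch] = ndi.convolve(filtered, k, mode="reflect")
            names.append(f"{fname}*{kname}")
            ch += 1
    return FeatureStack(values=values, feature_names=tuple(names),
                        bank_version=bank.version, kernel_version=kernels.version)
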