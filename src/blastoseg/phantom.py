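"""Synthetic blastocyst phantoms with exact ground-truth region masks.

A phantom emulates the geometry of a day-5/6 blastocyst micrograph as seen at
the equatorial focal plane: a roughly circular embryo on a noisy culture-medium
background (BG), a thin bright semi-transparent zona pellucida annulus (ZP), a
granular trophectoderm cell ring (TE), a smooth dark blastocoel cavity (BC)
and an optional granular inner-cell-mass blob attached to the inside of the TE
(ICM).  Three developmental stages are modelled:

* ``expansion`` — the embryo is fully contained within an intact ZP;
* ``hatching`` — cell material herniates through an angular breach of the ZP,
  producing the characteristic "figure-of-eight" silhouette;
* ``hatched`` — most or all of the cell material lies outside the ZP remnant.

Masks are exact by construction (the label map is rasterised from the same
geometry that drives the rendering), which makes phantoms usable as ground
truth for training and for quantitative evaluation without any external data.

Intensity model: region base levels BG < BC < TE ≈ ICM ≈ ZP with per-region
granular texture (low-pass filtered noise), a linear background illumination
gradient, a small optics blur and additive Gaussian sensor noise.  The TE, ICM
and ZP overlap in mean intensity on purpose: they are only separable through
texture, which keeps the per-pixel classification problem non-trivial.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import dataio

__all__ = [
    "STAGES",
    "REGION_CODES",
    "REGION_NAMES",
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
]

STAGES = ("expansion", "hatching", "hatched")

#: label codes of the five mutually exclusive regions
REGION_CODES = {"BG": 0, "ZP": 1, "TE": 2, "BC": 3, "ICM": 4}
REGION_NAMES = ("BG", "ZP", "TE", "BC", "ICM")

# region base intensity levels (8-bit) and granular texture amplitudes
_BASE = {"BG": 70.0, "ZP": 150.0, "TE": 135.0, "BC": 95.0, "ICM": 145.0}
_GRAIN_AMP = {"BG": 0.0, "ZP": 8.0, "TE": 35.0, "BC": 6.0, "ICM": 30.0}
_GRAIN_SIGMA = {"BG": 1.5, "ZP": 1.5, "TE": 1.0, "BC": 1.5, "ICM": 0.8}
_ZP_ALPHA = 0.8         # ZP semi-transparency: blend with underlying background
_OPTICS_SIGMA = 0.7     # point-spread blur applied before sensor noise


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic blastocyst.

    ``embryo_radius`` is the outer radius of the TE cell ring in pixels; the ZP
    annulus spans ``[embryo_radius, embryo_radius + zp_thickness)``.
    ``hatch_gap_angle`` is the angular arc (degrees) of the ZP breach and
    ``hatched_fraction`` the fraction of cell (TE+ICM) pixel mass that lies
    outside the ZP outer radius.
    """

    image_size: int = 256
    stage: str = "expansion"
    embryo_radius: float = 80.0
    zp_thickness: float = 10.0
    te_thickness: float = 16.0
    icm_present: bool = True
    icm_radius: float = 26.0
    hatch_gap_angle: float = 0.0
    hatched_fraction: float = 0.0
    noise_sd: float = 8.0
    background_gradient: float = 20.0
    pixel_size_um: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.embryo_radius + self.zp_thickness >= self.image_size / 2:
            raise ValueError(
                "embryo_radius + zp_thickness must be < image_size/2 "
                f"({self.embryo_radius} + {self.zp_thickness} vs {self.image_size / 2})")
        if self.stage == "expansion" and (self.hatch_gap_angle != 0 or self.hatched_fraction != 0):
            raise ValueError("expansion stage requires hatch_gap_angle = 0 and hatched_fraction = 0")
        if self.stage == "hatched" and self.hatched_fraction < 0.5:
            raise ValueError("hatched stage requires hatched_fraction >= 0.5")
        if self.stage == "hatching" and not (0 < self.hatched_fraction < 0.5):
            raise ValueError("hatching stage requires 0 < hatched_fraction < 0.5")
        if self.stage != "expansion" and self.hatch_gap_angle <= 0:
            raise ValueError("hatching/hatched stages require hatch_gap_angle > 0")
        if not 0 <= self.hatched_fraction <= 1:
            raise ValueError("hatched_fraction must lie in [0, 1]")
        if self.te_thickness >= self.embryo_radius:
            raise ValueError("te_thickness must be smaller than embryo_radius")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _dist(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    return np.hypot(yy - center[0], xx - center[1])


def _angle(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    return np.arctan2(yy - center[0], xx - center[1])


def _wrap(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def _lobe_labels(shape, c_lobe, r_lobe, te_thickness):
    """TE shell / BC interior label contributions of a herniated lobe."""
    d = _dist(shape, c_lobe)
    te = (d < r_lobe) & (d >= max(r_lobe - te_thickness, 0.0))
    bc = d < max(r_lobe - te_thickness, 0.0)
    return te, bc


def _build_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    shape = (size, size)
    jitter = 0.03 * size
    c0 = (size / 2 + rng.uniform(-jitter, jitter),
          size / 2 + rng.uniform(-jitter, jitter))
    d0 = _dist(shape, c0)
    edge_dist = min(c0[0], c0[1], size - 1 - c0[0], size - 1 - c0[1])

    r_te_out = spec.embryo_radius
    r_zp_out = r_te_out + spec.zp_thickness
    r_te_in = r_te_out - spec.te_thickness

    labels = np.zeros(shape, dtype=np.uint8)
    labels[(d0 >= r_te_out) & (d0 < r_zp_out)] = REGION_CODES["ZP"]
    if spec.stage != "hatched":
        labels[(d0 >= r_te_in) & (d0 < r_te_out)] = REGION_CODES["TE"]
        labels[d0 < r_te_in] = REGION_CODES["BC"]

    theta0 = rng.uniform(-np.pi, np.pi)        # direction of the ZP breach
    host_center: tuple[float, float] = c0
    host_r = r_te_in
    icm_toward_center = False

    if spec.stage != "expansion":
        half_gap = np.deg2rad(spec.hatch_gap_angle) / 2
        ang = _angle(shape, c0)
        in_gap = np.abs(_wrap(ang - theta0)) < half_gap
        # breach the ZP: gap pixels revert to background
        labels[in_gap & (labels == REGION_CODES["ZP"])] = REGION_CODES["BG"]

    if spec.stage == "hatching":
        # figure-of-eight: a herniated lobe through the breach; its radius is
        # solved so that the requested fraction of cell mass lies outside the
        # ZP outer radius (capped by the field of view)
        inside_cells = int(np.count_nonzero(labels == REGION_CODES["TE"]))
        f = spec.hatched_fraction
        lo = 3.0
        hi = max(lo + 1.0, (edge_dist - 2.0 - r_zp_out) / 1.75)

        def outside_cells(radius: float) -> int:
            cc = (c0[0] + (r_zp_out + 0.75 * radius) * np.sin(theta0),
                  c0[1] + (r_zp_out + 0.75 * radius) * np.cos(theta0))
            te, _ = _lobe_labels(shape, cc, radius, spec.te_thickness)
            return int(np.count_nonzero(te & (d0 >= r_zp_out)))

        for _ in range(20):
            mid = 0.5 * (lo + hi)
            out = outside_cells(mid)
            if out / max(inside_cells + out, 1) < f:
                lo = mid
            else:
                hi = mid
        r_lobe = 0.5 * (lo + hi)
        c_lobe = (c0[0] + (r_zp_out + 0.75 * r_lobe) * np.sin(theta0),
                  c0[1] + (r_zp_out + 0.75 * r_lobe) * np.cos(theta0))
        te_lobe, bc_lobe = _lobe_labels(shape, c_lobe, r_lobe, spec.te_thickness)
        free = labels == REGION_CODES["BG"]
        labels[te_lobe & free] = REGION_CODES["TE"]
        labels[bc_lobe & free] = REGION_CODES["BC"]

    elif spec.stage == "hatched":
        # the embryo has left the ZP: an (almost) empty remnant ring plus a
        # displaced embryo body whose offset is solved for the requested
        # outside fraction of cell mass
        r_body = r_te_out
        lo, hi = 0.0, max(1.0, edge_dist - 2.0 - r_body)

        def body_masks(delta: float):
            cc = (c0[0] + delta * np.sin(theta0), c0[1] + delta * np.cos(theta0))
            te, bc = _lobe_labels(shape, cc, r_body, spec.te_thickness)
            return cc, te, bc

        for _ in range(20):
            mid = 0.5 * (lo + hi)
            _, te, _ = body_masks(mid)
            n_te = int(np.count_nonzero(te))
            n_out = int(np.count_nonzero(te & (d0 >= r_zp_out)))
            if n_out / max(n_te, 1) < spec.hatched_fraction:
                lo = mid
            else:
                hi = mid
        c_body, te_body, bc_body = body_masks(0.5 * (lo + hi))
        keep = labels != REGION_CODES["ZP"]      # the remnant ZP stays on top
        labels[te_body & keep] = REGION_CODES["TE"]
        labels[bc_body & keep] = REGION_CODES["BC"]
        host_center, host_r = c_body, max(r_body - spec.te_thickness, 1.0)
        icm_toward_center = True

    if spec.icm_present:
        if icm_toward_center:
            phi = float(np.arctan2(c0[0] - host_center[0], c0[1] - host_center[1]))
        else:
            phi = rng.uniform(-np.pi, np.pi)
        off = max(host_r - 0.7 * spec.icm_radius, 0.0)
        c_icm = (host_center[0] + off * np.sin(phi), host_center[1] + off * np.cos(phi))
        icm = (_dist(shape, c_icm) < spec.icm_radius) & (labels == REGION_CODES["BC"])
        if not icm.any():
            icm = (_dist(shape, host_center) < spec.icm_radius) \
                & (labels == REGION_CODES["BC"])
        labels[icm] = REGION_CODES["ICM"]

    return labels


def _render(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = labels.shape
    xx = np.linspace(-0.5, 0.5, shape[1])[None, :]
    background = _BASE["BG"] + spec.background_gradient * np.broadcast_to(xx, shape)

    img = background.copy()
    for name in ("BC", "TE", "ICM", "ZP"):
        region = labels == REGION_CODES[name]
        if not region.any():
            continue
        level = _BASE[name]
        if name == "ZP":   # semi-transparent layer over the medium
            value = _ZP_ALPHA * level + (1 - _ZP_ALPHA) * background
        else:
            value = level
        img = np.where(region, value, img)
        amp = _GRAIN_AMP[name]
        if amp > 0:
            grain = ndi.gaussian_filter(rng.standard_normal(shape), _GRAIN_SIGMA[name])
            grain /= max(grain.std(), 1e-9)
            img = np.where(region, img + amp * grain, img)

    img = ndi.gaussian_filter(img, _OPTICS_SIGMA)
    img = img + spec.noise_sd * rng.standard_normal(shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom micrograph and its exact region label map.

    Returns ``(image, labels)`` where ``image`` is a ``uint8`` grid and
    ``labels`` uses the codes ``{0: BG, 1: ZP, 2: TE, 3: BC, 4: ICM}``.
    Two calls with an equal spec (including the seed) are bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec, rng)
    image = _render(labels, spec, rng)
    return image, labels


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _stage_counts(n: int, stage_mix: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n images over the three stages."""
    raw = [m * n for m in stage_mix]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def _spec_for(stage: str, image_size: int, pixel_size_um: float,
              rng: np.random.Generator, seed: int, icm_present: bool) -> PhantomSpec:
    size = image_size
    r = rng.uniform(0.28, 0.34) * size
    zp = max(3.0, 0.045 * size)
    te = max(5.0, 0.08 * size)
    icm = rng.uniform(0.09, 0.12) * size
    if stage == "expansion":
        gap, frac = 0.0, 0.0
    elif stage == "hatching":
        gap, frac = rng.uniform(45.0, 75.0), rng.uniform(0.1, 0.3)
        r *= 0.8
    else:
        gap, frac = rng.uniform(80.0, 120.0), rng.uniform(0.55, 0.8)
        r *= 0.55
        te *= 0.7
        icm *= 0.7
    return PhantomSpec(image_size=size, stage=stage, embryo_radius=r,
                       zp_thickness=zp, te_thickness=te, icm_present=icm_present,
                       icm_radius=icm, hatch_gap_angle=gap, hatched_fraction=frac,
                       pixel_size_um=pixel_size_um, seed=seed)


def generate_dataset(out_dir: str, n: int,
                     stage_mix: tuple[float, float, float] = (0.63, 0.34, 0.03),
                     icm_missing_rate: float = 0.18, seed: int = 0, *,
                     image_size: int = 256, pixel_size_um: float = 1.0,
                     train_fraction: float = 0.9) -> pd.DataFrame:
    """Write ``n`` phantom image/mask pairs plus a manifest CSV to ``out_dir``.

    The default stage mix and ICM-missing rate mirror a clinical collection in
    which expansion embryos dominate, hatched ones are rare, and roughly one in
    five images has no embryologist-identifiable ICM.  Returns the manifest as
    a :class:`pandas.DataFrame`; the CSV is written to ``out_dir/manifest.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(stage_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("stage_mix must be three proportions summing to 1")
    if not 0 <= icm_missing_rate <= 1:
        raise ValueError("icm_missing_rate must lie in [0, 1]")

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = _stage_counts(n, tuple(mix))
    stages = [s for s, c in zip(STAGES, counts) for _ in range(c)]

    n_missing = int(round(n * icm_missing_rate))
    missing = np.zeros(n, dtype=bool)
    missing[rng.permutation(n)[:n_missing]] = True

    n_test = int(round((1.0 - train_fraction) * n))
    split = np.array(["train"] * n)
    split[rng.permutation(n)[:n_test]] = "test"

    rows = []
    for i, stage in enumerate(stages):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = _spec_for(stage, image_size, pixel_size_um, rng, sub_seed,
                         icm_present=not missing[i])
        image, labels = generate_phantom(spec)
        img_path = os.path.join(out_dir, f"phantom_{i:04d}.png")
        mask_path = os.path.join(out_dir, f"phantom_{i:04d}_mask.png")
        dataio.write_image(img_path, image)
        dataio.write_mask(mask_path, labels)
        rows.append({"path": img_path, "mask_path": mask_path, "stage": stage,
                     "pixel_size_um": pixel_size_um,
                     "icm_present": bool(not missing[i]), "split": split[i]})

    manifest = pd.DataFrame(rows)
    dataio.write_manifest(os.path.join(out_dir, "manifest.csv"), manifest)
    return manifest
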