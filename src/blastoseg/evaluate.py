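"""Segmentation metrics, per-stage reporting and the robustness analysis.

The central metric is the Dice similarity coefficient,
``DSC(A, B) = 2 |A ∩ B| / (|A| + |B|)``, ranging from 0 (no spatial overlap)
to 1 (complete overlap).  When both masks are empty the DSC is defined as 1
(perfect agreement on absence; configurable) — the asymmetric case of an
empty ground truth against a non-empty prediction scores 0, which is what
depresses the ICM average on images where no ICM was marked.

``stage_report`` aggregates per-image, per-region DSC into mean ± standard
deviation grouped by developmental stage, with an additional ICM2 row that
restricts the ICM statistic to images whose ground truth actually contains an
ICM.  The 'All' column/row is the micro-average: the five-way label-agreement
DSC computed over all pixels of an image.

``sensitivity_analysis`` segments fourteen transformed variants of each
image (three right-angle rotations, three flips, eight additive brightness
changes), maps geometric variants back into the reference frame by the exact
inverse transform, and reports the mean per-region DSC of each variant
against the segmentation of the untransformed image.  Following the stated
protocol, brightness deltas are applied to the cropped image and then flow
through the rescaling, gamma-correction and normalisation steps, while
geometric transforms are applied after interpolation (equivalently, to the
fully pre-processed image, since right-angle rotations and flips commute with
the pixelwise brightness standardisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import preprocess as prep
from .augment import SENSITIVITY_DELTAS, apply_brightness_delta, \
    apply_geometric, invert_geometric
from .pixelclassifier import REGION_CODES

__all__ = [
    "dsc",
    "RegionMetrics",
    "region_metrics",
    "all_regions_dsc",
    "ImageEvaluation",
    "stage_report",
    "sensitivity_analysis",
    "SENSITIVITY_ROWS",
    "SENSITIVITY_COLUMNS",
]

STAGE_GROUPS = ("all", "expansion", "hatching", "hatched")
SENSITIVITY_GEOMETRIC = ("90D", "180D", "270D", "H-", "V-", "HV-")
SENSITIVITY_ROWS = ("0D",) + SENSITIVITY_GEOMETRIC + tuple(
    f"{d}B" for d in SENSITIVITY_DELTAS)
SENSITIVITY_COLUMNS = ("BC", "BG", "ICM", "TE", "ZP", "All")


def dsc(a: np.ndarray, b: np.ndarray, *, both_empty: float = 1.0) -> float:
    """Dice similarity coefficient of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return float(both_empty)
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


@dataclass(frozen=True)
class RegionMetrics:
    """One-vs-rest confusion statistics of a region.  Ratios with a zero
    denominator are reported as None (missing), not as 0."""

    region: str
    tp: int
    fp: int
    fn: int
    tn: int
    dsc: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def region_metrics(pred: np.ndarray, gt: np.ndarray, region: str) -> RegionMetrics:
    """Confusion-matrix metrics of one region, one-vs-rest."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"label map dimensions differ: {pred.shape} vs {gt.shape}")
    code = REGION_CODES[region]
    p = pred == code
    g = gt == code
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return RegionMetrics(
        region=region, tp=tp, fp=fp, fn=fn, tn=tn,
        dsc=_ratio(2 * tp, 2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, tp + fp + fn + tn))


def all_regions_dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Micro-average DSC over the five regions: the five-way label agreement
    fraction (2 * #agreeing / 2 * #pixels)."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"label map dimensions differ: {pred.shape} vs {gt.shape}")
    return float(np.count_nonzero(pred == gt)) / pred.size


def per_region_dsc(pred: np.ndarray, gt: np.ndarray, *,
                   both_empty: float = 1.0) -> dict[str, float]:
    """Per-region DSC dict (keys BG, ZP, TE, BC, ICM and 'All')."""
    out = {name: dsc(np.asarray(pred) == code, np.asarray(gt) == code,
                     both_empty=both_empty)
           for name, code in REGION_CODES.items()}
    out["All"] = all_regions_dsc(pred, gt)
    return out


@dataclass
class ImageEvaluation:
    """Per-image evaluation record used by :func:`stage_report`."""

    image_id: str
    stage: str
    icm_present: bool                     # ground truth contains ICM pixels
    dsc_before: dict[str, float]          # region -> DSC, initial segmentation
    dsc_after: dict[str, float]           # region -> DSC, refined segmentation


def stage_report(evals: Sequence[ImageEvaluation]) -> pd.DataFrame:
    """Aggregate DSC into a per-region x per-stage-group table.

    Rows: BC, BG, ICM, ICM2, TE, ZP, All.  Columns: before-refinement mean and
    std over the whole set, then after-refinement mean and std per group
    (all / expansion / hatching / hatched).  The ICM2 row restricts the ICM
    statistic to images with a non-empty ground-truth ICM.  Groups without any
    image are omitted with a warning.
    """
    if not evals:
        raise ValueError("stage_report requires at least one evaluation record")
    regions = ["BC", "BG", "ICM", "ICM2", "TE", "ZP", "All"]

    def select(group: str) -> list[ImageEvaluation]:
        return list(evals) if group == "all" else [e for e in evals if e.stage == group]

    def stats(records: list[ImageEvaluation], region: str, phase: str
              ) -> tuple[float, float]:
        key = "ICM" if region == "ICM2" else region
        pool = [e for e in records if e.icm_present] if region == "ICM2" else records
        vals = [getattr(e, f"dsc_{phase}")[key] for e in pool]
        if not vals:
            return np.nan, np.nan
        return float(np.mean(vals)), float(np.std(vals))

    data: dict[str, list[float]] = {}
    everything = select("all")
    data["before_mean"], data["before_std"] = zip(
        *[stats(everything, r, "before") for r in regions])
    for group in STAGE_GROUPS:
        records = select(group)
        if not records:
            warnings.warn(f"stage group {group!r} has no images; omitted from report")
            continue
        means, stds = zip(*[stats(records, r, "after") for r in regions])
        data[f"{group}_mean"] = means
        data[f"{group}_std"] = stds
    return pd.DataFrame(data, index=regions)


def sensitivity_analysis(micrographs: Sequence[prep.Micrograph],
                         segment: Callable[[np.ndarray], np.ndarray], *,
                         both_empty: float = 1.0) -> pd.DataFrame:
    """Robustness of a segmenter to the fourteen standard transforms.

    ``segment`` maps a pre-processed intensity grid in [0, 255] to a label
    map.  Returns a DataFrame with the reference '0D' row (all ones by
    construction) plus the fourteen transform rows, columns BC, BG, ICM, TE,
    ZP and All, each entry the mean DSC against the reference segmentation
    over all supplied micrographs.
    """
    if not micrographs:
        raise ValueError("sensitivity_analysis requires at least one micrograph")
    sums = {row: np.zeros(len(SENSITIVITY_COLUMNS)) for row in SENSITIVITY_ROWS}

    for m in micrographs:
        img = np.asarray(m.intensities, dtype=np.float64)
        box = prep.detect_bounding_box(img)
        cropped = prep.crop(img, box)

        def standardize(arr: np.ndarray) -> np.ndarray:
            scaled = prep.rescale_to_physical(arr, m.pixel_size_um)
            corrected = prep.gamma_correct(np.clip(scaled / 255.0, 0.0, 1.0))
            return prep.minmax_normalize(corrected.image)

        reference_img = standardize(cropped)
        ref_labels = segment(reference_img)

        for row in SENSITIVITY_ROWS:
            if row == "0D":
                back = ref_labels
            elif row.endswith("B"):
                delta = float(row[:-1])
                back = segment(standardize(apply_brightness_delta(cropped, delta)))
            else:
                transformed = apply_geometric(row, reference_img)
                back = invert_geometric(row, segment(transformed))
            scores = per_region_dsc(back, ref_labels, both_empty=both_empty)
            sums[row] += np.array([scores[c] for c in SENSITIVITY_COLUMNS])

    table = {row: sums[row] / len(micrographs) for row in SENSITIVITY_ROWS}
    return pd.DataFrame.from_dict(table, orient="index",
                                  columns=list(SENSITIVITY_COLUMNS))
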