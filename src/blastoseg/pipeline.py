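"""End-to-end orchestration: train, segment and evaluate whole datasets.

This module binds the stages together exactly in the published order:
pre-process (detect/crop/rescale/gamma/min-max) → extract the 861-dimensional
texture features → sample 50 labelled pixels per region per image → train the
per-pixel classifier → predict initial segmentations on the training images →
train the encoder–decoder refiner on (initial, ground-truth) pairs.
Segmentation of new images runs pre-process → features → classify → refine.

All functions operate on in-memory records; the CLI layers file I/O on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import augment, dataio, features, pixelclassifier as pc, refiner as rf
from .config import RunConfig
from .evaluate import ImageEvaluation, per_region_dsc, stage_report
from .preprocess import Micrograph, preprocess_mask, preprocess_pipeline

__all__ = [
    "DatasetRecord",
    "TrainedPipeline",
    "records_from_manifest",
    "train_pipeline",
    "segment_micrograph",
    "evaluate_dataset",
]


@dataclass
class DatasetRecord:
    """One dataset row: image, optional ground-truth mask and metadata."""

    image: np.ndarray
    mask: np.ndarray | None
    stage: str
    pixel_size_um: float = 1.0
    image_id: str = ""

    @property
    def icm_present(self) -> bool:
        if self.mask is None:
            return False
        return bool(np.any(self.mask == pc.REGION_CODES["ICM"]))


@dataclass
class TrainedPipeline:
    """Both trained models plus the feature-registry handles and versions."""

    classifier: pc.PixelClassifier
    refiner: rf.Refiner
    bank: features.FilterBank
    kernels: features.KernelSet
    provenance: list[dict] = field(default_factory=list)

    @property
    def versions(self) -> dict[str, str]:
        return {"bank_version": self.bank.version,
                "kernel_version": self.kernels.version}


def records_from_manifest(manifest: pd.DataFrame, *, split: str | None = None
                          ) -> list[DatasetRecord]:
    """Load dataset records (images + masks) referenced by a manifest."""
    rows = manifest if split is None else manifest[manifest["split"] == split]
    records = []
    for _, row in rows.iterrows():
        mask = dataio.read_mask(row["mask_path"]) if isinstance(row.get("mask_path"), str) \
            else None
        records.append(DatasetRecord(
            image=dataio.read_image(row["path"]), mask=mask,
            stage=str(row.get("stage", "expansion")),
            pixel_size_um=float(row.get("pixel_size_um", 1.0)),
            image_id=str(row["path"])))
    return records


def _preprocessed_pair(record: DatasetRecord, cfg: RunConfig):
    m = Micrograph(intensities=record.image, pixel_size_um=record.pixel_size_um,
                   stage=record.stage)
    image, prov = preprocess_pipeline(m)
    mask_t = None
    if record.mask is not None:
        from .preprocess import BoundingBox
        box = BoundingBox(*prov["box"])
        mask_t = preprocess_mask(record.mask, box, record.pixel_size_um)
    prov["image_id"] = record.image_id
    return image, mask_t, prov


def train_pipeline(records: list[DatasetRecord], cfg: RunConfig | None = None,
                   *, verbose: bool = False) -> TrainedPipeline:
    """Train classifier and refiner on a labelled dataset."""
    cfg = cfg or RunConfig()
    seeds = cfg.seeds()
    bank = features.build_filter_bank()
    kernels = features.build_kernel_set()

    if any(r.mask is None for r in records):
        bad = [r.image_id for r in records if r.mask is None]
        raise ValueError(f"training requires ground-truth masks; missing for: {bad}")

    # optional training augmentation (applied to raw images + masks)
    if cfg.augment_k > 1:
        imgs = [r.image for r in records]
        masks = [r.mask for r in records]
        a_imgs, a_masks, lineage = augment.augment_training_set(
            imgs, masks, cfg.augment_k, seed=seeds["sampling"])
        records = [DatasetRecord(image=np.clip(np.round(i), 0, 255).astype(np.uint8),
                                 mask=m, stage=records[l["source_index"]].stage,
                                 pixel_size_um=records[l["source_index"]].pixel_size_um,
                                 image_id=f'{records[l["source_index"]].image_id}'
                                          f'#aug{n}')
                   for n, (i, m, l) in enumerate(zip(a_imgs, a_masks, lineage))]

    # pre-process once; keep pre-processed pairs, re-extract features on demand
    provenance: list[dict] = []
    prepped: list[tuple[np.ndarray, np.ndarray]] = []
    sample_sets = []
    rng = np.random.default_rng(seeds["sampling"])
    for record in records:
        image, mask_t, prov = _preprocessed_pair(record, cfg)
        provenance.append(prov)
        prepped.append((image, mask_t))
        stack = features.extract_features(image, bank, kernels)
        sample_sets.append(pc.sample_training_pixels(
            stack, mask_t, n_per_region=cfg.n_pixels_per_region,
            seed=int(rng.integers(0, 2**31 - 1)), image_id=record.image_id))
        del stack

    samples = pc.PixelSampleSet.concatenate(sample_sets)
    if verbose:  # pragma: no cover - cosmetic
        print(f"training pixel classifier on {len(samples.labels)} samples")
    clf_spec = cfg.classifier if cfg.classifier.seed else \
        pc.ClassifierSpec(**{**cfg.classifier.__dict__, "seed": seeds["classifier"]})
    classifier = pc.train_pixel_classifier(samples, clf_spec)
    classifier.bank_version = bank.version
    classifier.kernel_version = kernels.version

    # initial segmentations of the training images feed the refiner
    pairs = []
    for image, mask_t in prepped:
        stack = features.extract_features(image, bank, kernels)
        initial = pc.predict_pixels(classifier, stack)
        pairs.append((initial, mask_t))
        del stack
    if verbose:  # pragma: no cover - cosmetic
        print(f"training refiner on {len(pairs)} pairs")
    ref_spec = cfg.refiner if cfg.refiner.seed else \
        rf.RefinerSpec(**{**cfg.refiner.__dict__, "seed": seeds["refiner"]})
    refiner = rf.train_refiner(pairs, ref_spec)
    refiner.bank_version = bank.version
    refiner.kernel_version = kernels.version

    return TrainedPipeline(classifier=classifier, refiner=refiner, bank=bank,
                           kernels=kernels, provenance=provenance)


def segment_preprocessed(tp: TrainedPipeline, image: np.ndarray, *,
                         refine: bool = True) -> np.ndarray:
    """Segment an already pre-processed intensity grid; returns a label map."""
    stack = features.extract_features(image, tp.bank, tp.kernels)
    initial = pc.predict_pixels(tp.classifier, stack)
    if not refine:
        return initial.labels
    refined = rf.refine_segmentation(tp.refiner, initial)
    return refined.labels


def segment_micrograph(tp: TrainedPipeline, record: DatasetRecord
                       ) -> dict[str, np.ndarray | dict]:
    """Full segmentation of one raw micrograph (before/after refinement)."""
    image, mask_t, prov = _preprocessed_pair(record, RunConfig())
    stack = features.extract_features(image, tp.bank, tp.kernels)
    initial = pc.predict_pixels(tp.classifier, stack)
    refined = rf.refine_segmentation(tp.refiner, initial)
    return {"preprocessed": image, "mask": mask_t, "provenance": prov,
            "initial_labels": initial.labels, "refined_labels": refined.labels}


def evaluate_dataset(tp: TrainedPipeline, records: list[DatasetRecord], *,
                     both_empty: float = 1.0
                     ) -> tuple[list[ImageEvaluation], pd.DataFrame]:
    """Segment and score a labelled dataset; returns per-image records and
    the per-region x per-stage report."""
    evals = []
    for record in records:
        if record.mask is None:
            raise ValueError(f"evaluation requires a mask for {record.image_id}")
        out = segment_micrograph(tp, record)
        gt = out["mask"]
        evals.append(ImageEvaluation(
            image_id=record.image_id, stage=record.stage,
            icm_present=bool(np.any(gt == pc.REGION_CODES["ICM"])),
            dsc_before=per_region_dsc(out["initial_labels"], gt, both_empty=both_empty),
            dsc_after=per_region_dsc(out["refined_labels"], gt, both_empty=both_empty)))
    return evals, stage_report(evals)
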