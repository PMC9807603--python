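"""Per-pixel texture classification into the five blastocyst regions.

Training pixels are sampled uniformly without replacement — at most 50 per
region per micrograph, so absent regions (e.g. an unmarked ICM) simply
contribute no rows and the class balance follows region presence, not region
size.  The classifier is a fully connected network (three hidden layers of
400 rectified-linear units on the 861-dimensional texture descriptor, softmax
over the five regions) trained with Adam on categorical cross-entropy, a 10 %
validation split, learning-rate reduction on a validation-loss plateau
(factor 0.5, patience 25) and early stopping (patience 60, min delta 0.001).
Features are z-scored with training-set statistics before the network sees
them; the statistics are part of the trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Sequential, make_mlp
from .features import FeatureStack, N_FEATURES

__all__ = [
    "REGION_CODES",
    "REGION_NAMES",
    "PixelSampleSet",
    "ClassifierSpec",
    "PixelClassifier",
    "InitialSegmentation",
    "sample_training_pixels",
    "train_pixel_classifier",
    "predict_pixels",
]

REGION_CODES = {"BG": 0, "ZP": 1, "TE": 2, "BC": 3, "ICM": 4}
REGION_NAMES = ("BG", "ZP", "TE", "BC", "ICM")
N_CLASSES = 5

# Arg-max ties are broken by this fixed outermost-to-innermost priority, which
# coincides with ascending label code, so a plain first-max argmax realises it.
TIE_BREAK_PRIORITY = ("BG", "ZP", "TE", "BC", "ICM")


@dataclass
class PixelSampleSet:
    """Labelled training pixels: features (N, 861), labels (N,), provenance
    rows of (image_id, x, y)."""

    features: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    @staticmethod
    def concatenate(sets: list["PixelSampleSet"]) -> "PixelSampleSet":
        return PixelSampleSet(
            features=np.concatenate([s.features for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets], axis=0),
            provenance=[p for s in sets for p in s.provenance])


@dataclass(frozen=True)
class ClassifierSpec:
    hidden_layers: int = 3
    units_per_layer: int = 400
    epochs: int = 500
    batch_size: int = 256
    validation_split: float = 0.10
    learning_rate: float = 1e-3
    lr_reduction_factor: float = 0.5
    lr_reduction_patience: int = 25
    early_stopping_patience: int = 60
    early_stopping_min_delta: float = 0.001
    seed: int = 0


@dataclass
class PixelClassifier:
    net: Sequential
    mean: np.ndarray
    std: np.ndarray
    spec: ClassifierSpec
    bank_version: str = ""
    kernel_version: str = ""
    history: dict = field(default_factory=dict)

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.mean) / self.std
        return self.net.predict(z.astype(np.float32))


@dataclass
class InitialSegmentation:
    """Soft per-pixel class scores plus the hard arg-max partition."""

    score_maps: np.ndarray               # (H, W, 5), rows sum to 1

    @property
    def labels(self) -> np.ndarray:
        # np.argmax returns the first maximum, which realises the documented
        # BG > ZP > TE > BC > ICM tie-break since codes ascend in that order
        return np.argmax(self.score_maps, axis=-1).astype(np.uint8)

    @property
    def binary_maps(self) -> np.ndarray:
        lab = self.labels
        return np.stack([lab == c for c in range(N_CLASSES)], axis=-1)


def sample_training_pixels(stack: FeatureStack, mask: np.ndarray,
                           n_per_region: int = 50, seed: int = 0,
                           image_id: str = "") -> PixelSampleSet:
    """Sample up to ``n_per_region`` pixels per present region, uniformly
    without replacement; absent regions contribute zero rows."""
    mask = np.asarray(mask)
    if stack.values.shape[:2] != mask.shape:
        raise ValueError(
            f"feature stack {stack.values.shape[:2]} and mask {mask.shape} "
            "dimensions differ")
    rng = np.random.default_rng(seed)
    feats, labels, prov = [], [], []
    for name, code in REGION_CODES.items():
        ys, xs = np.nonzero(mask == code)
        if len(ys) == 0:
            continue
        take = min(n_per_region, len(ys))
        idx = rng.choice(len(ys), size=take, replace=False)
        feats.append(stack.values[ys[idx], xs[idx], :])
        labels.append(np.full(take, code, dtype=np.int64))
        prov.extend((image_id, int(x), int(y)) for x, y in zip(xs[idx], ys[idx]))
    if not feats:
        return PixelSampleSet(features=np.empty((0, N_FEATURES), dtype=np.float32),
                              labels=np.empty(0, dtype=np.int64))
    return PixelSampleSet(features=np.concatenate(feats, axis=0),
                          labels=np.concatenate(labels, axis=0), provenance=prov)


def train_pixel_classifier(samples: PixelSampleSet,
                           spec: ClassifierSpec = ClassifierSpec()
                           ) -> PixelClassifier:
    """Train the fully connected per-pixel classifier on sampled features."""
    if samples.n_classes < 2:
        raise ValueError("training requires samples from at least two classes")
    x = np.asarray(samples.features, dtype=np.float64)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    z = ((x - mean) / std).astype(np.float32)
    y = np.zeros((len(z), N_CLASSES), dtype=np.float32)
    y[np.arange(len(z)), samples.labels] = 1.0

    net = make_mlp(z.shape[1], N_CLASSES, hidden_layers=spec.hidden_layers,
                   units=spec.units_per_layer, lr=spec.learning_rate,
                   seed=spec.seed)
    history = net.fit(
        z, y, epochs=spec.epochs, batch_size=spec.batch_size,
        validation_split=spec.validation_split, seed=spec.seed,
        early_stopping_patience=spec.early_stopping_patience,
        early_stopping_min_delta=spec.early_stopping_min_delta,
        reduce_lr_factor=spec.lr_reduction_factor,
        reduce_lr_patience=spec.lr_reduction_patience)
    return PixelClassifier(net=net, mean=mean, std=std, spec=spec, history=history)


def predict_pixels(model: PixelClassifier, stack: FeatureStack
                   ) -> InitialSegmentation:
    """Classify every pixel of a feature stack into the five regions."""
    h, w, depth = stack.values.shape
    if depth != N_FEATURES:
        raise ValueError(f"expected feature depth {N_FEATURES}, got {depth}")
    flat = stack.values.reshape(-1, depth)
    scores = model.predict_scores(flat).reshape(h, w, N_CLASSES)
    return InitialSegmentation(score_maps=scores)
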