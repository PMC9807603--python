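"""Encoder–decoder refinement of the initial per-pixel segmentation.

The per-pixel classifier sees only a local texture descriptor, so its output
ignores the blastocyst's topology (the ZP is the outermost ring, the TE lies
between ZP and BC/ICM, the ICM sits inside the cavity).  The refiner injects
that structure: a small convolutional encoder–decoder (three conv + three
max-pool encoding layers, four conv + three up-sampling decoding layers,
sigmoid output) maps the five hard binary maps of the initial segmentation to
refined region score maps, trained with mean squared error against the
ground-truth masks using RMSprop, a 10 % validation split and the same
early-stopping / learning-rate-reduction settings as the pixel classifier.

Inputs of arbitrary size are reflect-padded to a multiple of 8 (three 2x
poolings) and cropped back after inference, so refinement never changes
spatial dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Sequential, make_encoder_decoder
from .pixelclassifier import InitialSegmentation, N_CLASSES

__all__ = [
    "RefinerSpec",
    "Refiner",
    "RefinedSegmentation",
    "train_refiner",
    "refine_segmentation",
]

_POOL_FACTOR = 8    # three 2x max-poolings


@dataclass(frozen=True)
class RefinerSpec:
    widths: tuple[int, int, int] = (16, 32, 64)
    epochs: int = 100
    batch_size: int = 4
    validation_split: float = 0.10
    learning_rate: float = 1e-3
    lr_reduction_factor: float = 0.5
    lr_reduction_patience: int = 25
    early_stopping_patience: int = 60
    early_stopping_min_delta: float = 0.001
    seed: int = 0


@dataclass
class Refiner:
    net: Sequential
    spec: RefinerSpec
    bank_version: str = ""
    kernel_version: str = ""
    history: dict = field(default_factory=dict)


@dataclass
class RefinedSegmentation:
    score_maps: np.ndarray               # (H, W, 5)

    @property
    def labels(self) -> np.ndarray:
        # first-max argmax realises the BG > ZP > TE > BC > ICM tie-break
        return np.argmax(self.score_maps, axis=-1).astype(np.uint8)


def _as_tensor(s) -> np.ndarray:
    """Coerce an InitialSegmentation / label map / 5-channel array to a float
    (H, W, 5) binary tensor."""
    if isinstance(s, InitialSegmentation):
        return s.binary_maps.astype(np.float32)
    arr = np.asarray(s)
    if arr.ndim == 2:          # label map
        return np.stack([arr == c for c in range(N_CLASSES)], axis=-1).astype(np.float32)
    if arr.ndim == 3 and arr.shape[-1] == N_CLASSES:
        return arr.astype(np.float32)
    raise ValueError(f"cannot interpret segmentation input of shape {arr.shape}")


def _pad_to(t: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Reflect-pad a (H, W, C) tensor, centred, up to (target_h, target_w)."""
    h, w = t.shape[:2]
    dh, dw = target_h - h, target_w - w
    if dh < 0 or dw < 0:
        raise ValueError(f"cannot pad {t.shape} down to ({target_h}, {target_w})")
    top, left = dh // 2, dw // 2
    return np.pad(t, ((top, dh - top), (left, dw - left), (0, 0)), mode="reflect")


def _round_up(n: int, k: int = _POOL_FACTOR) -> int:
    return ((n + k - 1) // k) * k


def train_refiner(pairs: list[tuple[object, object]],
                  spec: RefinerSpec = RefinerSpec()) -> Refiner:
    """Train the refiner on (initial segmentation, ground-truth) pairs.

    Each pair is reflect-padded, centred, to the batch-wide maximum size
    rounded up to a multiple of 8, so that all pairs share spatial dimensions
    after padding.
    """
    if len(pairs) < 10:
        raise ValueError(f"refiner training requires at least 10 pairs, got {len(pairs)}")
    tensors = []
    for i, (s, g) in enumerate(pairs):
        ts, tg = _as_tensor(s), _as_tensor(g)
        if ts.shape != tg.shape:
            raise ValueError(
                f"pair {i}: segmentation {ts.shape} and ground truth {tg.shape} "
                "dimensions differ")
        tensors.append((ts, tg))
    target_h = _round_up(max(t.shape[0] for t, _ in tensors))
    target_w = _round_up(max(t.shape[1] for t, _ in tensors))
    x = np.stack([_pad_to(t, target_h, target_w) for t, _ in tensors])
    y = np.stack([_pad_to(t, target_h, target_w) for _, t in tensors])

    net = make_encoder_decoder(N_CLASSES, N_CLASSES, widths=spec.widths,
                               lr=spec.learning_rate, seed=spec.seed)
    history = net.fit(
        x, y, epochs=spec.epochs, batch_size=spec.batch_size,
        validation_split=spec.validation_split, seed=spec.seed,
        early_stopping_patience=spec.early_stopping_patience,
        early_stopping_min_delta=spec.early_stopping_min_delta,
        reduce_lr_factor=spec.lr_reduction_factor,
        reduce_lr_patience=spec.lr_reduction_patience)
    return Refiner(net=net, spec=spec, history=history)


def refine_segmentation(model: Refiner, s, *,
                        expected_versions: dict | None = None
                        ) -> RefinedSegmentation:
    """Run the trained refiner on an initial segmentation of any size."""
    if expected_versions is not None:
        for key, want in expected_versions.items():
            got = getattr(model, key, None)
            if got != want:
                raise ValueError(
                    f"refiner/feature version mismatch for {key!r}: {got!r} vs {want!r}")
    t = _as_tensor(s)
    h, w = t.shape[:2]
    th, tw = _round_up(h), _round_up(w)
    padded = _pad_to(t, th, tw)
    out = model.net.predict(padded[None, ...], batch_size=1)[0]
    top, left = (th - h) // 2, (tw - w) // 2
    return RefinedSegmentation(score_maps=out[top:top + h, left:left + w, :])
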