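"""File I/O: images, indexed label masks, dataset manifests, checkpoints.

Images are 8-bit grayscale PNG/TIFF (RGB inputs are converted to luminance);
masks are single-channel PNGs with label codes 0-4 (per-region binary PNG
export is available for interoperability); manifests are CSV with the columns
``path, mask_path, stage, pixel_size_um, icm_present, split``.  Model
checkpoints are NumPy ``.npz`` archives with a JSON metadata header that
records the feature-registry versions so stale models are rejected at load
time.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["path", "mask_path", "stage", "pixel_size_um", "icm_present", "split"]

_N_REGIONS = 5


def read_image(path: str) -> np.ndarray:
    """Read a micrograph as an 8-bit grayscale array.

    RGB(A) inputs are reduced to luminance with the Rec. 601 weights.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
        arr = np.clip(np.round(arr), 0, 255)
    return arr.astype(np.uint8)


def write_image(path: str, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path: str) -> np.ndarray:
    mask = iio.imread(path)
    if mask.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel")
    if mask.max() >= _N_REGIONS:
        raise ValueError(f"mask {path} contains codes outside 0..{_N_REGIONS - 1}")
    return mask.astype(np.uint8)


def write_mask(path: str, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() >= _N_REGIONS:
        raise ValueError(f"label map contains codes outside 0..{_N_REGIONS - 1}")
    iio.imwrite(path, labels.astype(np.uint8))


def write_binary_masks(prefix: str, labels: np.ndarray,
                       region_names: tuple[str, ...] = ("BG", "ZP", "TE", "BC", "ICM")
                       ) -> list[str]:
    """Export one 0/255 binary PNG per region next to the indexed mask."""
    paths = []
    for code, name in enumerate(region_names):
        path = f"{prefix}_{name}.png"
        iio.imwrite(path, ((labels == code) * 255).astype(np.uint8))
        paths.append(path)
    return paths


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "split"]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    return df


def write_manifest(path: str, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, weights: list[np.ndarray], meta: dict) -> None:
    """Save model weights plus a JSON metadata header to an ``.npz``."""
    arrays = {f"w{i:03d}": w for i, w in enumerate(weights)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> tuple[list[np.ndarray], dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        keys = sorted(k for k in data.files if k.startswith("w"))
        weights = [data[k] for k in keys]
    return weights, meta


def check_versions(meta: dict, expected: dict) -> None:
    """Raise if a checkpoint was produced under different registry versions."""
    for key, want in expected.items():
        got = meta.get(key)
        if got != want:
            raise ValueError(
                f"checkpoint version mismatch for {key!r}: checkpoint has {got!r}, "
                f"current is {want!r}")


def write_provenance(path: str, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
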