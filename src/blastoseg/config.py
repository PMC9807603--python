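"""Run configuration: one seed, one file, one reproducible run.

``RunConfig`` collects every tunable of the pipeline with defaults equal to
the published protocol where one exists (gamma band 0.45–0.75, at most three
gamma transforms, 50 sampled pixels per region, classifier 3x400 with Adam,
refiner with RMSprop/MSE, 10 % validation splits, the callback settings).
A single global seed fans out deterministically to per-stage seeds so that
one integer reproduces phantom generation, sampling and both trainings.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .pixelclassifier import ClassifierSpec
from .refiner import RefinerSpec

__all__ = ["RunConfig", "derive_seeds"]


def derive_seeds(global_seed: int, n: int = 4) -> list[int]:
    """Fan one global seed out into ``n`` independent per-stage seeds
    (each below 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    # paths
    manifest: str = "manifest.csv"
    out_dir: str = "runs"
    # seeds
    seed: int = 0
    # preprocessing
    target_um_per_px: float = 1.0
    detector: str = "variance"           # 'variance' or 'manifest' (external boxes)
    gamma_low: float = 0.45
    gamma_high: float = 0.75
    gamma_max_transforms: int = 3
    # augmentation
    augment_k: int = 1
    # sampling
    n_pixels_per_region: int = 50
    # model specs
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    refiner: RefinerSpec = field(default_factory=RefinerSpec)
    # evaluation
    dsc_both_empty: float = 1.0

    def seeds(self) -> dict[str, int]:
        phantom_s, sampling_s, classifier_s, refiner_s = derive_seeds(self.seed, 4)
        return {"phantom": phantom_s, "sampling": sampling_s,
                "classifier": classifier_s, "refiner": refiner_s}

    # -- YAML round-trip -----------------------------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "classifier" in kwargs and isinstance(kwargs["classifier"], dict):
            kwargs["classifier"] = ClassifierSpec(**kwargs["classifier"])
        if "refiner" in kwargs and isinstance(kwargs["refiner"], dict):
            spec = dict(kwargs["refiner"])
            if "widths" in spec:
                spec["widths"] = tuple(spec["widths"])
            kwargs["refiner"] = RefinerSpec(**spec)
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)
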