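"""Pipeline configuration: a single YAML-serializable record.

All randomness of a pipeline run flows from the one top-level ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bvalues import DEFAULT_BVALUES
from .exceptions import InvalidInputError
from .synthetic import DEFAULT_COHORT, DEFAULT_JITTER, DEFAULT_SNR


@dataclass
class PipelineConfig:
    """End-to-end settings of the simulate -> fit -> analyze pipeline."""

    bvalues: list[float] = field(default_factory=lambda: list(DEFAULT_BVALUES))
    n_malignant: int = DEFAULT_COHORT["malignant"]
    n_benign: int = DEFAULT_COHORT["benign"]
    n_normal: int = DEFAULT_COHORT["normal"]
    voxels_per_lesion: int = 50
    snr: float = DEFAULT_SNR
    jitter: float = DEFAULT_JITTER
    phantom_shape: list[int] = field(default_factory=lambda: [32, 32, 16])
    folds: int = 5
    pairwise_alpha: float = 0.0167
    omnibus_alpha: float = 0.05
    seed: int = 0
    output_dir: str = "outputs"

    def validate(self) -> None:
        for name in ("n_malignant", "n_benign", "n_normal"):
            v = getattr(self, name)
            if v and v < 2:
                raise InvalidInputError(f"{name} must be 0 or >= 2, got {v}")
        if self.snr <= 0:
            raise InvalidInputError(f"snr must be > 0, got {self.snr}")
        if self.folds < 2:
            raise InvalidInputError(f"folds must be >= 2, got {self.folds}")
        if self.voxels_per_lesion < 1:
            raise InvalidInputError("voxels_per_lesion must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
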