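"""Pipeline configuration with a frozen default profile.

The defaults pin the analysis contract: 180 s slices (trailing slice kept
from 60 s), 0.1 s interruption / 0.3 s pause thresholds, 25 ms / 10 ms
framing, 13 cepstral coefficients, 85% rolloff, and no audio retention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import DEFAULT_GRIDS


@dataclass
class PipelineConfig:
    slice_len_s: float = 180.0
    min_final_slice_s: float = 60.0
    min_overlap_s: float = 0.1
    min_gap_s: float = 0.3
    frame_len_ms: float = 25.0
    hop_ms: float = 10.0
    rolloff_percentile: float = 85.0
    n_mfcc: int = 13
    model_grids: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()})
    families: list = field(default_factory=lambda: ["LR", "DTC", "SVM-linear", "SVM-RBF", "RF", "GBDT"])
    seed: int = 0
    retain_audio: bool = False

    def __post_init__(self) -> None:
        for name in ("slice_len_s", "min_final_slice_s", "min_overlap_s",
                     "min_gap_s", "frame_len_ms", "hop_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.rolloff_percentile <= 100:
            raise ValueError("rolloff_percentile must be in (0, 100]")
        if self.n_mfcc < 1:
            raise ValueError("n_mfcc must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
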