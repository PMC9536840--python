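"""Run configuration: thresholds shared across the pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline thresholds and paths.

    All thresholds must be positive.  Defaults reproduce the analysis
    constants used throughout the pipeline (clump p-value cutoffs, the
    0.1 cM cross-trait merge radius, the 0.005 local-false-sign-rate
    cutoff for genetic-correlation pairs, and the gene-assignment window
    sizes in base pairs).
    """

    clump_p: float = 1e-4
    gw_p: float = 5e-8
    suggestive_p: float = 1e-4
    lfsr_cut: float = 0.005
    merge_cm: float = 0.1
    clump_r2: float = 0.01
    clump_window_bp: float = 1e6
    flank_bp: float = 1e5
    enzyme_flank_bp: float = 5e5
    fallback_flank_bp: float = 2e5
    seed: int = 0
    paths: dict = field(default_factory=dict)

    _THRESHOLDS = (
        "clump_p",
        "gw_p",
        "suggestive_p",
        "lfsr_cut",
        "merge_cm",
        "clump_r2",
        "clump_window_bp",
        "flank_bp",
        "enzyme_flank_bp",
        "fallback_flank_bp",
    )

    def __post_init__(self) -> None:
        for name in self._THRESHOLDS:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"threshold {name!r} must be positive, got {value}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short digest of the configuration, for run logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
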