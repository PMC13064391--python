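"""Run configuration with the pipeline's defaults in one place."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults: 60 s frame interval; 5-frame duration filter; 8-point
    tracklet window with stride 1; 2 µm/min arrest threshold; k = 5
    behavioral clusters; 40 µm band spacing. Every value is logged into the
    run manifest; unknown keys in a config file are rejected.
    """

    dt: float = 60.0                     # s/frame
    pixel_size: float = 1.0              # µm/px
    min_frames: int = 5
    window: int = 8
    stride: int = 1
    arrest_threshold: float = 2.0        # µm/min
    k: int = 5
    band_spacing_um: float = 40.0
    seed: int = 0
    planar: bool = False                 # drop z before computing metrics
    flow: dict = field(default_factory=lambda: {
        "algorithm": "ilk", "radius": 7, "num_warp": 10})
    umap: dict = field(default_factory=lambda: {
        "n_neighbors": 15, "min_dist": 0.1})
    kmeans: dict = field(default_factory=lambda: {"n_init": 10})
    out_dir: str = "ivmotion_run"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")
        if self.window < 2 or self.stride < 1:
            raise ValueError("window must be >= 2 and stride >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys raise."""
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
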