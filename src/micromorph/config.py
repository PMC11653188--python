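"""Validated pipeline configuration (YAML file + flag overrides).

Every tunable of every stage lives here so a run can be reproduced from
the single resolved config written next to its outputs.  Unknown keys are
rejected rather than ignored — a typo must not silently fall back to a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class IOConfig:
    masks_dir: str = ""
    metadata_csv: str | None = None
    annotations_json: str | None = None
    out_dir: str = "run"


@dataclass
class SegmentationConfig:
    binarize_threshold: int = 127
    min_area: int = 60
    connectivity: int = 8
    border_policy: str = "keep"
    gallery: bool = False


@dataclass
class MorphConfig:
    soma_opening_radius: int = 6
    sholl_step: float = 10.0
    diagonal_weight: float = 1.0


@dataclass
class RFEConfig:
    n_keep: int | None = None  # None -> half the features
    seed: int = 0


@dataclass
class UMAPConfig:
    n_neighbors: int = 10
    min_dist: float = 0.1
    n_components: int = 2
    seed: int = 0
    scale: bool = True


@dataclass
class HDBSCANConfig:
    min_cluster_size: int = 20
    min_samples: int = 10


@dataclass
class SpatialConfig:
    bin_start: float = 0.48
    bin_width: float = 0.24


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morphometry: MorphConfig = field(default_factory=MorphConfig)
    rfe: RFEConfig = field(default_factory=RFEConfig)
    umap: UMAPConfig = field(default_factory=UMAPConfig)
    hdbscan: HDBSCANConfig = field(default_factory=HDBSCANConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise ConfigError(f"unknown config section '{section}'")
            sub = getattr(cfg, section)
            if not isinstance(values, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            known = {f.name for f in fields(sub)}
            for key, val in values.items():
                if key not in known:
                    raise ConfigError(
                        f"unknown key '{section}.{key}' "
                        f"(known: {sorted(known)})"
                    )
                setattr(sub, key, val)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.segmentation.connectivity not in (4, 8):
            raise ConfigError("segmentation.connectivity must be 4 or 8")
        if self.segmentation.border_policy not in ("keep", "drop"):
            raise ConfigError("segmentation.border_policy must be keep|drop")
        if self.segmentation.min_area < 1:
            raise ConfigError("segmentation.min_area must be >= 1")
        if self.morphometry.sholl_step <= 0:
            raise ConfigError("morphometry.sholl_step must be positive")
        if not 0.0 <= self.umap.min_dist <= 1.0:
            raise ConfigError("umap.min_dist must be in [0,1]")
        if self.umap.n_neighbors < 2:
            raise ConfigError("umap.n_neighbors must be >= 2")
        if self.hdbscan.min_cluster_size < 2:
            raise ConfigError("hdbscan.min_cluster_size must be >= 2")
        if self.rfe.n_keep is not None and self.rfe.n_keep < 1:
            raise ConfigError("rfe.n_keep must be >= 1 or null")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
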