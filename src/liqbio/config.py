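"""Pipeline configuration: validated, hashable, YAML-serializable.

Defaults encode the assay geometry (two slides per test, thousands of frames
per slide reachable but not default) at a desk scale of 64 frames of
256x256 px at 1 um/px with ~100 cells per frame. Unknown keys are rejected on
load, and a SHA-256 hash of the canonical configuration is embedded in every
output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Strict):
    n_frames: int = Field(64, ge=1)
    cells_per_frame: float = Field(100.0, gt=0)
    frame_px: int = Field(256, ge=64)
    rare_fraction: float = Field(0.05, ge=0, le=1)
    n_debris_frames: int = Field(0, ge=0)
    n_utuc: int = Field(20, ge=1)
    n_nd: int = Field(50, ge=1)
    write_frames: bool = False


class GeometryConfig(_Strict):
    um_per_px: float = Field(1.0, gt=0)
    slides_per_test: int = Field(2, ge=1)
    frames_per_slide: int = Field(2304, ge=1)  # full-scan ceiling


class DetectionConfig(_Strict):
    min_nucleus_area_um2: float = Field(10.0, gt=0)
    halo_um: float = Field(2.5, gt=0)
    solidity_min: float = Field(0.7, ge=0, le=1)
    eccentricity_max: float = Field(0.95, ge=0, lt=1)


class GatingConfig(_Strict):
    # thresholds default to the synthetic mixture's population midpoints
    thresholds: dict[str, float] | None = None
    proximity_radius_um: float = Field(10.0, gt=0)
    lev_max_per_frame: int = Field(3, ge=0)
    lev_filter_mode: str = "drop"

    @model_validator(mode="after")
    def _check_mode(self):
        if self.lev_filter_mode not in ("drop", "cap"):
            raise ValueError("lev_filter_mode must be 'drop' or 'cap'")
        if self.thresholds is not None and any(
                v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")
        return self


class StatsConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    min_group: int = Field(4, ge=1)
    bh_correction: bool = False


class ClusterConfig(_Strict):
    k: int = Field(6, ge=1)
    perplexity: float = Field(30.0, gt=0)
    max_events: int = Field(2000, ge=10)  # subsample cap for the embedding


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "results/pipeline"
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    gating: GatingConfig = Field(default_factory=GatingConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)

    def config_hash(self) -> str:
        """Hash of the computational parameters; the output location is
        excluded so identical analyses hash identically wherever they run."""
        canon = json.dumps(self.model_dump(exclude={"output_dir"}),
                           sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
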