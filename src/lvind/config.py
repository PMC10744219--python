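"""Run configuration: validated YAML with documented defaults.

Unknown keys are rejected so typos fail loudly, and the effective
configuration is echoed (with a hash) into every report for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bullseye import ViewSegmentMap, WallSegments
from .contours import View
from .geometry import CenterRule


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    f_base: float = 0.5
    f_apex: float = 2.0 / 3.0
    center_mode: str = "continuous"  # or "discrete3"
    n_resample: int = Field(200, ge=20)

    def center_rule(self) -> CenterRule:
        return CenterRule(f_base=self.f_base, f_apex=self.f_apex, mode=self.center_mode)


class WallMapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    first_wall: tuple[int, int, int]
    second_wall: tuple[int, int, int]


class BullseyeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cap_fraction: float = Field(0.10, gt=0.0, lt=0.5)
    level_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    shared_segment_weighting: str = "view"  # or "points"
    view_map: dict[str, WallMapConfig] | None = None  # override, keys "2CH"/"3CH"/"4CH"

    def segment_map(self) -> ViewSegmentMap:
        if self.view_map is None:
            return ViewSegmentMap.default(self.cap_fraction, self.level_boundaries)
        walls = {
            View(k): (WallSegments(*v.first_wall), WallSegments(*v.second_wall))
            for k, v in self.view_map.items()
        }
        return ViewSegmentMap(walls, self.cap_fraction, self.level_boundaries)


class MetricsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_disks: int = Field(250, ge=20)
    bsa_formula: str = "dubois"  # or "mosteller"


class ClassificationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    akinesis_band_pct: float = 2.0
    hypokinesia_z: float = -1.96
    outlier_z: float = 1.96


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig = GeometryConfig()
    bullseye: BullseyeConfig = BullseyeConfig()
    metrics: MetricsConfig = MetricsConfig()
    classification: ClassificationConfig = ClassificationConfig()
    reference_segments_csv: str | None = None  # None -> packaged normal ranges
    reference_regions_csv: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        self.geometry.center_rule()  # validates fractions
        self.bullseye.segment_map()  # validates coverage of segments 1..17
        if self.metrics.bsa_formula not in ("dubois", "mosteller"):
            raise ValueError("bsa_formula must be 'dubois' or 'mosteller'")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; with no path, return the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(doc)
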