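"""Normal reference ranges for segmental InD and wall-motion classification.

The packaged ranges are the published normal values from a 120-subject
healthy-adult CMR cohort (mean and SD per AHA segment, plus basal /
mid-cavity / apical / overall region values). They let a measured
bullseye be z-scored segment by segment and each segment classified as
normal, hypokinetic, akinetic or dyskinetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .bullseye import Bullseye17, SEGMENT_NAMES, region_averages

_REGION_ROUNDING_TOL = 0.05  # one-decimal printed region means


class WallMotion(str, enum.Enum):
    NORMAL = "normal"
    HYPOKINETIC = "hypokinetic"
    AKINETIC = "akinetic"
    DYSKINETIC = "dyskinetic"


@dataclass(frozen=True)
class ReferenceRange:
    """Per-segment and per-region normal InD mean/SD (%)."""

    segments: pd.DataFrame  # index segment_id 1..17; segment_name, mean_pct, sd_pct
    regions: pd.DataFrame  # index base/mid/apex/overall; mean_pct, sd_pct

    def __post_init__(self) -> None:
        seg = self.segments
        if list(seg.index) != list(range(1, 18)):
            raise ValueError("reference must cover segments 1..17 exactly")
        if (seg["sd_pct"] <= 0).any() or (self.regions["sd_pct"] <= 0).any():
            raise ValueError("reference SDs must be positive")
        # self-consistency: region means must equal the segment-mean
        # arithmetic means within one-decimal rounding
        rm = region_averages(seg["mean_pct"].to_numpy())
        for name, got in zip(("base", "mid", "apex", "overall"), rm.astuple()):
            stated = float(self.regions.loc[name, "mean_pct"])
            if abs(got - stated) > _REGION_ROUNDING_TOL:
                raise ValueError(
                    f"region '{name}' mean {stated} inconsistent with segment means ({got:.3f})"
                )

    def entry(self, segment_id: int) -> tuple[float, float]:
        row = self.segments.loc[segment_id]
        return float(row["mean_pct"]), float(row["sd_pct"])

    @classmethod
    def packaged(cls) -> "ReferenceRange":
        """Load the reference ranges shipped with the package."""
        pkg = resources.files("lvind.data")
        seg = pd.read_csv(pkg / "reference_segments.csv").set_index("segment_id")
        reg = pd.read_csv(pkg / "reference_regions.csv").set_index("region")
        return cls(segments=seg, regions=reg)

    @classmethod
    def from_csv(cls, segments_path, regions_path) -> "ReferenceRange":
        return cls(
            segments=pd.read_csv(segments_path).set_index("segment_id"),
            regions=pd.read_csv(regions_path).set_index("region"),
        )


def zscore_bullseye(b: Bullseye17, ref: ReferenceRange, flag_z: float = 1.96) -> pd.DataFrame:
    """Z-score each segment against the normal range.

    Returns a frame indexed by segment id with the measured value, z score
    and an ``outside_band`` flag for |z| > ``flag_z`` (the 95 % reference
    band by default). Missing segments keep NaN z and are flagged missing.
    """
    rows = []
    for sid in range(1, 18):
        mean, sd = ref.entry(sid)
        value = b[sid]
        z = (value - mean) / sd if np.isfinite(value) else np.nan
        rows.append(
            {
                "segment_id": sid,
                "segment_name": SEGMENT_NAMES[sid],
                "ind_pct": value,
                "z": z,
                "outside_band": bool(np.isfinite(z) and abs(z) > flag_z),
                "missing": not np.isfinite(value),
            }
        )
    return pd.DataFrame(rows).set_index("segment_id")


def classify_wall_motion(
    ind_pct: float,
    ref_mean: float,
    ref_sd: float,
    akinesis_band_pct: float = 2.0,
    hypokinesia_z: float = -1.96,
) -> WallMotion:
    """Classify one segment's InD value.

    Negative InD is dyskinetic (paradoxical outward motion); values in
    [0, ``akinesis_band_pct``) are called akinetic; otherwise a z score
    below ``hypokinesia_z`` against the normal range is hypokinetic, and
    anything else is normal. Only the 0 % and negative anchors are
    published semantics; the two thresholds are package conventions.
    """
    if not np.isfinite(ind_pct):
        raise ValueError("cannot classify a non-finite InD value")
    if ind_pct < 0.0:
        return WallMotion.DYSKINETIC
    if ind_pct < akinesis_band_pct:
        return WallMotion.AKINETIC
    if (ind_pct - ref_mean) / ref_sd < hypokinesia_z:
        return WallMotion.HYPOKINETIC
    return WallMotion.NORMAL
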