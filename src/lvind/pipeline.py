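"""End-to-end subject analysis: contours -> bullseye + global metrics +
normal-range comparison."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bullseye import (
    Bullseye17,
    SEGMENT_NAMES,
    assign_segments,
    merge_views,
    segment_means,
)
from .config import RunConfig
from .contours import Phase, View
from .geometry import compute_view_ind
from .io import ContourSet
from .metrics import LvMetrics, derive_metrics
from .reference import ReferenceRange, classify_wall_motion, zscore_bullseye


@dataclass
class SubjectResult:
    """Everything the pipeline derives for one subject."""

    subject_id: str
    bullseye: Bullseye17
    per_view: dict[View, dict[int, tuple[float, int]]]
    metrics: LvMetrics | None
    comparison: pd.DataFrame | None  # z-scores + wall-motion classes, or None
    config: RunConfig
    warnings: list[str] = field(default_factory=list)

    def report_dict(self) -> dict:
        regions = self.bullseye.regions().rounded()
        doc = {
            "subject_id": self.subject_id,
            "segments": [
                {
                    "segment_id": sid,
                    "segment_name": SEGMENT_NAMES[sid],
                    "ind_pct": None if not np.isfinite(self.bullseye[sid]) else round(self.bullseye[sid], 3),
                    "n_points": int(self.bullseye.n_points[sid - 1]),
                }
                for sid in range(1, 18)
            ],
            "regions": {
                "base_pct": regions.base,
                "mid_pct": regions.mid,
                "apex_pct": regions.apex,
                "overall_pct": regions.overall,
            },
            "missing_segments": self.bullseye.missing,
            "warnings": self.warnings,
            "config": self.config.model_dump(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
        }
        if self.metrics is not None:
            doc["metrics"] = {
                "edv_ml": round(self.metrics.edv_ml, 2),
                "esv_ml": round(self.metrics.esv_ml, 2),
                "ef_pct": round(self.metrics.ef_pct, 2),
                "gls_pct": round(self.metrics.gls_pct, 2),
                "bsa_m2": None if self.metrics.bsa_m2 is None else round(self.metrics.bsa_m2, 3),
                "edvi_ml_m2": None if self.metrics.edvi_ml_m2 is None else round(self.metrics.edvi_ml_m2, 2),
                "esvi_ml_m2": None if self.metrics.esvi_ml_m2 is None else round(self.metrics.esvi_ml_m2, 2),
            }
        if self.comparison is not None:
            doc["reference_comparison"] = self.comparison.reset_index().to_dict(orient="records")
        return doc

    def bullseye_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": range(1, 18),
                "segment_name": [SEGMENT_NAMES[i] for i in range(1, 18)],
                "ind_pct": self.bullseye.seg_pct,
                "n_points": self.bullseye.n_points,
            }
        )


def analyze_subject(
    cs: ContourSet,
    config: RunConfig | None = None,
    height_cm: float | None = None,
    weight_kg: float | None = None,
    reference: ReferenceRange | None = None,
    compute_metrics: bool = True,
) -> SubjectResult:
    """Run the full InD pipeline on one subject's contour set.

    Views missing a phase are dropped with a warning; segments not covered
    by the remaining views are marked missing rather than invented.
    """
    config = config or RunConfig()
    rule = config.geometry.center_rule()
    vmap = config.bullseye.segment_map()
    notes: list[str] = []

    views = cs.views()
    if not views:
        raise ValueError("no view has both ED and ES contours")
    if len(views) < 3:
        absent = [v.value for v in (View.CH2, View.CH3, View.CH4) if v not in views]
        notes.append(f"partial analysis: missing views {absent}; uncovered segments marked missing")

    per_view: dict[View, dict[int, tuple[float, int]]] = {}
    for view in views:
        res = compute_view_ind(
            cs.contours[(view, Phase.ED)],
            cs.contours[(view, Phase.ES)],
            rule=rule,
            n=config.geometry.n_resample,
            paired=cs.paired,
        )
        assignment = assign_segments(res.p_ed, res.axis, vmap, view)
        per_view[view] = segment_means(res.ind_pct, assignment)

    bullseye = merge_views(
        per_view,
        weighting=config.bullseye.shared_segment_weighting,
        strict=(len(views) == 3),
    )

    metrics = None
    if compute_metrics:
        metrics = derive_metrics(
            cs.phase_map(Phase.ED),
            cs.phase_map(Phase.ES),
            n_disks=config.metrics.n_disks,
            height_cm=height_cm,
            weight_kg=weight_kg,
            bsa_formula=config.metrics.bsa_formula,
        )

    comparison = None
    if reference is not None:
        comparison = zscore_bullseye(bullseye, reference, flag_z=config.classification.outlier_z)
        classes = []
        for sid in range(1, 18):
            value = bullseye[sid]
            if not np.isfinite(value):
                classes.append(None)
                continue
            mean, sd = reference.entry(sid)
            classes.append(
                classify_wall_motion(
                    value,
                    mean,
                    sd,
                    akinesis_band_pct=config.classification.akinesis_band_pct,
                    hypokinesia_z=config.classification.hypokinesia_z,
                ).value
            )
        comparison = comparison.assign(wall_motion=classes)

    return SubjectResult(cs.subject_id, bullseye, per_view, metrics, comparison, config, notes)


def write_report(result: SubjectResult, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json and bullseye.csv for one subject; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{result.subject_id}_report.json"
    csv_path = out / f"{result.subject_id}_bullseye.csv"
    json_path.write_text(json.dumps(result.report_dict(), indent=2))
    result.bullseye_frame().to_csv(csv_path, index=False)
    return {"report": json_path, "bullseye": csv_path}
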