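"""Contour-set and report I/O.

Contour schema (JSON):

.. code-block:: json

    {"subject_id": "S001",
     "paired": false,
     "views": [{"view": "2CH", "phase": "ED", "points_mm": [[x, y], ...]}, ...]}

Coordinates are physical millimetres in the view plane; the polyline runs
annulus -> apex -> annulus and y increases toward the apex. The long CSV
equivalent has columns subject_id, view, phase, point_index, x_mm, y_mm.
``paired`` declares that ED and ES point indices are matched (externally
tracked pairs); otherwise correspondence is established by arc-length
resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import LaxContour, Phase, View


@dataclass(frozen=True)
class ContourSet:
    """All contours of one subject, keyed by (view, phase)."""

    subject_id: str
    contours: dict[tuple[View, Phase], LaxContour]
    paired: bool = False

    def views(self) -> list[View]:
        """Views for which both phases are present."""
        return [
            v
            for v in (View.CH2, View.CH3, View.CH4)
            if (v, Phase.ED) in self.contours and (v, Phase.ES) in self.contours
        ]

    def phase_map(self, phase: Phase) -> dict[View, LaxContour]:
        return {v: self.contours[(v, phase)] for v in self.views()}


def read_contours(path: str | Path, paired: bool | None = None) -> ContourSet:
    """Read a contour set from JSON or long-format CSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path, paired)
    if path.suffix.lower() == ".csv":
        return _read_csv(path, paired)
    raise ValueError(f"unsupported contour file extension: {path.suffix!r}")


def _read_json(path: Path, paired: bool | None) -> ContourSet:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        subject_id = doc["subject_id"]
        entries = doc["views"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed contour JSON, missing {exc}") from exc
    contours = {}
    for i, entry in enumerate(entries):
        try:
            view = View(entry["view"])
            phase = Phase(entry["phase"])
            pts = np.asarray(entry["points_mm"], dtype=float)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: views[{i}] is malformed: {exc}") from exc
        contours[(view, phase)] = LaxContour(view, phase, pts)
    return ContourSet(
        subject_id=str(subject_id),
        contours=contours,
        paired=bool(doc.get("paired", False) if paired is None else paired),
    )


def _read_csv(path: Path, paired: bool | None) -> ContourSet:
    df = pd.read_csv(path)
    required = {"subject_id", "view", "phase", "point_index", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"{path}: expected one subject per file, found {len(subjects)}")
    contours = {}
    for (view_s, phase_s), grp in df.groupby(["view", "phase"], sort=False):
        grp = grp.sort_values("point_index")
        view, phase = View(view_s), Phase(phase_s)
        contours[(view, phase)] = LaxContour(
            view, phase, grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        )
    return ContourSet(str(subjects[0]), contours, paired=bool(paired or False))


def write_contours(cs: ContourSet, path: str | Path) -> None:
    """Write a contour set as JSON or long CSV (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "subject_id": cs.subject_id,
            "paired": cs.paired,
            "views": [
                {
                    "view": c.view.value,
                    "phase": c.phase.value,
                    "points_mm": c.points.tolist(),
                }
                for c in cs.contours.values()
            ],
        }
        path.write_text(json.dumps(doc))
    elif path.suffix.lower() == ".csv":
        rows = []
        for c in cs.contours.values():
            for i, (x, y) in enumerate(c.points):
                rows.append(
                    {
                        "subject_id": cs.subject_id,
                        "view": c.view.value,
                        "phase": c.phase.value,
                        "point_index": i,
                        "x_mm": x,
                        "y_mm": y,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported contour file extension: {path.suffix!r}")
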