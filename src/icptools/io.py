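"""Text I/O for ICP matrices, ground-truth marks, results and configs.

Conventions (documented here once, used everywhere): all times in files are
seconds; all indices are 0-based frame indices; CSV is comma-separated with
"." decimals and optional ``#``-prefixed comment lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    ArtifactMask,
    ClassLabel,
    EventSet,
    CandidateEvent,
    FormatError,
    GroundTruthMarks,
    Recording,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["read_icp_matrix", "write_icp_matrix", "read_gt_marks",
           "write_gt_marks", "write_results", "read_results"]


def _auto_cell_ids(n: int) -> list[str]:
    return [f"cell_{i + 1:04d}" for i in range(n)]


def read_icp_matrix(
    path: str | Path,
    orientation: str = "rows_are_cells",
    sample_period_s: float = 3.0,
) -> Recording:
    """Read a CSV matrix of ratio values into a :class:`Recording`.

    The file may carry a header row and/or a leading identifier column;
    both are detected by non-numeric content. ``orientation`` states what
    the file rows are; the returned traces are always cells x frames.
    """
    if orientation not in ("rows_are_cells", "rows_are_frames"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append([f.strip() for f in line.split(",")])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    for r in rows:
        if len(r) != width:
            raise FormatError(
                f"{path}: ragged rows (expected {width} fields, got {len(r)})"
            )

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    # header row: any non-numeric field beyond a possible id column
    has_header = not all(_is_number(f) for f in rows[0][1:])
    body = rows[1:] if has_header else rows
    if not body:
        raise FormatError(f"{path}: header but no data rows")
    has_id_col = not _is_number(body[0][0])

    labels = [r[0] for r in body] if has_id_col else None
    start = 1 if has_id_col else 0
    data = np.empty((len(body), width - start), dtype=float)
    for i, r in enumerate(body):
        for j, f in enumerate(r[start:]):
            try:
                data[i, j] = float(f)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {f!r} at data row {i + 1}, "
                    f"column {j + start + 1}"
                ) from None

    if orientation == "rows_are_frames":
        data = data.T
        cell_ids = (rows[0][start:] if has_header else None)
    else:
        cell_ids = labels
    if cell_ids is None:
        cell_ids = _auto_cell_ids(data.shape[0])
    if data.shape[1] < 2:
        raise ValidationError(f"{path}: fewer than 2 frames")
    return Recording(traces=data, cell_ids=list(cell_ids),
                     sample_period_s=sample_period_s)


def write_icp_matrix(rec: Recording, path: str | Path) -> None:
    """Write a recording as rows-are-cells CSV with an id column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# ICP matrix: rows are cells, columns are frames; "
                 f"sample_period_s={rec.sample_period_s:g}\n")
        header = ",".join(["cell_id"] + [f"f{i}" for i in range(rec.n_frames)])
        fh.write(header + "\n")
        for cid, row in zip(rec.cell_ids, rec.traces):
            fh.write(cid + "," + ",".join(f"{v:.6f}" for v in row) + "\n")


def read_gt_marks(path: str | Path) -> GroundTruthMarks:
    """Read expert event markers from a ``cell_id,time_s`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"cell_id": str})
    required = {"cell_id", "time_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if len(df) and (df["time_s"] < 0).any():
        raise ValidationError(f"{path}: negative marker time")
    marks: dict[str, np.ndarray] = {}
    for cell, grp in df.groupby("cell_id", sort=False):
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        uniq = np.unique(t)
        if len(uniq) != len(t):
            logger.warning("duplicate ground-truth marks for cell %s dropped", cell)
        marks[str(cell)] = uniq
    return GroundTruthMarks(marks)


def write_gt_marks(gt: GroundTruthMarks, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cell_id,time_s\n")
        for cell, times in gt.marks.items():
            for t in times:
                fh.write(f"{cell},{t:g}\n")


def _event_record(e: CandidateEvent, ts: float) -> dict:
    return {
        "frame": int(e.report_index),
        "time_s": float(e.report_index * ts),
        "max_index": int(e.max_index),
        "min_index": int(e.min_index),
        "lp": float(e.lp),
        "value_max": float(e.value_max),
        "value_min": float(e.value_min),
        "above_threshold": bool(e.above_threshold),
        "artifact_discarded": bool(e.artifact_discarded),
        "shifted": bool(e.shifted),
    }


def write_results(
    events: EventSet,
    classes: Mapping[str, ClassLabel],
    mask: ArtifactMask | None,
    path: str | Path,
    params: Mapping | None = None,
    sample_period_s: float = 3.0,
    injury_frame: int | None = None,
) -> None:
    """Write a lossless JSON report of the full analysis.

    The report embeds the parameter set used so a run can be reproduced
    from its own output.
    """
    cells = {}
    ids = set(events.events) | set(classes)
    for cid in sorted(ids):
        cells[cid] = {
            "events": [_event_record(e, sample_period_s) for e in events.cell(cid)],
            "class": classes[cid].code if cid in classes else 0,
        }
    doc = {
        "format": "icptools-results-v1",
        "sample_period_s": sample_period_s,
        "injury_frame": injury_frame,
        "artifact_frames": ([] if mask is None
                            else [int(i) for i in mask.flagged_frames()]),
        "params": dict(params or {}),
        "cells": cells,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_results(path: str | Path) -> dict:
    """Read back a results report; inverse of :func:`write_results`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "icptools-results-v1":
        raise FormatError(f"{path}: not an icptools results file")
    return doc


def results_to_events(doc: dict) -> tuple[EventSet, dict[str, ClassLabel]]:
    """Rebuild the in-memory event set and labels from a results report."""
    events: dict[str, list[CandidateEvent]] = {}
    classes: dict[str, ClassLabel] = {}
    for cid, cell in doc["cells"].items():
        events[cid] = [
            CandidateEvent(
                cell_id=cid,
                max_index=r["max_index"],
                min_index=r["min_index"],
                lp=r["lp"],
                value_max=r["value_max"],
                value_min=r["value_min"],
                above_threshold=r["above_threshold"],
                artifact_discarded=r["artifact_discarded"],
                shifted=r["shifted"],
                report_index=r["frame"],
            )
            for r in cell["events"]
        ]
        classes[cid] = ClassLabel.from_code(cell["class"])
    return EventSet(events), classes
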