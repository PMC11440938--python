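"""End-to-end per-field analysis and batch orchestration.

`analyze_field` chains segmentation, detection and mapping for one field and
returns both the intermediate objects and flat result tables; `run_batch`
applies it over a directory of fields, isolating per-field failures, and
writes the aggregated tables, the manifest and a copy of the settings file
used.
"""

from __future__ import annotations

import datetime
import traceback
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .detect import Detection, detect_organelles
from .io import (FieldImage, read_field, write_tables,
                 CELLS_COLUMNS, DETECTIONS_COLUMNS, PROFILES_COLUMNS,
                 FIELD_SUMMARY_COLUMNS)
from .mapping import (CellRecord, FieldSummary, IntensityProfile, compute_edm,
                      estimate_background, intensity_profile, measure_cell,
                      measure_detection)
from .segment import LabelMask, match_nuclei_to_cells, segment_cells, \
    segment_nuclei, unfiltered_cell_mask
from .settings import Settings, write_settings

__all__ = ["FieldResult", "RunManifest", "analyze_field", "run_batch",
           "field_result_tables"]


@dataclass
class FieldResult:
    """All per-field analysis products."""

    field: FieldImage
    nuclei: LabelMask
    cells: LabelMask
    cell_records: list[CellRecord]
    detections: list[Detection]
    profiles: dict[int, IntensityProfile]
    summary: FieldSummary


@dataclass
class RunManifest:
    """Per-field status record of a batch run."""

    rows: list[dict] = dc_field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def add(self, field_id: str, status: str, reason: str = "") -> None:
        self.rows.append({"field_id": field_id, "status": status, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["field_id", "status", "reason"])
        df["version"] = self.version
        df["timestamp"] = self.timestamp
        return df


def analyze_field(field: FieldImage, settings: Settings,
                  nuclei: Optional[LabelMask] = None,
                  cells: Optional[LabelMask] = None,
                  external_detections: Optional[np.ndarray] = None) -> FieldResult:
    """Segment, detect and map one field.

    External label masks or detection points (from other tools) can replace
    the internal segmentation/detection stages.
    """
    seg = settings.segmentation
    if nuclei is None:
        nuclei = segment_nuclei(field, seg)
    raw_mask = unfiltered_cell_mask(field, seg)
    if cells is None:
        cells = segment_cells(field, nuclei, seg)
    total_cells = int(np.max(cells.labels)) if cells.n_instances else 0
    summary = estimate_background(field, raw_mask, total_cell_count=total_cells)

    if external_detections is not None:
        detections = []
        for x, y in np.asarray(external_detections, dtype=float):
            xi, yi = int(round(x)), int(round(y))
            cid = int(cells.labels[yi, xi])
            if cid == 0:
                continue
            if settings.detection.exclude_in_nucleus and nuclei.labels[yi, xi] > 0:
                continue
            detections.append(Detection(x=xi, y=yi, cell_id=cid))
    else:
        detections = detect_organelles(field, cells, nuclei, settings.detection)

    cell_to_nucleus = match_nuclei_to_cells(nuclei, cells)
    records: list[CellRecord] = []
    profiles: dict[int, IntensityProfile] = {}
    per_cell_detections: dict[int, list[Detection]] = {}
    for det in detections:
        per_cell_detections.setdefault(det.cell_id, []).append(det)

    for cid in cells.instance_ids:
        cid = int(cid)
        nid = cell_to_nucleus.get(cid)
        if nid is None:  # cannot happen for internal segmentation
            warnings.warn(f"cell {cid} has no matched nucleus; skipped", stacklevel=2)
            continue
        cell_mask = cells.mask(cid)
        nucleus_mask = nuclei.mask(nid) & cell_mask
        record = measure_cell(cell_mask, nucleus_mask, field, cell_id=cid)
        dmap = compute_edm(cell_mask, nucleus_mask, field.pixel_size)
        for det in per_cell_detections.get(cid, []):
            measure_detection(det, record, dmap, field)
        record.detection_count = len(per_cell_detections.get(cid, []))
        profiles[cid] = intensity_profile(
            cell_mask, nucleus_mask, dmap, field,
            bin_width=settings.analysis.intensity_bin_width, cell_id=cid)
        records.append(record)

    return FieldResult(field=field, nuclei=nuclei, cells=cells,
                       cell_records=records, detections=detections,
                       profiles=profiles, summary=summary)


def field_result_tables(result: FieldResult) -> dict[str, pd.DataFrame]:
    """Flatten a FieldResult into the four standard result tables."""
    fid = result.field.field_id
    px = result.field.pixel_size
    cells_rows = [{
        "field_id": fid, "cell_id": r.cell_id, "area_um2": r.area_um2,
        "feret_um": r.feret_um,
        "nucleus_com_x_px": r.nucleus_com[0], "nucleus_com_y_px": r.nucleus_com[1],
        "mean_organelle_intensity": r.mean_organelle_intensity,
        "mean_measurement_intensity": r.mean_measurement_intensity,
        "detection_count": r.detection_count,
    } for r in result.cell_records]
    det_rows = [{
        "field_id": fid, "cell_id": d.cell_id, "x_px": d.x, "y_px": d.y,
        "distance_raw_px": (None if d.raw_distance_um is None else d.raw_distance_um / px),
        "distance_um": d.raw_distance_um,
        "distance_normalized": d.normalized_distance,
        "organelle_peak": d.organelle_peak, "measurement_peak": d.measurement_peak,
        "angle_deg": d.angle_deg,
    } for d in result.detections]
    prof_rows = []
    for cid, p in result.profiles.items():
        for i in range(len(p.bin_centers)):
            prof_rows.append({
                "field_id": fid, "cell_id": cid,
                "bin_center_um": p.bin_centers[i],
                "mean_organelle_intensity": p.bin_mean_organelle[i],
                "mean_measurement_intensity": (
                    None if p.bin_mean_measurement is None else p.bin_mean_measurement[i]),
                "pixel_count": p.bin_pixel_count[i],
            })
    summary_rows = [{
        "field_id": fid, "total_cell_count": result.summary.total_cell_count,
        "background_mean_organelle": result.summary.background_mean_organelle,
        "background_mean_measurement": result.summary.background_mean_measurement,
    }]
    return {
        "cells": pd.DataFrame(cells_rows, columns=CELLS_COLUMNS),
        "detections": pd.DataFrame(det_rows, columns=DETECTIONS_COLUMNS),
        "profiles": pd.DataFrame(prof_rows, columns=PROFILES_COLUMNS),
        "field_summary": pd.DataFrame(summary_rows, columns=FIELD_SUMMARY_COLUMNS),
    }


def run_batch(input_dir: str | Path, settings: Settings,
              output_dir: str | Path) -> RunManifest:
    """Analyze every multi-channel TIFF field in *input_dir*.

    Per-field failures are recorded in the manifest and do not abort the run;
    result tables, the manifest and a copy of the settings are written to
    *output_dir*.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF fields found in {input_dir}")

    manifest = RunManifest(timestamp=datetime.datetime.now().isoformat(timespec="seconds"))
    tables: dict[str, list[pd.DataFrame]] = {
        "cells": [], "detections": [], "profiles": [], "field_summary": []}
    for path in paths:
        try:
            field = read_field(path, settings.channel_roles, settings.pixel_size)
            result = analyze_field(field, settings)
            for key, df in field_result_tables(result).items():
                tables[key].append(df)
            manifest.add(field.field_id, "ok")
        except Exception as exc:  # fault isolation per field
            manifest.add(path.stem, "failed", f"{type(exc).__name__}: {exc}")
            warnings.warn(f"field {path.stem} failed: {traceback.format_exc(limit=3)}",
                          stacklevel=2)

    def _concat(key, columns):
        frames = tables[key]
        return pd.concat(frames, ignore_index=True) if frames \
            else pd.DataFrame(columns=columns)

    write_tables(_concat("cells", CELLS_COLUMNS),
                 _concat("detections", DETECTIONS_COLUMNS),
                 _concat("profiles", PROFILES_COLUMNS),
                 _concat("field_summary", FIELD_SUMMARY_COLUMNS),
                 output_dir)
    manifest.to_frame().to_csv(output_dir / "manifest.csv", index=False)
    write_settings(settings, output_dir / "settings.xml")
    return manifest
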