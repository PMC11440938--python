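"""Image and table input/output.

The on-disk contract of the pipeline: calibrated multi-channel TIFF fields in,
TIFF label masks, CSV result tables and XML settings out.  Coordinates are
0-based with x = column and y = row, origin at the top-left pixel; distances
are reported in micrometres (columns in pixels are kept alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "FieldImage",
    "read_field",
    "write_field",
    "load_external_labels",
    "load_external_detections",
    "write_tables",
    "CELLS_COLUMNS",
    "DETECTIONS_COLUMNS",
    "PROFILES_COLUMNS",
    "FIELD_SUMMARY_COLUMNS",
]

REQUIRED_ROLES = ("nucleus", "cytoplasm", "organelle")


@dataclass
class FieldImage:
    """One calibrated 2D multi-channel field of view.

    ``channels`` has shape (C, H, W); ``channel_roles`` maps the roles
    ``nucleus`` / ``cytoplasm`` / ``organelle`` (and optionally
    ``measurement``) to channel indices; ``pixel_size`` is in um/pixel.
    """

    channels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size: float = 1.0
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ValueError(
                f"channels must be a (C, H, W) array, got shape {self.channels.shape}; "
                "3D stacks are unsupported (maximum-project upstream)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        missing = set(REQUIRED_ROLES) - set(self.channel_roles)
        if missing:
            raise ValueError(f"missing required channel roles: {sorted(missing)}")
        n = self.channels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n:
                raise ValueError(f"channel index {idx} for role {role!r} out of range (C={n})")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the field."""
        return self.channels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the channel for *role*; KeyError if the role is absent."""
        return self.channels[self.channel_roles[role]]

    @property
    def nucleus(self) -> np.ndarray:
        return self.channel("nucleus")

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.channel("cytoplasm")

    @property
    def organelle(self) -> np.ndarray:
        return self.channel("organelle")

    @property
    def measurement(self) -> Optional[np.ndarray]:
        if "measurement" in self.channel_roles:
            return self.channel("measurement")
        return None


def _read_plane(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr


def read_field(paths: str | Path | Sequence[str | Path],
               channel_roles: dict[str, int],
               pixel_size: float = 1.0,
               field_id: str | None = None) -> FieldImage:
    """Read a field from a multi-channel TIFF or a list of per-channel TIFFs.

    For a single path the file must hold a (C, H, W) or (H, W, C) stack (the
    smaller axis is taken as channels); for a list, each file holds one 2D
    plane and list order defines channel order.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
        arr = _read_plane(paths[0])
        if arr.ndim == 2:
            arr = arr[None]
        elif arr.ndim == 3:
            if arr.shape[-1] < arr.shape[0]:
                arr = np.moveaxis(arr, -1, 0)
        else:
            raise ValueError(f"unsupported image dimensionality {arr.ndim} in {paths[0]}; "
                             "only 2D multi-channel images are supported")
    else:
        planes = []
        for p in paths:
            plane = _read_plane(p)
            if plane.ndim != 2:
                raise ValueError(f"per-channel file {p} is not a single 2D plane "
                                 f"(shape {plane.shape})")
            planes.append(plane)
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise ValueError(f"per-channel images have mismatched shapes: {sorted(shapes)}")
        arr = np.stack(planes)
    if field_id is None:
        field_id = Path(paths[0]).stem
    return FieldImage(arr, dict(channel_roles), pixel_size, field_id)


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a field as a multi-channel (C, H, W) TIFF."""
    path = Path(path)
    tifffile.imwrite(str(path), field.channels, photometric="minisblack")
    return path


def load_external_labels(path: str | Path, field: FieldImage):
    """Load an externally produced instance segmentation as a label mask.

    Instance images (distinct positive integers per object) are used as-is;
    binary masks (exactly one positive value) are split into instances by
    8-connected component labeling.  Float images and geometry mismatches are
    rejected.
    """
    from .segment import LabelMask  # local import to avoid a cycle

    arr = _read_plane(path)
    if arr.ndim != 2:
        raise ValueError(f"label image {path} must be 2D, got shape {arr.shape}")
    if arr.shape != field.shape:
        raise ValueError(f"label image shape {arr.shape} does not match field {field.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label image {path} must be integer-valued, got dtype {arr.dtype}")
    if arr.min() < 0:
        raise ValueError("label image contains negative values")
    values = np.unique(arr)
    positive = values[values > 0]
    if positive.size == 1:
        labels, _ = ndi.label(arr > 0, structure=np.ones((3, 3), dtype=int))
    else:
        labels = arr.astype(np.int32)
    return LabelMask(labels, pixel_size=field.pixel_size)


def load_external_detections(path: str | Path, field: FieldImage) -> np.ndarray:
    """Load externally produced point detections from a mask image.

    Each foreground connected component yields one point at its centroid
    (paper-style masks mark each detection with a single pixel of value 255).
    Returns an (N, 2) float array of (x, y) coordinates.
    """
    arr = _read_plane(path)
    if arr.ndim != 2 or arr.shape != field.shape:
        raise ValueError(f"detection mask shape {arr.shape} does not match field {field.shape}")
    labels, n = ndi.label(arr > 0, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2), dtype=float)
    centroids = ndi.center_of_mass(arr > 0, labels, range(1, n + 1))
    # center_of_mass returns (row, col) = (y, x)
    return np.array([(c, r) for r, c in centroids], dtype=float)


CELLS_COLUMNS = [
    "field_id", "cell_id", "area_um2", "feret_um",
    "nucleus_com_x_px", "nucleus_com_y_px",
    "mean_organelle_intensity", "mean_measurement_intensity", "detection_count",
]
DETECTIONS_COLUMNS = [
    "field_id", "cell_id", "x_px", "y_px",
    "distance_raw_px", "distance_um", "distance_normalized",
    "organelle_peak", "measurement_peak", "angle_deg",
]
PROFILES_COLUMNS = [
    "field_id", "cell_id", "bin_center_um",
    "mean_organelle_intensity", "mean_measurement_intensity", "pixel_count",
]
FIELD_SUMMARY_COLUMNS = [
    "field_id", "total_cell_count",
    "background_mean_organelle", "background_mean_measurement",
]


def write_tables(cells: pd.DataFrame, detections: pd.DataFrame,
                 profiles: pd.DataFrame, field_summary: pd.DataFrame,
                 outdir: str | Path) -> dict[str, Path]:
    """Write the four result tables with documented headers.

    Row order is deterministic: (field_id, cell_id) then (x, y) / bin center,
    so re-running an identical analysis produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = {
        "cells.csv": (cells, CELLS_COLUMNS, ["field_id", "cell_id"]),
        "detections.csv": (detections, DETECTIONS_COLUMNS,
                           ["field_id", "cell_id", "x_px", "y_px"]),
        "intensity_profiles.csv": (profiles, PROFILES_COLUMNS,
                                   ["field_id", "cell_id", "bin_center_um"]),
        "field_summary.csv": (field_summary, FIELD_SUMMARY_COLUMNS, ["field_id"]),
    }
    written: dict[str, Path] = {}
    for name, (df, columns, sort_keys) in specs.items():
        df = df.copy() if len(df) else pd.DataFrame(columns=columns)
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"{name}: missing columns {sorted(missing)}")
        df = df[columns]
        if len(df):
            df = df.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.6g")
        written[name] = path
    return written
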