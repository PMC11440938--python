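"""Laplacian-of-Gaussian organelle detection.

Blob-shaped organelles are enhanced with a scale-normalized LoG filter
(response = -sigma^2 * gaussian_laplace, so bright blobs on a dark background
produce positive maxima with amplitude comparable across sigmas) and localized
as prominence-filtered local maxima: a maximum is kept when it stands at least
``prominence`` above the highest saddle connecting it to a higher maximum;
plateau maxima are merged to their centroid.  Maxima on the image border are
discarded (undefined filter support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .io import FieldImage
from .segment import LabelMask
from .settings import DetectionSettings

__all__ = ["Detection", "log_response", "find_maxima", "detect_organelles",
           "preview_overlay"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Detection:
    """One detected organelle.

    Positions are pixel coordinates (x = column, y = row).  Distance and
    intensity fields are filled by the mapping stage; ``raw_distance_um`` is
    the Euclidean distance to the nucleus edge and ``normalized_distance`` is
    that distance divided by the owning cell's Feret diameter.
    """

    x: int
    y: int
    cell_id: int = 0
    raw_distance_um: Optional[float] = None
    normalized_distance: Optional[float] = None
    organelle_peak: Optional[float] = None
    measurement_peak: Optional[float] = None
    angle_deg: Optional[float] = None


def log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized LoG response; positive at bright blobs."""
    return -sigma ** 2 * ndi.gaussian_laplace(np.asarray(image, dtype=float), sigma)


def _prominence_maxima(image: np.ndarray, prominence: float) -> np.ndarray:
    """Binary mask of maxima with topographic prominence >= *prominence*.

    Regional maxima of the h-maxima transform (morphological reconstruction
    of image - h under image): maxima whose connecting saddle lies within
    *prominence* of each other merge into a single flat plateau, matching
    ImageJ's find-maxima noise-tolerance semantics.
    """
    if prominence <= 0:
        return morphology.local_maxima(image, footprint=_EIGHT)
    rec = morphology.reconstruction(image - prominence, image, method="dilation",
                                    footprint=_EIGHT)
    return morphology.local_maxima(rec, footprint=_EIGHT)


def find_maxima(response: np.ndarray, prominence: float) -> np.ndarray:
    """Prominence-filtered local maxima of *response*.

    Returns an (N, 2) float array of (x, y) plateau centroids, excluding
    maxima whose plateau touches the image border.
    """
    peaks = _prominence_maxima(response, prominence)
    labels, n = ndi.label(peaks, structure=_EIGHT)
    if n == 0:
        return np.empty((0, 2), dtype=float)
    h, w = response.shape
    points = []
    for idx, (r, c) in enumerate(ndi.center_of_mass(peaks, labels, range(1, n + 1)), start=1):
        rows, cols = np.nonzero(labels == idx)
        if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
            continue
        points.append((c, r))
    return np.array(points, dtype=float) if points else np.empty((0, 2), dtype=float)


def detect_organelles(field: FieldImage, cells: LabelMask, nuclei: LabelMask,
                      settings: DetectionSettings) -> list[Detection]:
    """Detect organelles inside surviving cells.

    Maxima of the LoG response are kept when they fall inside a cell instance
    and (when ``exclude_in_nucleus``) outside every nucleus; each detection is
    assigned the id of its cell.
    """
    if cells.labels.shape != field.shape or nuclei.labels.shape != field.shape:
        raise ValueError("mask geometry does not match the field")
    response = log_response(field.organelle, settings.log_sigma)
    points = find_maxima(response, settings.prominence)
    detections: list[Detection] = []
    for x, y in points:
        xi, yi = int(round(x)), int(round(y))
        cid = int(cells.labels[yi, xi])
        if cid == 0:
            continue
        if settings.exclude_in_nucleus and nuclei.labels[yi, xi] > 0:
            continue
        detections.append(Detection(x=xi, y=yi, cell_id=cid))
    occupied = {d.cell_id for d in detections}
    for cid in cells.instance_ids:
        if int(cid) not in occupied:
            warnings.warn(f"field {field.field_id!r}: cell {int(cid)} has 0 detections",
                          stacklevel=2)
    return detections


def preview_overlay(field: FieldImage, cells: LabelMask, nuclei: LabelMask,
                    detections: list[Detection], cross_radius: int = 3) -> np.ndarray:
    """QC overlay: organelle channel with outlines and detection crosses.

    Cell outlines are drawn in green, nucleus outlines in blue and each
    detection as a white cross; the output RGB image has the field's size.
    """
    from skimage.segmentation import find_boundaries

    raw = field.organelle
    if np.issubdtype(raw.dtype, np.integer):
        top = float(np.iinfo(raw.dtype).max)
    else:
        top = float(raw.max()) or 1.0
    gray = np.clip(raw.astype(float) / top * 255.0, 0, 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    cell_edges = find_boundaries(cells.labels, mode="inner")
    nuc_edges = find_boundaries(nuclei.labels, mode="inner")
    rgb[cell_edges] = (0, 255, 0)
    rgb[nuc_edges] = (60, 60, 255)
    h, w = gray.shape
    for det in detections:
        x0, x1 = max(det.x - cross_radius, 0), min(det.x + cross_radius, w - 1)
        y0, y1 = max(det.y - cross_radius, 0), min(det.y + cross_radius, h - 1)
        rgb[det.y, x0:x1 + 1] = (255, 255, 255)
        rgb[y0:y1 + 1, det.x] = (255, 255, 255)
    return rgb
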