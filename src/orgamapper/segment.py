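"""Nucleus and single-cell segmentation.

Nuclei are segmented on the nucleus channel by median filtering, rolling-ball
background subtraction, an automatic global threshold and optional binary
erosions; instances touching the field border or failing the size/circularity
filter are rejected.  Cells are segmented on the cytoplasm channel (optionally
inverted for membrane stains) with a fixed threshold, then separated by a
marker-controlled watershed seeded at the nuclei; cells failing the
size/circularity filter or not containing exactly one surviving nucleus are
rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, restoration, segmentation as skseg
from skimage.morphology import disk

from .io import FieldImage
from .settings import SegmentationSettings

__all__ = ["LabelMask", "segment_nuclei", "segment_cells", "unfiltered_cell_mask",
           "circularity"]

_THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "li": filters.threshold_li,
    "yen": filters.threshold_yen,
    "triangle": filters.threshold_triangle,
    "mean": filters.threshold_mean,
    "isodata": filters.threshold_isodata,
}

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class LabelMask:
    """Instance-label image (background 0, instances 1..n) with calibration."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D integer image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_ids.size)

    def mask(self, instance_id: int) -> np.ndarray:
        """Binary mask of one instance."""
        return self.labels == instance_id

    def regionprops(self):
        return measure.regionprops(self.labels)


def circularity(region) -> float:
    """ImageJ-style circularity 4*pi*A/P^2 of a regionprops region, clamped to 1."""
    p = region.perimeter
    if p == 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * region.area / p ** 2))


def _preprocess(channel: np.ndarray, median_radius: int, rolling_ball_radius: int,
                invert: bool = False) -> np.ndarray:
    img = np.asarray(channel)
    if invert:
        if np.issubdtype(img.dtype, np.integer):
            img = np.iinfo(img.dtype).max - img
        else:
            img = img.max() - img
    if median_radius > 0:
        img = filters.median(img, footprint=disk(median_radius))
    if rolling_ball_radius > 0:
        background = restoration.rolling_ball(img, radius=rolling_ball_radius)
        img = img - np.minimum(background, img)
    return img


def _filter_instances(binary: np.ndarray, pixel_size: float,
                      size_range: tuple[float, float],
                      circularity_range: tuple[float, float],
                      reject_border: bool,
                      structure: np.ndarray = _EIGHT) -> np.ndarray:
    labels, _ = ndi.label(binary, structure=structure)
    h, w = labels.shape
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for region in measure.regionprops(labels):
        if reject_border:
            minr, minc, maxr, maxc = region.bbox
            if minr == 0 or minc == 0 or maxr == h or maxc == w:
                continue
        area_um2 = region.area * pixel_size ** 2
        if not size_range[0] <= area_um2 <= size_range[1]:
            continue
        circ = circularity(region)
        if not circularity_range[0] <= circ <= circularity_range[1]:
            continue
        out[labels == region.label] = next_id
        next_id += 1
    return out


def segment_nuclei(field: FieldImage, settings: SegmentationSettings) -> LabelMask:
    """Segment nuclei on the nucleus channel.

    An empty mask is a valid result (a warning is emitted when no nucleus
    survives the filters).
    """
    img = _preprocess(field.nucleus, settings.nucleus_median_radius,
                      settings.nucleus_rolling_ball_radius)
    method = _THRESHOLD_METHODS.get(settings.nucleus_threshold_method)
    if method is None:
        raise ValueError(
            f"unknown threshold method {settings.nucleus_threshold_method!r}; "
            f"choose from {sorted(_THRESHOLD_METHODS)}")
    flat = img.ravel()
    if np.all(flat == flat[0]):  # constant image: no foreground
        binary = np.zeros(img.shape, dtype=bool)
    else:
        binary = img > method(img)
    for _ in range(settings.nucleus_erosion_count):
        binary = morphology.binary_erosion(binary, footprint=disk(1))
    labels = _filter_instances(binary, field.pixel_size,
                               settings.nucleus_size_range,
                               settings.nucleus_circularity_range,
                               reject_border=True)
    if labels.max() == 0:
        warnings.warn(f"field {field.field_id!r}: no nuclei survive segmentation filters",
                      stacklevel=2)
    return LabelMask(labels, pixel_size=field.pixel_size)


def unfiltered_cell_mask(field: FieldImage, settings: SegmentationSettings) -> np.ndarray:
    """Thresholded cell-area mask before watershed and instance filtering.

    The complement of this mask defines the background region used for
    field-level background intensity estimation.
    """
    img = _preprocess(field.cytoplasm, settings.cell_median_radius,
                      settings.cell_rolling_ball_radius,
                      invert=settings.invert_cytoplasm_channel)
    return img > settings.cell_fixed_threshold


def segment_cells(field: FieldImage, nuclei: LabelMask,
                  settings: SegmentationSettings) -> LabelMask:
    """Segment single cells with a marker-controlled watershed.

    The nucleus and cytoplasm channels are summed and Gaussian-smoothed;
    prominence-filtered maxima of that composite seed a watershed whose
    boundary lines (1 px wide) are multiplied into the thresholded area
    mask, separating touching cells.  Surviving instances pass the
    size/circularity filter and contain exactly one surviving nucleus —
    note that two nuclei close enough to merge into a single composite
    maximum leave their cell unseparated and therefore rejected as
    binucleate.
    """
    if nuclei.labels.shape != field.shape:
        raise ValueError("nuclei mask geometry does not match the field")
    area_mask = unfiltered_cell_mask(field, settings)
    relief = filters.gaussian(field.nucleus.astype(float) + field.cytoplasm.astype(float),
                              sigma=settings.watershed_gaussian_sigma,
                              preserve_range=True)
    from .detect import _prominence_maxima

    peaks = _prominence_maxima(relief, settings.watershed_maxima_prominence)
    markers, n_markers = ndi.label(peaks, structure=_EIGHT)
    if n_markers > 0:
        ws = skseg.watershed(-relief, markers=markers, watershed_line=True)
        separated = area_mask & (ws != 0)
    else:
        separated = area_mask
    # 4-connectivity so the 1-px watershed lines actually disconnect regions
    labels = _filter_instances(separated, field.pixel_size,
                               settings.cell_size_range,
                               settings.cell_circularity_range,
                               reject_border=settings.reject_border_cells,
                               structure=ndi.generate_binary_structure(2, 1))

    # keep only cells containing exactly one surviving nucleus (majority overlap)
    out = np.zeros_like(labels)
    next_id = 1
    nucleus_owner: dict[int, int] = {}
    for nid in nuclei.instance_ids:
        nucleus_pixels = labels[nuclei.labels == nid]
        nucleus_pixels = nucleus_pixels[nucleus_pixels > 0]
        if nucleus_pixels.size == 0:
            continue
        counts = np.bincount(nucleus_pixels)
        nucleus_owner[int(nid)] = int(counts.argmax())
    owners = list(nucleus_owner.values())
    for cid in range(1, labels.max() + 1):
        if owners.count(cid) == 1:
            out[labels == cid] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn(f"field {field.field_id!r}: no cells survive segmentation filters",
                      stacklevel=2)
    return LabelMask(out, pixel_size=field.pixel_size)


def match_nuclei_to_cells(nuclei: LabelMask, cells: LabelMask) -> dict[int, int]:
    """Map each surviving cell id to the id of the nucleus it contains.

    Assignment is by majority pixel overlap of the nucleus with the cell.
    """
    mapping: dict[int, int] = {}
    for nid in nuclei.instance_ids:
        cell_pixels = cells.labels[nuclei.labels == nid]
        cell_pixels = cell_pixels[cell_pixels > 0]
        if cell_pixels.size == 0:
            continue
        cid = int(np.bincount(cell_pixels).argmax())
        mapping[cid] = int(nid)
    return mapping
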