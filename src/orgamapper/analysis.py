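"""Cross-field aggregation, positioning statistics and group comparisons.

This is the headless data-analysis stage: it consumes the per-cell /
per-detection tables produced by the mapping stage, applies field-level
background subtraction and the cell-diameter filter, and computes the
positioning summaries (mean raw and Feret-normalized distances, perinuclear
intensity ratios, kernel density curves, binned intensity maps) and the
two-sample Wilcoxon rank-sum comparison between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .mapping import IntensityProfile

__all__ = [
    "aggregate", "perinuclear_index", "distance_density", "DensityCurve",
    "compare_groups", "RankSumResult", "intensity_ratio_map",
]


def aggregate(cells: pd.DataFrame, detections: pd.DataFrame,
              field_summary: pd.DataFrame, condition: str,
              background_subtract: bool = True,
              cell_diameter_max: float = 600.0) -> pd.DataFrame:
    """Per-cell condition summary across one condition's fields.

    Applies field-level background subtraction to mean and peak intensities
    (clamped at 0), removes cells with a Feret diameter above
    ``cell_diameter_max`` (um) and averages each cell's detection distances.
    Returns one row per surviving cell.
    """
    cells = cells.copy()
    if len(cells) == 0:
        raise ValueError(f"condition {condition!r} has 0 cells")
    bg = field_summary.set_index("field_id")["background_mean_organelle"]

    cells = cells[cells["feret_um"] <= cell_diameter_max].copy()
    if len(cells) == 0:
        raise ValueError(f"condition {condition!r}: no cells survive the "
                         f"{cell_diameter_max} um diameter filter")

    if background_subtract:
        offsets = cells["field_id"].map(bg).fillna(0.0)
        cells["mean_organelle_intensity"] = np.clip(
            cells["mean_organelle_intensity"] - offsets, 0.0, None)

    per_cell = detections.groupby(["field_id", "cell_id"]).agg(
        mean_distance_um=("distance_um", "mean"),
        mean_normalized_distance=("distance_normalized", "mean"),
        mean_organelle_peak=("organelle_peak", "mean"),
        n_detections=("x_px", "size"),
    ).reset_index()
    if background_subtract and len(per_cell):
        offsets = per_cell["field_id"].map(bg).fillna(0.0)
        per_cell["mean_organelle_peak"] = np.clip(
            per_cell["mean_organelle_peak"] - offsets, 0.0, None)

    out = cells.merge(per_cell, on=["field_id", "cell_id"], how="left")
    out["n_detections"] = out["n_detections"].fillna(0).astype(int)
    out.insert(0, "condition", condition)
    return out


def perinuclear_index(profile: IntensityProfile, perimeter_um: float = 10.0,
                      channel: str = "organelle", background: float = 0.0,
                      integrated: bool = False) -> float:
    """Perinuclear intensity ratio of one cell.

    Splits the cytoplasm at a fixed distance ``perimeter_um`` from the
    nucleus edge and divides the mean intensity of the inner region by the
    mean intensity of the outer region.  With ``integrated=True`` the ratio
    of integrated densities (sums) is returned instead, which is sensitive to
    the region areas.  ``background`` is subtracted (clamped at 0) first.
    Raises ``ValueError`` when either region is empty or the outer intensity
    is 0.
    """
    values = profile.organelle if channel == "organelle" else profile.measurement
    if values is None:
        raise ValueError(f"profile has no {channel!r} channel")
    values = np.clip(values - background, 0.0, None)
    inner = profile.distances_um < perimeter_um
    outer = ~inner
    if not inner.any():
        raise ValueError("perinuclear region is empty (perimeter smaller than one pixel ring)")
    if not outer.any():
        raise ValueError("outer region is empty: cell lies entirely within the perimeter")
    if integrated:
        denom = values[outer].sum()
    else:
        denom = values[outer].mean()
    if denom == 0:
        raise ValueError("outer-region intensity is 0: perinuclear index undefined")
    num = values[inner].sum() if integrated else values[inner].mean()
    return float(num / denom)


@dataclass
class DensityCurve:
    """Gaussian-kernel density over distances, evaluated on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    @property
    def integral(self) -> float:
        """Exact integral of the density over the grid span (via the normal CDF)."""
        return float(self._integral)

    _integral: float = 0.0

    @property
    def mode(self) -> float:
        """Grid location of the highest density value."""
        return float(self.grid[np.argmax(self.density)])

    def n_modes(self) -> int:
        """Number of strict local maxima of the curve on its grid."""
        d = self.density
        return int(np.sum((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])))


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        # degenerate sample: pick a nominal width so the curve is a narrow
        # peak at the common value
        scale = abs(float(x[0]))
        return max(1e-3, 1e-3 * scale)
    return 0.9 * spread * n ** (-1 / 5)


def distance_density(distances: Sequence[float],
                     bandwidth: float | str = "auto",
                     grid_size: int = 512,
                     pad_bandwidths: float = 9.0) -> DensityCurve:
    """Gaussian kernel density estimate of a condition's detection distances.

    ``bandwidth`` is an absolute kernel width in the data's units; the default
    ("auto") uses Silverman's rule.  The grid extends ``pad_bandwidths``
    bandwidths beyond the data range so the density integrates to 1 over the
    grid span (checked exactly through the normal CDF).
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size < 2:
        raise ValueError("density estimation needs at least 2 points")
    h = _silverman_bandwidth(x) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    lo = x.min() - pad_bandwidths * h
    hi = x.max() + pad_bandwidths * h
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (x.size * h * math.sqrt(2 * math.pi))
    integral = float(np.mean(
        0.5 * (special.erf((hi - x) / (h * math.sqrt(2)))
               - special.erf((lo - x) / (h * math.sqrt(2))))))
    curve = DensityCurve(grid=grid, density=density, bandwidth=h, n=x.size)
    curve._integral = integral
    return curve


@dataclass
class RankSumResult:
    """Two-sample rank-sum comparison result."""

    statistic: float  # Mann-Whitney U of sample A
    pvalue: float
    method: str  # "exact-enumeration", "exact", or "asymptotic"


_MAX_ENUMERATION = 50_000


def _rank_sum_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of group assignments (midranks)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = pooled.size, a.size
    mu = na * (n + 1) / 2.0
    observed = abs(ranks[:na].sum() - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
            count += 1
    return count / total


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> RankSumResult:
    """Unpaired two-sample two-sided Wilcoxon rank-sum test.

    Small samples are handled exactly — by full enumeration of all group
    assignments with midranks when feasible, else by the tie-free exact
    distribution — larger or tied samples by the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = float(stats.rankdata(np.concatenate([a, b]))[:a.size].sum()
              - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if math.comb(a.size + b.size, a.size) <= _MAX_ENUMERATION:
        p = _rank_sum_enumeration(a, b)
        return RankSumResult(u, min(1.0, p), "exact-enumeration")
    if not has_ties and max(a.size, b.size) <= 50:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankSumResult(u, float(res.pvalue), "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return RankSumResult(u, float(res.pvalue), "asymptotic")


def intensity_ratio_map(profiles: Iterable[IntensityProfile],
                        channel: str = "organelle",
                        background: float = 0.0) -> pd.DataFrame:
    """Condition-level mean binned intensity vs distance from the nucleus.

    Cells' binned profiles are combined with pixel-count weights, so for a
    single cell the pixel-weighted mean of the curve equals the cell's mean
    cytoplasmic intensity.  All profiles must share the same bin width.
    """
    rows = []
    widths = set()
    for p in profiles:
        widths.add(p.bin_width)
        values = (p.bin_mean_organelle if channel == "organelle"
                  else p.bin_mean_measurement)
        if values is None:
            raise ValueError(f"profile of cell {p.cell_id} has no {channel!r} channel")
        values = np.clip(values - background, 0.0, None)
        rows.append(pd.DataFrame({
            "bin_center_um": p.bin_centers,
            "weighted_sum": values * p.bin_pixel_count,
            "pixel_count": p.bin_pixel_count,
        }))
    if len(widths) > 1:
        raise ValueError(f"inconsistent bin widths across profiles: {sorted(widths)}")
    if not rows:
        raise ValueError("no profiles given")
    table = pd.concat(rows).groupby("bin_center_um", as_index=False).sum()
    table["mean_intensity"] = table["weighted_sum"] / table["pixel_count"]
    return table[["bin_center_um", "mean_intensity", "pixel_count"]]
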