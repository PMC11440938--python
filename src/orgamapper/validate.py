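"""Quantitative validation of point-detection performance.

Any detector's point output is scored against manually curated point labels:
the pairwise Euclidean distance matrix between manual and automatic points is
matched greedily in increasing distance order (one-to-one, ties broken by
point index), accepting only pairs closer than the threshold.  Matched pairs
are true positives; unmatched manual points are false negatives; unmatched
automatic points farther than the threshold from every manual point are false
positives; unmatched automatic points near an already-matched manual point
indicate over-detection and are counted separately as ambiguous (N_ambi),
excluded from FP by default.

F1 = TP / (TP + 0.5 * (FN + FP)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["MatchResult", "match_detections", "f1", "average_f1"]

DEFAULT_THRESHOLD = 4.0  # px; smallest distance between individual objects


@dataclass
class MatchResult:
    """Detection-validation counts and score for one example."""

    tp: int
    fp: int
    fn: int
    n_ambiguous: int
    f1: float
    threshold: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)


def f1(tp: int, fp: int, fn: int) -> float:
    """F1 score TP / (TP + 0.5*(FN + FP)); undefined when all counts are 0."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("F1 is undefined when TP = FP = FN = 0")
    return tp / (tp + 0.5 * (fn + fp))


def _as_points(points) -> np.ndarray:
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.size == 0:
        return np.empty((0, 2), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"points must be an (N, 2) array of (x, y), got shape {arr.shape}")
    return arr


def match_detections(manual_points, auto_points,
                     threshold: float = DEFAULT_THRESHOLD,
                     ambiguous_as_fp: bool = False) -> MatchResult:
    """Greedily match automatic to manual points and score the detector.

    Pairs are considered in increasing distance order (ties by manual then
    automatic index) and accepted one-to-one when their distance is strictly
    below *threshold*.  Set ``ambiguous_as_fp`` to count over-detections as
    false positives instead of reporting them separately.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    manual = _as_points(manual_points)
    auto = _as_points(auto_points)
    pairs: list[tuple[int, int, float]] = []
    manual_used = np.zeros(len(manual), dtype=bool)
    auto_used = np.zeros(len(auto), dtype=bool)
    if len(manual) and len(auto):
        d = cdist(manual, auto)
        mi, ai = np.unravel_index(
            np.lexsort((np.tile(np.arange(len(auto)), len(manual)),
                        np.repeat(np.arange(len(manual)), len(auto)),
                        d.ravel())),
            d.shape)
        for m, a in zip(mi, ai):
            dist = d[m, a]
            if dist >= threshold:
                break
            if manual_used[m] or auto_used[a]:
                continue
            manual_used[m] = True
            auto_used[a] = True
            pairs.append((int(m), int(a), float(dist)))
    tp = len(pairs)
    fn = int((~manual_used).sum())
    ambiguous = 0
    fp = 0
    for a in np.nonzero(~auto_used)[0]:
        if len(manual) and cdist(manual, auto[a:a + 1]).min() < threshold:
            ambiguous += 1
        else:
            fp += 1
    if ambiguous_as_fp:
        fp += ambiguous
        ambiguous = 0
    score = f1(tp, fp, fn) if tp + fp + fn > 0 else 1.0
    return MatchResult(tp=tp, fp=fp, fn=fn, n_ambiguous=ambiguous,
                       f1=score, threshold=threshold, pairs=pairs)


def average_f1(results: Iterable[MatchResult]) -> float:
    """Unweighted mean F1 over validation examples."""
    scores = [r.f1 for r in results]
    if not scores:
        raise ValueError("average_f1 needs at least one result")
    return float(np.mean(scores))
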