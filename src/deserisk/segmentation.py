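"""Optimal segmentation of an ordered sample into contiguous classes.

Dynamic program minimizing the total within-class sum of squared deviations
(the classical ordered-clustering / Fisher criterion), used to derive the
grading standards for indicators and for the composite risk index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError


@dataclass
class SegmentationResult:
    """A contiguous k-partition of a sorted sample.

    boundaries : the k-1 cut values, midpoints between adjacent class edges.
    classes    : list of (start, stop) index ranges, stop exclusive.
    loss       : total within-class sum of squared deviations, minimal over
                 all contiguous k-partitions.
    """

    boundaries: list[float]
    classes: list[tuple[int, int]]
    loss: float


def _within_ss(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """Sum of squares of values[i:j] around their mean (prefix sums precomputed)."""
    n = j - i
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    return sq - s * s / n


def optimal_segmentation(values, k: int) -> SegmentationResult:
    """Partition a sorted sample into k contiguous classes with minimal within-class SS.

    ``values`` must be sorted ascending (the caller sorts unordered samples).
    Among equal-loss partitions the one whose leftmost differing boundary
    index is smallest is returned, so output is deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("values must be one-dimensional")
    n = x.size
    if k < 2:
        raise ValidationError("k must be at least 2 (trivial partition otherwise)")
    if k > n:
        raise DegenerateInputError(f"cannot split {n} values into {k} classes")
    if np.any(np.diff(x) < 0):
        raise ValidationError("values must be sorted ascending")

    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])

    # cost[c][j] = minimal loss of splitting x[0:j] into c classes
    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[1][j] = _within_ss(prefix, prefix_sq, 0, j)
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            # last class is x[i:j]; i ascending + strict < keeps the
            # smallest split index on ties
            for i in range(c - 1, j):
                cand = cost[c - 1][i] + _within_ss(prefix, prefix_sq, i, j)
                if cand < best:
                    best, best_i = cand, i
            cost[c][j] = best
            back[c][j] = best_i

    cuts = []
    j = n
    for c in range(k, 1, -1):
        i = back[c][j]
        cuts.append(i)
        j = i
    cuts.reverse()

    classes = []
    starts = [0] + cuts
    stops = cuts + [n]
    for a, b in zip(starts, stops):
        classes.append((a, b))
    boundaries = [float((x[c - 1] + x[c]) / 2.0) for c in cuts]
    return SegmentationResult(boundaries=boundaries, classes=classes, loss=float(cost[k][n]))


def grade_boundaries_from_sample(values) -> tuple[float, float, float, float]:
    """Four grade cut values from a sample via optimal 5-segmentation.

    Requires at least five distinct values; the input may be unsorted.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if np.unique(x).size < 5:
        raise DegenerateInputError(
            "need at least 5 distinct values to derive five grades"
        )
    result = optimal_segmentation(x, k=5)
    return tuple(result.boundaries)
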