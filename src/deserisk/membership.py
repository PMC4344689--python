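"""Five-grade trapezoidal fuzzy partitions per indicator.

Each indicator's four grade boundaries are widened into eight split points
(a1-, a1+, ..., a4-, a4+) that define five trapezoidal membership functions
v1..v5 forming an exact partition of unity: between a ramp's endpoints two
adjacent grades share membership linearly; on a plateau a single grade holds
membership 1.

For increasing-type indicators (value rises with the graded quantity) the
split points around ascending boundaries b1 < b2 < b3 < b4 are

    a1- = b1 - |b1|/4          a1+ = (3 b1 + b2)/4
    a2- = (b1 + 3 b2)/4        a2+ = (3 b2 + b3)/4
    a3- = (b2 + 3 b3)/4        a3+ = (3 b3 + b4)/4
    a4- = (b3 + 3 b4)/4        a4+ = b4 + |b4|/4

Decreasing-type indicators use the exact mirror with descending boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .config import IndicatorSpec
    from .grid import GridLayer
    from .fuzzy import FuzzyResult

N_GRADES = 5


@dataclass(frozen=True)
class GradeBoundaries:
    """Four grade split points plus the direction the grade runs in.

    For direction 'increasing' the boundaries must ascend; for 'decreasing'
    they must descend (mirror convention of the trapezoid formulas).
    """

    values: tuple[float, float, float, float]
    direction: str = "increasing"

    def __post_init__(self):
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        v = self.values
        diffs = np.diff(v)
        if self.direction == "increasing" and not (diffs > 0).all():
            raise ValidationError(f"increasing boundaries must ascend strictly, got {v}")
        if self.direction == "decreasing" and not (diffs < 0).all():
            raise ValidationError(f"decreasing boundaries must descend strictly, got {v}")


@dataclass(frozen=True)
class GradePartition:
    """Eight derived split points defining five trapezoidal membership functions.

    splits holds (a1-, a1+, a2-, a2+, a3-, a3+, a4-, a4+). For an increasing
    partition the sequence ascends (weakly at collapsed outer ramps); for a
    decreasing partition it descends.
    """

    splits: tuple[float, ...]
    direction: str = "increasing"

    def __post_init__(self):
        if len(self.splits) != 8:
            raise ValidationError("a grade partition has exactly 8 split points")
        s = np.asarray(self.splits, dtype=float)
        d = np.diff(s)
        if self.direction == "increasing" and (d < 0).any():
            raise ValidationError(f"increasing split points must be non-decreasing: {self.splits}")
        if self.direction == "decreasing" and (d > 0).any():
            raise ValidationError(f"decreasing split points must be non-increasing: {self.splits}")

    @property
    def ramps(self) -> list[tuple[float, float]]:
        """The four (a_g-, a_g+) ramp intervals."""
        s = self.splits
        return [(s[0], s[1]), (s[2], s[3]), (s[4], s[5]), (s[6], s[7])]


def derive_split_points(b: GradeBoundaries, literal_outer: bool = False) -> GradePartition:
    """Widen four grade boundaries into the eight trapezoid split points.

    ``literal_outer`` reproduces the as-tabulated increasing-type outer split
    a4+ = b4 + b1/4 instead of the symmetric b4 + |b4|/4 (compatibility only).
    """
    b1, b2, b3, b4 = b.values
    if b.direction == "increasing":
        a4_plus = b4 + (b1 / 4.0 if literal_outer else abs(b4) / 4.0)
        splits = (
            b1 - abs(b1) / 4.0,
            (3 * b1 + b2) / 4.0,
            (b1 + 3 * b2) / 4.0,
            (3 * b2 + b3) / 4.0,
            (b2 + 3 * b3) / 4.0,
            (3 * b3 + b4) / 4.0,
            (b3 + 3 * b4) / 4.0,
            a4_plus,
        )
    else:
        splits = (
            b1 + abs(b1) / 4.0,
            (3 * b1 + b2) / 4.0,
            (b1 + 3 * b2) / 4.0,
            (3 * b2 + b3) / 4.0,
            (b2 + 3 * b3) / 4.0,
            (3 * b3 + b4) / 4.0,
            (b3 + 3 * b4) / 4.0,
            b4 - abs(b4) / 4.0,
        )
    return GradePartition(splits=splits, direction=b.direction)


def partition_for(spec: "IndicatorSpec", literal_outer: bool = False) -> GradePartition:
    """Grade partition for a configured indicator.

    The config stores boundaries ascending; a decreasing membership
    direction reverses them to satisfy the mirror convention.
    """
    direction = spec.membership_direction
    bounds = spec.boundaries if direction == "increasing" else spec.boundaries[::-1]
    return derive_split_points(
        GradeBoundaries(values=tuple(bounds), direction=direction),
        literal_outer=literal_outer,
    )


def _ramp(x: np.ndarray, lo: float, hi: float, direction: str) -> np.ndarray:
    """Transition function of one ramp: 0 before it, 1 after, linear inside.

    'Before'/'after' follow the partition direction. A zero-width ramp
    degenerates to a step at the boundary (limiting trapezoid).
    """
    if direction == "increasing":
        if hi > lo:
            return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        return (x > lo).astype(float)
    else:
        if lo > hi:
            return np.clip((lo - x) / (lo - hi), 0.0, 1.0)
        return (x < lo).astype(float)


def membership_vector(x, p: GradePartition) -> np.ndarray:
    """Evaluate the five membership functions at x (scalar or array).

    Returns an array with a trailing axis of length 5; components lie in
    [0, 1] and sum to 1 for every finite x. Non-finite x yields NaN in all
    five components (masked-cell propagation, not an exception).
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    xsafe = np.where(finite, x, 0.0)
    # cumulative transitions t_g through each ramp; v_g = t_{g-1} - t_g
    # telescopes to an exact partition of unity
    t = [np.ones_like(xsafe)]
    for lo, hi in p.ramps:
        t.append(_ramp(xsafe, lo, hi, p.direction))
    t.append(np.zeros_like(xsafe))
    grades = [t[g] - t[g + 1] for g in range(N_GRADES)]
    out = np.stack(grades, axis=-1)
    out[~finite] = np.nan
    return out


def grade_layers(layer: "GridLayer", spec: "IndicatorSpec") -> "FuzzyResult":
    """Per-cell grade membership vectors for one indicator layer.

    Masked cells stay masked. The layer and spec must name the same indicator.
    """
    from .fuzzy import FuzzyResult

    if layer.name != spec.name:
        raise ValidationError(
            f"layer {layer.name!r} does not match indicator spec {spec.name!r}"
        )
    p = partition_for(spec)
    x = np.where(layer.nodata_mask, np.nan, layer.values)
    memberships = membership_vector(x, p)
    return FuzzyResult(
        name=spec.name,
        memberships=memberships,
        nodata_mask=layer.nodata_mask.copy(),
        cell_size=layer.cell_size,
        origin=layer.origin,
    )
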