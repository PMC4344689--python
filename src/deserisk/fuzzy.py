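"""Fuzzy comprehensive evaluation, DDRI aggregation, grading and zoning.

Per factor, the weighted-sum composition B = A x R mixes its indicators'
per-cell grade-membership vectors into one comprehensive vector; grade
scores collapse B to a scalar factor index. The four factor indices combine
into the Desertification Disaster Risk Index

    DDRI = H^Wh * E^We * V^Wv * (1 - R)^Wr

(a weighted geometric mean; restorability enters through its complement so
more restorability means less risk). The index is graded on half-open
intervals and summarized per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import GridLayer
from .weighting import WeightVector

N_GRADES = 5
GRADE_LABELS = ("very low", "low", "middle", "high", "very high")

#: Class-midpoint grade scores on [0, 1] used to collapse a membership
#: vector to a scalar factor index.
DEFAULT_GRADE_SCORES = (0.1, 0.3, 0.5, 0.7, 0.9)

#: Half-open (lo, hi] grading intervals of the composite risk index.
DEFAULT_DDRI_BOUNDS = (0.29, 0.47, 0.63, 0.78)


@dataclass
class FuzzyResult:
    """Per-cell 5-vector of grade memberships on a grid.

    memberships has shape (nrows, ncols, 5); unmasked vectors are
    non-negative and sum to 1.
    """

    name: str
    memberships: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.memberships = np.asarray(self.memberships, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.memberships.ndim != 3 or self.memberships.shape[-1] != N_GRADES:
            raise ValidationError(
                f"memberships must have shape (nrows, ncols, {N_GRADES})"
            )
        if self.memberships.shape[:2] != self.nodata_mask.shape:
            raise ValidationError("memberships and mask shapes disagree")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    def grid_like(self) -> GridLayer:
        """An empty GridLayer on this result's grid (for with_values)."""
        return GridLayer(
            self.name,
            np.where(self.nodata_mask, np.nan, 0.0),
            self.nodata_mask,
            self.cell_size,
            self.origin,
        )


@dataclass
class RiskModel:
    """Factor weights, grade scores and grading boundaries of the risk index."""

    factor_weights: dict = field(
        default_factory=lambda: {
            "hazard": 0.4088,
            "exposure": 0.2055,
            "vulnerability": 0.1992,
            "restorability": 0.1865,
        }
    )
    grade_scores: tuple = DEFAULT_GRADE_SCORES
    ddri_bounds: tuple = DEFAULT_DDRI_BOUNDS
    grade_labels: tuple = GRADE_LABELS

    def __post_init__(self):
        total = sum(self.factor_weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"factor weights sum to {total}, expected 1")
        s = self.grade_scores
        if len(s) != N_GRADES or not all(s[i] < s[i + 1] for i in range(N_GRADES - 1)):
            raise ValidationError("grade scores must be 5 strictly increasing values")
        b = self.ddri_bounds
        if len(b) != 4 or not all(0 < b[i] < 1 for i in range(4)) or not all(
            b[i] < b[i + 1] for i in range(3)
        ):
            raise ValidationError("DDRI bounds must be 4 ascending values in (0, 1)")

    @classmethod
    def from_config(cls, config, **kwargs) -> "RiskModel":
        """Factor weights taken as each factor's combined-indicator weight sum."""
        return cls(factor_weights=config.factor_weights(), **kwargs)


def factor_evaluate(
    memberships: list[FuzzyResult], weights: WeightVector
) -> FuzzyResult:
    """Comprehensive evaluation B = A x R of one factor's indicators.

    ``weights`` must cover exactly the given indicators; they are
    renormalized to sum 1 within the factor. Output vectors are normalized
    per cell (a safeguard — the convex mixture of unit-sum vectors already
    sums to 1).
    """
    if not memberships:
        raise ValidationError("no membership results given")
    names = [m.name for m in memberships]
    if sorted(names) != sorted(weights.names):
        raise ValidationError(
            f"indicators {names} do not match weight names {weights.names}"
        )
    shape = memberships[0].shape
    for m in memberships:
        if m.shape != shape:
            raise ValidationError("membership results are not on the same grid")
    a = np.array([weights[name] for name in names])
    a = a / a.sum()
    stack = np.stack([m.memberships for m in memberships])  # (j, rows, cols, 5)
    combined = np.einsum("j,jrcg->rcg", a, stack)
    mask = np.logical_or.reduce([m.nodata_mask for m in memberships])
    totals = combined.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(totals > 0, combined / totals, np.nan)
    combined[mask] = np.nan
    first = memberships[0]
    return FuzzyResult(
        name="factor", memberships=combined, nodata_mask=mask,
        cell_size=first.cell_size, origin=first.origin,
    )


def defuzzify(b: FuzzyResult, scores=DEFAULT_GRADE_SCORES) -> GridLayer:
    """Collapse grade-membership vectors to a scalar index, sum_g s_g B_g."""
    s = np.asarray(scores, dtype=float)
    if s.size != N_GRADES:
        raise ValidationError("need exactly 5 grade scores")
    values = np.einsum("rcg,g->rc", np.nan_to_num(b.memberships), s)
    values = np.where(b.nodata_mask, np.nan, values)
    return GridLayer(b.name, values, b.nodata_mask.copy(), b.cell_size, b.origin)


def _check_unit_interval(layer: GridLayer, label: str) -> None:
    vals = layer.unmasked()
    if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
        raise ValidationError(
            f"factor {label!r} has values outside [0, 1]: "
            f"range ({vals.min():.6g}, {vals.max():.6g})"
        )


def ddri(
    h: GridLayer,
    e: GridLayer,
    v: GridLayer,
    r: GridLayer,
    model: RiskModel | None = None,
    aggregation: str = "geometric",
) -> GridLayer:
    """Combine the four factor indices into the composite risk index.

    Default is the weighted geometric form H^Wh E^We V^Wv (1-R)^Wr, which
    keeps the index inside [0, 1] and makes each factor's weight an
    elasticity. ``aggregation='product'`` gives the literal weighted product
    (H Wh)(E We)(V Wv)((1-R) Wr) for sensitivity comparison only — its scale
    is not comparable to the grading standards.
    """
    model = model or RiskModel()
    layers = {"hazard": h, "exposure": e, "vulnerability": v, "restorability": r}
    for label, layer in layers.items():
        _check_unit_interval(layer, label)
    wh = model.factor_weights["hazard"]
    we = model.factor_weights["exposure"]
    wv = model.factor_weights["vulnerability"]
    wr = model.factor_weights["restorability"]
    hv = np.clip(h.values, 0.0, 1.0)
    ev = np.clip(e.values, 0.0, 1.0)
    vv = np.clip(v.values, 0.0, 1.0)
    rc = np.clip(1.0 - r.values, 0.0, 1.0)
    if aggregation == "geometric":
        values = hv**wh * ev**we * vv**wv * rc**wr
    elif aggregation == "product":
        values = (hv * wh) * (ev * we) * (vv * wv) * (rc * wr)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    mask = h.nodata_mask | e.nodata_mask | v.nodata_mask | r.nodata_mask
    values = np.where(mask, np.nan, values)
    return GridLayer("ddri", values, mask, h.cell_size, h.origin)


def grade_risk(ddri_layer: GridLayer, model: RiskModel | None = None) -> GridLayer:
    """Grade the risk index on half-open intervals (lo, hi] into codes 1-5."""
    model = model or RiskModel()
    vals = ddri_layer.unmasked()
    if vals.size and (vals.min() <= 0 or vals.max() > 1):
        raise ValidationError(
            f"risk index values outside (0, 1]: range ({vals.min():.6g}, {vals.max():.6g})"
        )
    bounds = np.asarray(model.ddri_bounds)
    # side='left': a value equal to a bound falls in the interval it closes
    codes = 1 + np.searchsorted(bounds, ddri_layer.values, side="left").astype(float)
    codes = np.where(ddri_layer.nodata_mask, np.nan, codes)
    return GridLayer("risk_grade", codes, ddri_layer.nodata_mask.copy(),
                     ddri_layer.cell_size, ddri_layer.origin)


def area_ratio(part: float, total: float, decimals: int | None = 1) -> float:
    """Percentage share of an area in a total, optionally rounded."""
    if total <= 0:
        raise ValidationError("total area must be positive")
    pct = 100.0 * part / total
    return pct if decimals is None else round(pct, decimals)


def zonal_stats(
    grades: GridLayer, ddri_layer: GridLayer, regions: GridLayer
) -> pd.DataFrame:
    """Per-region and global grade area ratios and mean risk index.

    Returns a DataFrame indexed by region id (plus a "global" row) with
    cell_count, mean_ddri, and ratio_<grade> columns. Unlabeled unmasked
    cells are excluded with a warning.
    """
    if not (grades.same_grid(ddri_layer) and grades.same_grid(regions)):
        raise ValidationError("grade, risk and region layers must share the grid")
    valid = ~(grades.nodata_mask | ddri_layer.nodata_mask)
    unlabeled = valid & regions.nodata_mask
    if unlabeled.any():
        warnings.warn(
            f"zonal_stats: {int(unlabeled.sum())} unmasked cells have no region label"
        )
        valid &= ~regions.nodata_mask
    df = pd.DataFrame(
        {
            "region": regions.values[valid].astype(int),
            "grade": grades.values[valid].astype(int),
            "ddri": ddri_layer.values[valid],
        }
    )
    rows = []
    groups = [(rid, grp) for rid, grp in df.groupby("region")]
    groups.append(("global", df))
    for rid, grp in groups:
        counts = grp["grade"].value_counts()
        n = len(grp)
        row = {
            "region": rid,
            "cell_count": n,
            "mean_ddri": grp["ddri"].mean(),
        }
        for g, label in enumerate(GRADE_LABELS, start=1):
            row[f"ratio_{label.replace(' ', '_')}"] = counts.get(g, 0) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
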