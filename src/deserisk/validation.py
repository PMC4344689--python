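"""Validation of the risk index against a loss layer at regional scale.

Aggregates the risk index and the loss layer to per-region means, fits an
ordinary least-squares line of loss on risk, and reports R^2 (squared
Pearson correlation of the regional means) and the slope's two-sided
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .grid import GridLayer


@dataclass
class ValidationReport:
    """Regional means, OLS fit of loss on risk, and goodness of fit."""

    pairs: pd.DataFrame  # columns: region, mean_ddri, mean_loss
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError(f"R^2 = {self.r_squared} outside [0, 1]")


def regional_pairs(
    ddri_layer: GridLayer, loss_layer: GridLayer, regions: GridLayer
) -> pd.DataFrame:
    """Per-region unmasked-cell means of the risk index and the loss layer."""
    if not (ddri_layer.same_grid(loss_layer) and ddri_layer.same_grid(regions)):
        raise ValidationError("risk, loss and region layers must share the grid")
    valid = ~(ddri_layer.nodata_mask | loss_layer.nodata_mask | regions.nodata_mask)
    labels = np.unique(regions.values[~regions.nodata_mask]).astype(int)
    rows = []
    for rid in labels:
        sel = valid & (regions.values == rid)
        if not sel.any():
            warnings.warn(f"region {rid} has no unmasked cells; excluded")
            continue
        rows.append(
            {
                "region": rid,
                "mean_ddri": float(ddri_layer.values[sel].mean()),
                "mean_loss": float(loss_layer.values[sel].mean()),
                "cell_count": int(sel.sum()),
            }
        )
    if len(rows) < 3:
        raise DegenerateInputError("need at least 3 regions with data for validation")
    return pd.DataFrame(rows)


def fit_linear(pairs: pd.DataFrame) -> ValidationReport:
    """OLS of regional mean loss on regional mean risk index."""
    if len(pairs) < 3:
        raise DegenerateInputError("need at least 3 regional pairs")
    x = pairs["mean_ddri"].to_numpy(dtype=float)
    y = pairs["mean_loss"].to_numpy(dtype=float)
    if np.isclose(x.var(), 0.0):
        raise DegenerateInputError("zero variance in regional mean risk — cannot fit")
    if np.isclose(y.var(), 0.0):
        # flat losses: zero slope, no explained variance
        return ValidationReport(pairs=pairs, slope=0.0, intercept=float(y.mean()),
                                r_squared=0.0, p_value=1.0)
    fit = stats.linregress(x, y)
    return ValidationReport(
        pairs=pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def gridwise_fit(ddri_layer: GridLayer, loss_layer: GridLayer) -> ValidationReport:
    """Cell-level OLS of loss on risk (beyond the regional analysis; exploratory).

    The study-design analysis is regional; this helper exists for synthetic
    experiments only.
    """
    valid = ~(ddri_layer.nodata_mask | loss_layer.nodata_mask)
    x = ddri_layer.values[valid]
    y = loss_layer.values[valid]
    if x.size < 3 or np.isclose(x.var(), 0.0):
        raise DegenerateInputError("too few or degenerate cells for a grid-level fit")
    fit = stats.linregress(x, y)
    pairs = pd.DataFrame({"region": ["grid"], "mean_ddri": [x.mean()], "mean_loss": [y.mean()],
                          "cell_count": [x.size]})
    return ValidationReport(
        pairs=pairs, slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
    )
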