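"""Remote-sensing indicators (NDVI, vegetation coverage index) and min-max scaling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .grid import GridLayer, require_shared_grid


@dataclass
class ReflectancePair:
    """Near-infrared and red reflectance layers on a shared grid, values in [0, 1]."""

    nir: GridLayer
    red: GridLayer

    def __post_init__(self):
        require_shared_grid([self.nir, self.red])
        for layer in (self.nir, self.red):
            vals = layer.unmasked()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValidationError(
                    f"reflectance layer {layer.name!r} has values outside [0, 1]"
                )


def ndvi(pair: ReflectancePair) -> GridLayer:
    """Normalized difference vegetation index, (NIR - R) / (NIR + R), in [-1, 1].

    Cells where NIR + R = 0 are masked and counted in a warning rather than
    raising, so a few dark cells do not abort a run.
    """
    nir, red = pair.nir.values, pair.red.values
    total = nir + red
    mask = pair.nir.nodata_mask | pair.red.nodata_mask
    zero = (total == 0) & ~mask
    if zero.any():
        warnings.warn(f"ndvi: masked {int(zero.sum())} cells with NIR + R = 0")
        mask = mask | zero
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (nir - red) / total
    values[mask] = np.nan
    return GridLayer("ndvi", values, mask, pair.nir.cell_size, pair.nir.origin)


def vci(ndvi_layer: GridLayer) -> GridLayer:
    """Vegetation coverage index: NDVI min-max scaled over the study grid, in [0, 1]."""
    vals = ndvi_layer.unmasked()
    if vals.size < 2 or vals.min() == vals.max():
        raise DegenerateInputError(
            "vci: NDVI layer needs at least two distinct unmasked values"
        )
    lo, hi = vals.min(), vals.max()
    scaled = (ndvi_layer.values - lo) / (hi - lo)
    return ndvi_layer.with_values(scaled, name="vci")


def minmax_normalize(layer: GridLayer, direction: str = "benefit") -> GridLayer:
    """Min-max scale a layer to [0, 1].

    direction 'benefit' maps the minimum to 0; 'cost' maps the minimum to 1.
    """
    if direction not in ("benefit", "cost"):
        raise ValidationError(f"unknown direction {direction!r}")
    vals = layer.unmasked()
    if vals.size < 2 or vals.min() == vals.max():
        raise DegenerateInputError(f"minmax_normalize: layer {layer.name!r} has degenerate range")
    lo, hi = vals.min(), vals.max()
    if direction == "benefit":
        scaled = (layer.values - lo) / (hi - lo)
    else:
        scaled = (hi - layer.values) / (hi - lo)
    return layer.with_values(scaled)
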