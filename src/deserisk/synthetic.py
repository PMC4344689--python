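"""Synthetic study inputs: autocorrelated indicator fields, regions, loss layer.

Stands in for the undeposited study data so the whole pipeline is testable
offline: each indicator is a kernel-smoothed Gaussian white-noise field
rescaled into its configured value envelope on a ~1 km grid; the study area
is partitioned into contiguous (Voronoi) administrative regions; and a
biomass-loss layer is linearly coupled to the computed risk index with
additive Gaussian noise, mirroring the loss-vs-risk validation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, spatial

from .config import IndicatorConfigTable, canonical_config
from .errors import DegenerateInputError, ValidationError
from .grid import GridLayer


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the study setting: a 1 km grid, 13 administrative
    regions, 19 indicators spanning their tabulated value envelopes, and a
    loss layer whose regional means correlate strongly (R^2 near 0.85) with
    the risk index.
    """

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 1.0  # km
    indicators: IndicatorConfigTable = field(default_factory=canonical_config)
    smoothing_cells: int = 5
    n_regions: int = 13
    loss_slope: float = 100.0  # loss units per unit risk index
    loss_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        nrows, ncols = self.shape
        if nrows < 1 or ncols < 1:
            raise ValidationError("grid must have at least one cell")
        if self.n_regions < 2:
            raise ValidationError("need at least 2 regions")
        if self.smoothing_cells < 1:
            raise ValidationError("smoothing length-scale must be >= 1 cell")
        if self.loss_noise_sd < 0:
            raise ValidationError("noise standard deviation must be >= 0")


def _smooth_field(rng: np.random.Generator, shape, smoothing_cells: int) -> np.ndarray:
    """Moving-average-smoothed white noise; larger kernels give longer-range correlation."""
    noise = rng.standard_normal(shape)
    return ndimage.uniform_filter(noise, size=smoothing_cells, mode="reflect")


def _rescale(field_values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field_values.min(), field_values.max()
    if fmax == fmin:
        # constant field (e.g. 1x1 grid): park it mid-envelope
        return np.full_like(field_values, (lo + hi) / 2.0)
    return lo + (field_values - fmin) * (hi - lo) / (fmax - fmin)


def generate_indicator_layers(config: SyntheticConfig) -> list[GridLayer]:
    """One spatially autocorrelated layer per configured indicator.

    Each layer's values exactly span the indicator's (level-1 lower,
    level-5 upper) envelope; deterministic given the seed.
    """
    child_seeds = np.random.SeedSequence(config.seed).spawn(len(config.indicators))
    layers = []
    for spec, child in zip(config.indicators, child_seeds):
        rng = np.random.default_rng(child)
        f = _smooth_field(rng, config.shape, config.smoothing_cells)
        values = _rescale(f, *spec.envelope)
        layers.append(
            GridLayer(
                name=spec.name,
                values=values,
                nodata_mask=np.zeros(config.shape, dtype=bool),
                cell_size=config.cell_size,
            )
        )
    return layers


def generate_regions(shape, k: int, seed: int = 0, cell_size: float = 1.0) -> GridLayer:
    """Seeded Voronoi partition of the grid into k contiguous labeled regions.

    Labels run 1..k; every cell is labeled and every region contains at
    least its own seed cell (Voronoi cells on a grid are connected).
    """
    nrows, ncols = shape
    n_cells = nrows * ncols
    if k > n_cells:
        raise DegenerateInputError(f"cannot place {k} regions on {n_cells} cells")
    if k < 1:
        raise ValidationError("need at least 1 region")
    rng = np.random.default_rng(seed)
    centers_flat = rng.choice(n_cells, size=k, replace=False)
    centers = np.column_stack(np.unravel_index(centers_flat, shape))
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    points = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = spatial.cKDTree(centers).query(points)
    labels = (nearest + 1).reshape(shape).astype(float)
    return GridLayer(
        name="regions",
        values=labels,
        nodata_mask=np.zeros(shape, dtype=bool),
        cell_size=cell_size,
    )


def generate_biomass_losses(
    true_risk: GridLayer, slope: float, noise_sd: float, seed: int = 0
) -> GridLayer:
    """Loss layer linearly coupled to the risk index: slope * risk + noise, floored at 0."""
    if slope < 0:
        raise ValidationError("loss slope must be non-negative (losses rise with risk)")
    if noise_sd < 0:
        raise ValidationError("noise standard deviation must be >= 0")
    vals = true_risk.unmasked()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValidationError("true risk layer must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=true_risk.shape) if noise_sd > 0 else 0.0
    losses = np.maximum(true_risk.values * slope + noise, 0.0)
    return true_risk.with_values(losses, name="biomass_loss")
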