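"""Raster container and ESRI ASCII grid I/O.

All layers in a run live on one shared grid: row 0 is the northernmost row,
the origin is the lower-left corner, and the cell size is stored in km
(ESRI headers carry cellsize in metres; 1000 m = 1 km).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GridFormatError, ValidationError

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
DEFAULT_NODATA = -9999.0


@dataclass
class GridLayer:
    """One named indicator or result raster.

    Parameters
    ----------
    name : str
        Indicator or result name.
    values : ndarray of shape (nrows, ncols)
        Cell values, row-major, north-up.
    nodata_mask : ndarray of bool, same shape
        True marks a nodata cell; masked cells are excluded from all statistics.
    cell_size : float
        Cell edge length in km.
    origin : tuple of (x, y)
        Coordinates of the lower-left corner.
    """

    name: str
    values: np.ndarray
    nodata_mask: np.ndarray = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"layer {self.name!r}: values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValidationError(
                f"layer {self.name!r}: mask shape {self.nodata_mask.shape} "
                f"!= values shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ValidationError(f"layer {self.name!r}: cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """Values at valid cells, as a flat array."""
        return self.values[~self.nodata_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GridLayer":
        """New layer on the same grid with replaced values (mask unioned with non-finite)."""
        values = np.asarray(values, dtype=float)
        mask = self.nodata_mask | ~np.isfinite(values)
        return GridLayer(name or self.name, values, mask, self.cell_size, self.origin)

    def same_grid(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


def require_shared_grid(layers: list[GridLayer]) -> None:
    """Raise unless all layers share shape, origin and cell size."""
    if not layers:
        raise ValidationError("no layers given")
    first = layers[0]
    for layer in layers[1:]:
        if not first.same_grid(layer):
            raise ValidationError(
                f"layers {first.name!r} and {layer.name!r} are not on the same grid"
            )


def read_ascii_grid(path: str | Path, name: str | None = None) -> GridLayer:
    """Read an ESRI ASCII grid file into a :class:`GridLayer`.

    The header must carry ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (default -9999). Cells equal to NODATA_value
    are masked. The file's cellsize is interpreted in metres.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(tokens) != 2:
                raise GridFormatError(f"{path}: malformed header line {line!r}")
            header[key] = float(tokens[1])
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"{path}: missing header key {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    for row_index, line in enumerate(lines[i:]):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != ncols:
            raise GridFormatError(
                f"{path}: data row {row_index} has {len(tokens)} values, expected {ncols}"
            )
        try:
            data_rows.append(np.array(tokens, dtype=float))
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric token in data row {row_index}") from exc
    if len(data_rows) != nrows:
        raise GridFormatError(f"{path}: {len(data_rows)} data rows, header says {nrows}")
    values = np.vstack(data_rows) if data_rows else np.empty((0, ncols))
    mask = values == nodata
    return GridLayer(
        name=name or path.stem,
        values=values,
        nodata_mask=mask,
        cell_size=header["cellsize"] / 1000.0,
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_ascii_grid(
    layer: GridLayer,
    path: str | Path,
    nodata: float = DEFAULT_NODATA,
    fmt: str = "%.17g",
) -> Path:
    """Write a layer as an ESRI ASCII grid; the emitted file re-reads to an equal layer.

    The default format round-trips doubles exactly.
    """
    path = Path(path)
    nrows, ncols = layer.shape
    out = layer.values.copy()
    out[layer.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {layer.origin[0]:.17g}\n")
        fh.write(f"yllcorner {layer.origin[1]:.17g}\n")
        fh.write(f"cellsize {layer.cell_size * 1000.0:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")
    return path
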