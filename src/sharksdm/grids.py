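"""Raster data model and bathymetry-derived predictor layers.

The study area is a rectangular grid of square cells in a projected planar
coordinate system (meters).  All environmental predictors — depth, terrain
derivatives, distance-to-isobath layers, chlorophyll-a and SST climatologies —
live on the same registration as :class:`Grid` objects, grouped per month into
an :class:`EnvStack`.  Rasters are exchanged on disk as ESRI ASCII grids
(plain text), the lingua franca of desktop GIS.

Conventions
-----------
* ``values`` is row-major with row 0 at the **north** edge.
* ``x_origin``/``y_origin`` are the lower-left corner of the lower-left cell.
* The cell center of row ``i``, column ``j`` is
  ``(x_origin + (j + 0.5) * cell_size, y_origin + (nrows - i - 0.5) * cell_size)``.
* ``mask`` is True where data are missing; masked cells are excluded from
  every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Grid",
    "EnvStack",
    "GridFormatError",
    "RegistrationError",
    "ContourAbsentError",
    "ENV_VARIABLES",
    "MONTHS",
    "read_ascii_grid",
    "write_ascii_grid",
    "slope_aspect",
    "distance_to_contour",
    "resample_nearest",
    "climatology_mean",
]

#: Predictor names of one monthly environmental stack.
ENV_VARIABLES = (
    "depth",
    "aspect",
    "slope",
    "dist_0",
    "dist_50",
    "dist_100",
    "dist_150",
    "dist_200",
    "chl_a",
    "sst",
)

#: Analysis months (peak basking-shark season in the lower Bay of Fundy).
MONTHS = ("July", "August", "September", "October")


class GridFormatError(ValueError):
    """Raised for a malformed ESRI ASCII grid file."""


class RegistrationError(ValueError):
    """Raised when grids that must share shape/origin/cell size do not."""


class ContourAbsentError(ValueError):
    """Raised when a requested depth contour does not exist in a grid."""


@dataclass
class Grid:
    """A single raster layer: values + missing-data mask + georeferencing."""

    values: np.ndarray
    mask: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs_label: str = "projected-m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of grid shape."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x < self.x_origin + self.ncols * self.cell_size
            and self.y_origin <= y < self.y_origin + self.nrows * self.cell_size
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (no bounds check)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = self.nrows - 1 - int(np.floor((y - self.y_origin) / self.cell_size))
        return row, col

    # -- values -------------------------------------------------------------

    @property
    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_registration(self, other: "Grid", *, rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin, rtol=rtol)
            and np.isclose(self.y_origin, other.y_origin, rtol=rtol)
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
        )

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """A new grid on this registration with different values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
        )

    def __eq__(self, other: object) -> bool:  # value equality, used in round trips
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.same_registration(other)
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values[~self.mask], other.values[~other.mask])
        )


@dataclass
class EnvStack:
    """Co-registered monthly predictor layers under an intersection mask.

    A cell masked in any layer (e.g. the near-shore exclusion zone, or flat
    cells whose aspect is undefined) is masked in all layers, so every
    statistic downstream sees one common set of valid cells.
    """

    month: str
    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.month not in MONTHS:
            raise ValueError(f"month must be one of {MONTHS}, got {self.month!r}")
        unknown = set(self.layers) - set(ENV_VARIABLES)
        if unknown:
            raise ValueError(f"unknown layer names: {sorted(unknown)}")
        grids = list(self.layers.values())
        if grids:
            ref = grids[0]
            for name, g in self.layers.items():
                if not g.same_registration(ref):
                    raise RegistrationError(f"layer {name!r} is not co-registered")
            common = np.zeros(ref.shape, dtype=bool)
            for g in grids:
                common |= g.mask
            for name, g in list(self.layers.items()):
                self.layers[name] = g.like(g.values, common)

    @property
    def mask(self) -> np.ndarray:
        ref = next(iter(self.layers.values()))
        return ref.mask

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in ENV_VARIABLES if v in self.layers)

    def unmasked_cells(self) -> np.ndarray:
        """(n, 2) array of (row, col) of valid cells, row-major order."""
        rows, cols = np.nonzero(~self.mask)
        return np.column_stack([rows, cols])

    def values_at(self, cells: np.ndarray) -> np.ndarray:
        """(n_cells, n_variables) matrix of predictor values."""
        cells = np.asarray(cells)
        out = np.empty((len(cells), len(self.variables)))
        for k, name in enumerate(self.variables):
            out[:, k] = self.layers[name].values[cells[:, 0], cells[:, 1]]
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
_DEFAULT_NODATA = -9999.0


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc) file.

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (default -9999).  Cells equal to NODATA_value
    become masked.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            body_start = i + 1
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"{path}: malformed header line {i + 1}: {line!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: unparseable header value on line {i + 1}: {line!r}"
                ) from exc
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing {missing}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols < 1 or nrows < 1:
        raise GridFormatError(f"{path}: non-positive grid dimensions")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)

    rows: list[np.ndarray] = []
    for i, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        try:
            row = np.array([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GridFormatError(f"{path}: unparseable value on line {i}") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"{path}: line {i} has {row.size} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: found {len(rows)} data rows, expected {nrows}")
    values = np.vstack(rows)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return Grid(
        values=values,
        mask=mask,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
    )


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = _DEFAULT_NODATA) -> Path:
    """Write a grid as an ESRI ASCII file; masked cells become NODATA_value."""
    path = Path(path)
    vals = np.where(grid.mask, nodata, grid.values)
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {_fmt(grid.x_origin)}",
        f"yllcorner {_fmt(grid.y_origin)}",
        f"cellsize {_fmt(grid.cell_size)}",
        f"NODATA_value {_fmt(nodata)}",
    ]
    lines += [" ".join(_fmt(v) for v in row) for row in vals]
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt(v: float) -> str:
    """Canonical number formatting: shortest repr that round-trips."""
    if np.isnan(v):
        return "nan"
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------


def slope_aspect(depth: Grid) -> tuple[Grid, Grid]:
    """Seafloor slope (degrees) and aspect (compass degrees) from a depth grid.

    Central differences on the 4-neighborhood: a cell needs itself and all four
    neighbors unmasked, so the outer ring is masked.  Slope is
    ``arctan(|∇ depth|)`` in degrees; aspect is the compass direction of
    steepest descent of the seafloor (i.e. of increasing depth, depth positive
    down), clockwise from north.  Cells with zero gradient have slope 0 and
    masked aspect.
    """
    if depth.nrows < 3 or depth.ncols < 3:
        raise ValueError("slope_aspect needs a grid of at least 3x3 cells")
    z = depth.values
    c = depth.cell_size
    valid = ~depth.mask

    dzdx = np.full(z.shape, np.nan)
    dzdy = np.full(z.shape, np.nan)  # northward derivative
    interior = np.zeros(z.shape, dtype=bool)
    interior[1:-1, 1:-1] = (
        valid[1:-1, 1:-1]
        & valid[1:-1, :-2]
        & valid[1:-1, 2:]
        & valid[:-2, 1:-1]
        & valid[2:, 1:-1]
    )
    # row 0 is the north edge: northward difference is row i-1 minus row i+1
    dzdx[1:-1, 1:-1] = (z[1:-1, 2:] - z[1:-1, :-2]) / (2 * c)
    dzdy[1:-1, 1:-1] = (z[:-2, 1:-1] - z[2:, 1:-1]) / (2 * c)

    grad = np.hypot(dzdx, dzdy)
    slope_vals = np.degrees(np.arctan(grad))
    aspect_vals = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0

    slope_mask = ~interior
    aspect_mask = ~interior | (grad == 0)
    slope_vals = np.where(slope_mask, np.nan, slope_vals)
    aspect_vals = np.where(aspect_mask, np.nan, aspect_vals)
    return depth.like(slope_vals, slope_mask), depth.like(aspect_vals, aspect_mask)


def _contour_cells(depth: Grid, level: float) -> np.ndarray:
    """Boolean array marking contour cells for an isobath level.

    A contour cell is an unmasked cell that equals the level exactly, or one
    of a 4-neighbor pair lying strictly on opposite sides of the level.
    """
    z = depth.values
    valid = ~depth.mask
    on = valid & (z == level)
    above = valid & (z > level)
    below = valid & (z < level)

    def _pair(a: np.ndarray, b: np.ndarray, axis: int) -> np.ndarray:
        out = np.zeros_like(a)
        if axis == 0:
            hit = a[:-1, :] & b[1:, :]
            out[:-1, :] |= hit
            out[1:, :] |= hit
        else:
            hit = a[:, :-1] & b[:, 1:]
            out[:, :-1] |= hit
            out[:, 1:] |= hit
        return out

    straddle = np.zeros_like(on)
    for axis in (0, 1):
        straddle |= _pair(above, below, axis)
        straddle |= _pair(below, above, axis)
    return on | straddle


def distance_to_contour(depth: Grid, level: float) -> Grid:
    """Euclidean distance (m) from every cell center to the nearest contour cell.

    Contour cells (see :func:`_contour_cells`) have distance 0.  Raises
    :class:`ContourAbsentError` when the isobath does not exist in the grid.
    """
    contour = _contour_cells(depth, level)
    if not contour.any():
        raise ContourAbsentError(f"no cell straddles the {level} m contour")
    x, y = depth.cell_centers()
    cpts = np.column_stack([x[contour], y[contour]])
    tree = cKDTree(cpts)
    qpts = np.column_stack([x.ravel(), y.ravel()])
    dist, _ = tree.query(qpts)
    vals = dist.reshape(depth.shape)
    vals = np.where(depth.mask, np.nan, vals)
    return depth.like(vals, depth.mask.copy())


# ---------------------------------------------------------------------------
# Resampling and climatology
# ---------------------------------------------------------------------------


def resample_nearest(grid: Grid, target_cell_size: float) -> Grid:
    """Nearest-neighbor resampling to a new cell size over the same extent.

    Each output cell takes the value (and mask) of the input cell containing
    the output cell center.  The output dimension is the rounded number of
    target cells spanning the input extent.
    """
    if not target_cell_size > 0:
        raise ValueError("target_cell_size must be positive")
    if target_cell_size == grid.cell_size:
        return grid.like(grid.values.copy())
    width = grid.ncols * grid.cell_size
    height = grid.nrows * grid.cell_size
    ncols = max(1, int(round(width / target_cell_size)))
    nrows = max(1, int(round(height / target_cell_size)))

    xc = grid.x_origin + (np.arange(ncols) + 0.5) * target_cell_size
    yc = grid.y_origin + (nrows - np.arange(nrows) - 0.5) * target_cell_size
    src_col = np.clip(
        np.floor((xc - grid.x_origin) / grid.cell_size).astype(int), 0, grid.ncols - 1
    )
    src_row = np.clip(
        (grid.nrows - 1 - np.floor((yc - grid.y_origin) / grid.cell_size)).astype(int),
        0,
        grid.nrows - 1,
    )
    values = grid.values[np.ix_(src_row, src_col)]
    mask = grid.mask[np.ix_(src_row, src_col)]
    return Grid(
        values=values,
        mask=mask,
        x_origin=grid.x_origin,
        y_origin=grid.y_origin,
        cell_size=target_cell_size,
        crs_label=grid.crs_label,
    )


def climatology_mean(grids: Iterable[Grid]) -> Grid:
    """Cellwise mean over co-registered grids, ignoring masked cells.

    A cell is masked in the result only where it is masked in every input —
    the convention used when averaging monthly satellite composites with
    partial cloud cover.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("climatology_mean needs at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if not g.same_registration(ref):
            raise RegistrationError("climatology_mean inputs are not co-registered")
    stack = np.ma.stack([g.masked for g in grids])
    mean = stack.mean(axis=0)
    mask = np.ma.getmaskarray(mean)
    values = np.where(mask, np.nan, mean.filled(np.nan))
    return ref.like(values, mask)
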