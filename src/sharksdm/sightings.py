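"""Sighting records: ingest, monthly pooling, and the dive-geometry check.

Surface sightings of basking sharks are presence-only records: each row is a
sighting of ``count`` animals at a projected (x, y) location in a given month
and year, from some data source (whale-watch or standardized survey).  Each
record expands to ``count`` individual presences downstream, so a group of
four sharks contributes four presence points at the same location.

The dive-geometry check supports treating surface sightings as proxies for
habitat at depth: given a mean vertical movement rate, dive-phase duration
and pitch angle, the horizontal displacement of an average descent or ascent
is ``|rate| * duration * tan(90° - |pitch|)``.  When this is small relative
to the model cell size (2.5 km here), a surface sighting stays within the
cell of the underlying habitat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import Grid, MONTHS

__all__ = [
    "SightingTable",
    "DiveGeometry",
    "CellAssignment",
    "collate",
    "monthly_summary",
    "horizontal_displacement",
    "presences_to_cells",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["x", "y", "year", "month", "count", "source"]

_MONTH_ALIASES = {m.lower(): m for m in MONTHS}
_MONTH_ALIASES.update({m.lower()[:3]: m for m in MONTHS})
_MONTH_ALIASES.update({"7": "July", "8": "August", "9": "September", "10": "October"})


def _parse_month(raw: object, row: int) -> str:
    key = str(raw).strip().lower()
    if key in _MONTH_ALIASES:
        return _MONTH_ALIASES[key]
    raise ValueError(f"row {row}: unparseable month {raw!r} (expected one of {MONTHS})")


@dataclass
class SightingTable:
    """Validated table of sighting records with columns x,y,year,month,count,source."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sighting table missing columns: {missing}")
        self.frame = self.frame[_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_individuals(self) -> int:
        return int(self.frame["count"].sum())

    def for_month(self, month: str) -> "SightingTable":
        return SightingTable(self.frame[self.frame["month"] == month].copy())

    def expand(self) -> pd.DataFrame:
        """One row per individual presence (records repeated by count)."""
        reps = self.frame.loc[
            self.frame.index.repeat(self.frame["count"].to_numpy())
        ].copy()
        reps["count"] = 1
        return reps.reset_index(drop=True)

    def points(self, expanded: bool = True) -> np.ndarray:
        """(n, 2) array of x,y; expanded per individual by default."""
        df = self.expand() if expanded else self.frame
        return df[["x", "y"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path


def collate(csv: str | Path | pd.DataFrame) -> SightingTable:
    """Load and validate a sightings CSV, pooling all sources together.

    Rows with non-positive counts or unparseable months are rejected with the
    offending (0-based) data row index in the error message.
    """
    df = csv.copy() if isinstance(csv, pd.DataFrame) else pd.read_csv(csv)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sightings CSV missing columns: {missing}")
    df = df[_COLUMNS].reset_index(drop=True)
    df["month"] = [_parse_month(m, i) for i, m in enumerate(df["month"])]
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 1) | (counts != counts.round())
    if bad.any():
        rows = list(df.index[bad])
        raise ValueError(f"invalid count (must be a positive integer) at rows {rows}")
    df["count"] = counts.astype(int)
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    df["x"] = pd.to_numeric(df["x"]).astype(float)
    df["y"] = pd.to_numeric(df["y"]).astype(float)
    return SightingTable(df)


def monthly_summary(table: SightingTable) -> pd.DataFrame:
    """Per-month individual counts and percent of total (2 decimals).

    Percentages are 100·count/total rounded to 2 decimals, the resolution at
    which monthly sighting shares are conventionally reported.
    """
    if len(table) == 0:
        raise ValueError("monthly_summary needs at least one record")
    counts = (
        table.frame.groupby("month")["count"].sum().reindex(MONTHS).dropna().astype(int)
    )
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "month": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 2),
        }
    ).reset_index(drop=True)
    out.attrs["total"] = total
    return out


@dataclass(frozen=True)
class DiveGeometry:
    """Mean dive-phase kinematics: vertical rate (m/s), duration (s), pitch (deg)."""

    vertical_rate: float
    duration: float
    pitch: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0 < abs(self.pitch) < 90:
            raise ValueError("pitch must be strictly between 0 and 90 degrees in magnitude")


def horizontal_displacement(g: DiveGeometry) -> float:
    """Horizontal distance (m) covered during a dive phase.

    ``|vertical_rate| * duration`` is the vertical distance; dividing by the
    tangent of the pitch (equivalently multiplying by tan(90° − |pitch|))
    converts it to the horizontal leg of the dive track.
    """
    vertical = abs(g.vertical_rate) * g.duration
    return vertical * math.tan(math.radians(90.0 - abs(g.pitch)))


@dataclass
class CellAssignment:
    """Presences mapped to grid cells, with counts of dropped points."""

    cells: np.ndarray  # (n, 2) row/col per retained presence
    n_dropped_masked: int
    n_dropped_outside: int

    def __len__(self) -> int:
        return len(self.cells)


def presences_to_cells(
    table_or_points: SightingTable | np.ndarray | Sequence[Sequence[float]],
    grid: Grid,
    month: str | None = None,
) -> CellAssignment:
    """Map expanded presences to containing grid cells.

    Points outside the grid extent or landing on masked cells are dropped with
    a logged count rather than raising — field sighting data are messy.
    """
    if isinstance(table_or_points, SightingTable):
        table = table_or_points
        if month is not None:
            table = table.for_month(month)
        pts = table.points(expanded=True)
    else:
        pts = np.asarray(table_or_points, dtype=float).reshape(-1, 2)

    cells: list[tuple[int, int]] = []
    dropped_outside = 0
    dropped_masked = 0
    for x, y in pts:
        if not grid.contains(x, y):
            dropped_outside += 1
            continue
        row, col = grid.cell_of(x, y)
        if grid.mask[row, col]:
            dropped_masked += 1
            continue
        cells.append((row, col))
    if dropped_outside:
        logger.warning("dropped %d presences outside the grid extent", dropped_outside)
    if dropped_masked:
        logger.warning("dropped %d presences on masked cells", dropped_masked)
    arr = np.array(cells, dtype=int).reshape(-1, 2)
    return CellAssignment(arr, dropped_masked, dropped_outside)
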