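"""Threshold habitat delineation and month-to-month distribution comparison.

A cumulative suitability map becomes a binary habitat map by thresholding at
the max-sensitivity+specificity score: a cell is suitable iff its cumulative
score is ≥ the threshold (so threshold 0 marks everything suitable).  Areas
are counted over unmasked cells only, in km².

Monthly suitability surfaces are compared with the (Brownian) distance
correlation, a [0,1] dependence measure computed from double-centered
pairwise distance matrices of the two surfaces' cell values; it is 0 in the
population exactly under independence and 1 for affinely related surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grids import Grid, RegistrationError
from .maxent import SuitabilityMap

__all__ = [
    "HabitatSummary",
    "binarize",
    "distance_correlation",
    "compare_months",
]


@dataclass
class HabitatSummary:
    """Binary habitat map plus its area bookkeeping."""

    threshold: float
    binary: Grid | None
    suitable_area: float  # km²
    percent_suitable: float
    total_area: float  # km²

    @classmethod
    def from_areas(
        cls, threshold: float, suitable_area: float, total_area: float
    ) -> "HabitatSummary":
        """Summary from areas alone (no map): percent = 100·suitable/total."""
        if not total_area > 0:
            raise ValueError("total_area must be positive")
        return cls(
            threshold=threshold,
            binary=None,
            suitable_area=float(suitable_area),
            percent_suitable=100.0 * suitable_area / total_area,
            total_area=float(total_area),
        )


def _as_grid(obj: SuitabilityMap | Grid) -> Grid:
    if isinstance(obj, SuitabilityMap):
        return obj.best
    return obj


def binarize(smap: SuitabilityMap | Grid, threshold: float) -> HabitatSummary:
    """Binary suitable/unsuitable habitat at a cumulative-score threshold.

    Suitable means cumulative ≥ threshold.  For a replicate ensemble the
    replicate-mean map is thresholded.  Areas come from unmasked cells times
    the cell area.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    grid = _as_grid(smap)
    suitable = (~grid.mask) & (grid.values >= threshold)
    binary_vals = np.where(grid.mask, np.nan, suitable.astype(float))
    binary = grid.like(binary_vals, grid.mask.copy())
    cell_km2 = grid.cell_area_km2
    n_valid = int((~grid.mask).sum())
    n_suit = int(suitable.sum())
    total_area = n_valid * cell_km2
    suitable_area = n_suit * cell_km2
    return HabitatSummary(
        threshold=float(threshold),
        binary=binary,
        suitable_area=suitable_area,
        percent_suitable=100.0 * suitable_area / total_area if total_area else 0.0,
        total_area=total_area,
    )


def _joint_values(a: Grid, b: Grid) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_registration(b):
        raise RegistrationError("suitability maps are not co-registered")
    ok = ~(a.mask | b.mask)
    return a.values[ok], b.values[ok]


def _dcov_sq(A: np.ndarray, B: np.ndarray) -> float:
    return float((A * B).mean())


def _center(x: np.ndarray) -> np.ndarray:
    d = squareform(pdist(x[:, None]))
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(
    a: SuitabilityMap | Grid | np.ndarray, b: SuitabilityMap | Grid | np.ndarray
) -> float:
    """Sample distance correlation between two surfaces' cell values.

    Pairwise absolute-difference matrices of each surface are double-centered
    (subtract row and column means, add the grand mean); the distance
    covariance is the mean elementwise product, each distance variance the
    mean elementwise square, and the correlation is
    ``sqrt(dCov² / sqrt(dVar_A · dVar_B))`` — 0 when either surface has no
    variation.
    """
    if isinstance(a, (SuitabilityMap, Grid)) and isinstance(b, (SuitabilityMap, Grid)):
        va, vb = _joint_values(_as_grid(a), _as_grid(b))
    else:
        va = np.asarray(a, dtype=float).ravel()
        vb = np.asarray(b, dtype=float).ravel()
        if va.shape != vb.shape:
            raise ValueError("value vectors must have equal length")
    if len(va) < 2:
        raise ValueError("need at least 2 jointly unmasked cells")
    A = _center(va)
    B = _center(vb)
    dvar_a = _dcov_sq(A, A)
    dvar_b = _dcov_sq(B, B)
    if dvar_a <= 0 or dvar_b <= 0:
        return 0.0
    dcov2 = _dcov_sq(A, B)
    r2 = dcov2 / np.sqrt(dvar_a * dvar_b)
    return float(np.sqrt(max(r2, 0.0)))


def compare_months(maps: Mapping[str, SuitabilityMap | Grid]) -> pd.DataFrame:
    """Symmetric matrix of pairwise distance correlations between months."""
    months = list(maps)
    if len(months) < 2:
        raise ValueError("compare_months needs at least 2 months")
    out = pd.DataFrame(np.eye(len(months)), index=months, columns=months)
    for i, mi in enumerate(months):
        for j in range(i + 1, len(months)):
            mj = months[j]
            r = distance_correlation(maps[mi], maps[mj])
            out.iloc[i, j] = r
            out.iloc[j, i] = r
    return out
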