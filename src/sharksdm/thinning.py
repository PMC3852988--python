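"""Spatial autocorrelation diagnostics and nearest-neighbor thinning.

Sighting effort at sea is rarely uniform: whale-watch vessels concentrate
near port, so raw sightings are spatially clustered and violate the
independence the presence-only model assumes.  The remedy used here is
decimation to the expected average-nearest-neighbor (ANN) spacing: compute
the mean nearest-neighbor distance a random pattern of the same intensity
would show, ``0.5 / sqrt(n / A)``, then greedily drop points closer than
that to an already-kept point.  Months left with very few points are not
thinned at all (small samples carry little redundancy and every record
counts).

Moran's I correlograms and semivariograms are provided as diagnostics of the
residual autocorrelation structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AnnResult",
    "ThinResult",
    "ann_statistic",
    "decimate",
    "thin_month",
    "morans_i_correlogram",
    "semivariogram",
]


@dataclass(frozen=True)
class AnnResult:
    """Average-nearest-neighbor statistic: observed vs expected under CSR."""

    n: int
    observed_mean_nn: float
    expected_mean_nn: float
    ratio: float
    area_used: float


@dataclass
class ThinResult:
    points: np.ndarray
    ann: AnnResult
    skipped: bool


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pts


def ann_statistic(points, area: float | None = None) -> AnnResult:
    """Observed vs expected mean nearest-neighbor distance.

    ``expected = 0.5 / sqrt(n / A)`` is the mean NN distance under complete
    spatial randomness at intensity n/A.  When no study area is supplied the
    minimum bounding rectangle of the points is used (the common GIS default).
    A ratio < 1 indicates clustering, > 1 inhibition/dispersion.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("ann_statistic needs at least 2 points")
    if area is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        area = float(span[0] * span[1])
    if not area > 0:
        raise ValueError("study area must be positive (degenerate bounding rectangle?)")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    observed = float(dist[:, 1].mean())
    expected = 0.5 / np.sqrt(n / area)
    return AnnResult(n, observed, float(expected), observed / expected, float(area))


def decimate(points, min_distance: float, seed: int = 0) -> np.ndarray:
    """Greedy thinning: keep points at least ``min_distance`` from kept points.

    Points are visited in a seeded random order; a point is kept iff it is at
    least ``min_distance`` from every already-kept point.  The retained set is
    returned in the original input order, making the sparse case an identity.
    """
    pts = _as_points(points)
    if min_distance < 0:
        raise ValueError("min_distance must be non-negative")
    if min_distance == 0 or len(pts) == 0:
        return pts.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    kept_idx: list[int] = []
    kept_pts: list[np.ndarray] = []
    for i in order:
        p = pts[i]
        if all(np.hypot(*(p - q)) >= min_distance for q in kept_pts):
            kept_idx.append(i)
            kept_pts.append(p)
    kept_idx.sort()
    return pts[kept_idx]


def thin_month(
    points,
    area: float | None = None,
    seed: int = 0,
    skip_threshold: int = 5,
) -> ThinResult:
    """ANN-based monthly thinning with a small-sample escape hatch.

    Decimates at the expected ANN spacing; if the thinned set would have
    ``skip_threshold`` or fewer points, the original (unthinned) points are
    returned with ``skipped=True`` — months with so few sightings are used
    as-is.
    """
    pts = _as_points(points)
    if len(pts) < 1:
        raise ValueError("thin_month needs at least one point")
    if len(pts) < 2:
        ann = AnnResult(len(pts), 0.0, 0.0, float("nan"), area or 0.0)
        return ThinResult(pts.copy(), ann, True)
    ann = ann_statistic(pts, area=area)
    thinned = decimate(pts, ann.expected_mean_nn, seed=seed)
    if len(thinned) <= skip_threshold:
        return ThinResult(pts.copy(), ann, True)
    return ThinResult(thinned, ann, False)


def _pair_bins(points, values, bin_edges):
    pts = _as_points(points)
    vals = np.asarray(values, dtype=float)
    if len(pts) != len(vals):
        raise ValueError("points and values must have equal length")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("bin_edges must be a 1-D array of at least 2 edges")
    d = pdist(pts)
    return pts, vals, edges, d


def morans_i_correlogram(points, values, bin_edges) -> pd.DataFrame:
    """Moran's I per distance bin, with binary in-bin weights.

    For each bin, w_ij = 1 if the pair distance falls in [lo, hi), and
    ``I = (n / ΣΣ w_ij) · (ΣΣ w_ij z_i z_j) / (Σ z_i²)`` with z the centered
    values.  Empty bins are omitted from the output.  Under no spatial
    structure E[I] = −1/(n−1).
    """
    pts, vals, edges, d = _pair_bins(points, values, bin_edges)
    n = len(pts)
    if n < 3:
        raise ValueError("morans_i_correlogram needs at least 3 points")
    z = vals - vals.mean()
    denom = float((z**2).sum())
    if denom == 0:
        raise ValueError("values are constant; Moran's I is undefined")
    dmat = squareform(d)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = (dmat >= lo) & (dmat < hi)
        np.fill_diagonal(w, False)
        wsum = int(w.sum())
        if wsum == 0:
            continue
        cross = float(z @ w @ z)
        moran = (n / wsum) * cross / denom
        rows.append({"bin_lo": lo, "bin_hi": hi, "n_pairs": wsum // 2, "morans_i": moran})
    if not rows:
        raise ValueError("no distance bin contains any pair of points")
    return pd.DataFrame(rows)


def semivariogram(points, values, bin_edges) -> pd.DataFrame:
    """Empirical semivariogram: γ(bin) = mean over in-bin pairs of ½(v_i − v_j)²."""
    pts, vals, edges, d = _pair_bins(points, values, bin_edges)
    if len(pts) < 2:
        raise ValueError("semivariogram needs at least 2 points")
    sq = 0.5 * pdist(vals[:, None], metric="sqeuclidean")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        npairs = int(sel.sum())
        if npairs == 0:
            continue
        rows.append(
            {"bin_lo": lo, "bin_hi": hi, "n_pairs": npairs, "gamma": float(sq[sel].mean())}
        )
    if not rows:
        raise ValueError("no distance bin contains any pair of points")
    return pd.DataFrame(rows)
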