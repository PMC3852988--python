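"""Presence-only maximum-entropy density estimation over raster cells.

The model seeks the probability distribution p over background cells that is
closest to uniform (maximum entropy) subject to matching the empirical means
of environmental "features" at the presence cells.  In its dual form this is
a Gibbs distribution p_λ(i) ∝ exp(Σ_j λ_j f_j(i)) fitted by maximizing the
L1-penalized average log probability of the presences:

    (1/m) Σ_presence log p_λ(i)  −  β Σ_j s_j |λ_j|

where s_j = SD of feature j over the background, scaled by 1/√m.  The L1
penalty (regularization multiplier β) zeroes weak weights and smooths the
fitted surface.  Covariates are expanded into the usual feature suite:
linear, quadratic, pairwise product, threshold (step) and hinge.

The fitted raw distribution sums to 1 over background cells; the cumulative
transform rescales it to 0–100, where a cell's score is 100 times the total
raw probability of all cells with equal or lower probability (the best cell
scores 100).

Fitting is by proximal-gradient (ISTA) ascent with backtracking line search:
deterministic, with exact zeros from soft-thresholding so that the count of
nonzero weights — the parameter count used by AICc — is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .grids import EnvStack, Grid

__all__ = [
    "FeatureMeta",
    "FeatureExpansion",
    "MaxentFit",
    "SuitabilityMap",
    "FEATURE_CLASSES",
    "sample_background",
    "build_features",
    "fit_maxent",
    "raw_distribution",
    "cumulative_scores",
    "cumulative_output",
    "training_gain",
]

FEATURE_CLASSES = ("linear", "quadratic", "product", "threshold", "hinge")


@dataclass(frozen=True)
class FeatureMeta:
    """One expanded feature: class, source variable(s), optional knot."""

    cls: str
    variables: tuple[str, ...]
    knot: float | None = None

    def label(self) -> str:
        base = f"{self.cls}({'*'.join(self.variables)}"
        if self.knot is not None:
            base += f"@{self.knot:.6g}"
        return base + ")"


@dataclass
class FeatureExpansion:
    """Design matrix over background∪presence cells plus bookkeeping.

    Rows are the unique background cells (which include every presence cell,
    the Maxent convention); ``presence_rows`` indexes rows with multiplicity,
    one entry per individual presence.
    """

    design: np.ndarray  # (n_cells, n_features), each column scaled to [0,1] over rows
    feature_meta: list[FeatureMeta]
    presence_rows: np.ndarray
    cells: np.ndarray  # (n_cells, 2) row/col in the source grid
    variables: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.design.shape[0]

    @property
    def n_features(self) -> int:
        return self.design.shape[1]

    @property
    def background_rows(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def feature_sd(self) -> np.ndarray:
        return self.design.std(axis=0)

    def columns_for(self, variables: set[str]) -> np.ndarray:
        """Feature column indices whose source variables are all in the set."""
        return np.array(
            [
                j
                for j, meta in enumerate(self.feature_meta)
                if set(meta.variables) <= variables
            ],
            dtype=int,
        )

    def subset(self, variables: set[str]) -> "FeatureExpansion":
        cols = self.columns_for(variables)
        return FeatureExpansion(
            design=self.design[:, cols],
            feature_meta=[self.feature_meta[j] for j in cols],
            presence_rows=self.presence_rows,
            cells=self.cells,
            variables=tuple(v for v in self.variables if v in variables),
        )


@dataclass
class MaxentFit:
    """A fitted maximum-entropy model."""

    lambdas: np.ndarray
    beta: float
    raw: np.ndarray  # probability over background cells, sums to 1
    training_gain: float
    n_params: int
    iterations: int
    converged: bool
    penalty_scale: np.ndarray
    gain_increments: np.ndarray = field(default_factory=lambda: np.empty(0))
    dlambda_trace: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


@dataclass
class SuitabilityMap:
    """Cumulative (0–100) habitat suitability on the model grid."""

    cumulative: Grid
    replicate_mean: Grid | None = None
    replicate_sd: Grid | None = None

    @property
    def best(self) -> Grid:
        """The map to use for comparisons: replicate mean when available."""
        return self.replicate_mean if self.replicate_mean is not None else self.cumulative


# ---------------------------------------------------------------------------
# Background sampling and feature expansion
# ---------------------------------------------------------------------------


def sample_background(
    stack: EnvStack,
    max_points: int = 10000,
    seed: int = 0,
    presence_cells: np.ndarray | None = None,
) -> np.ndarray:
    """Background cell sample: all unmasked cells, capped at ``max_points``.

    When the cap binds, a uniform seeded sample without replacement is drawn;
    presence cells are always unioned in so every presence has a design row.
    Returns unique (row, col) pairs in row-major order.
    """
    cells = stack.unmasked_cells()
    if len(cells) == 0:
        raise ValueError("environmental stack is fully masked")
    if len(cells) > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(cells), size=max_points, replace=False)
        cells = cells[np.sort(idx)]
    if presence_cells is not None and len(presence_cells):
        presence_cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
        cells = np.unique(np.vstack([cells, presence_cells]), axis=0)
    return cells


def _row_lookup(cells: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Map (row, col) queries to row indices in ``cells`` (must be present)."""
    ncol = int(max(cells[:, 1].max(), queries[:, 1].max() if len(queries) else 0)) + 1
    flat = cells[:, 0] * ncol + cells[:, 1]
    qflat = queries[:, 0] * ncol + queries[:, 1]
    order = np.argsort(flat)
    pos = np.searchsorted(flat[order], qflat)
    if np.any(pos >= len(flat)) or np.any(flat[order][np.minimum(pos, len(flat) - 1)] != qflat):
        raise ValueError("presence cell not found among background cells")
    return order[pos]


def build_features(
    stack: EnvStack,
    cells: np.ndarray,
    presence_cells: np.ndarray,
    classes: tuple[str, ...] = FEATURE_CLASSES,
    knots_per_variable: int = 10,
) -> FeatureExpansion:
    """Expand stack variables at the given cells into scaled features.

    Every variable is first min–max scaled to [0,1] over the background rows.
    Linear features are the scaled variable, quadratic its square, product
    the pairwise products of scaled variables; threshold features are step
    indicators 1[x > knot] and hinge features max(0, x − knot)/(max − knot),
    with up to ``knots_per_variable`` knots at evenly spaced interior
    quantiles of the background values.  Variables constant over the
    background are skipped with a warning.
    """
    cells = np.asarray(cells, dtype=int).reshape(-1, 2)
    presence_cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
    if len(cells) == 0:
        raise ValueError("no background cells supplied")
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    X = stack.values_at(cells)
    names = stack.variables
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    keep = hi > lo
    for k, name in enumerate(names):
        if not keep[k]:
            warnings.warn(
                f"variable {name!r} is constant over the background; its features are skipped",
                stacklevel=2,
            )
    names = tuple(n for n, k in zip(names, keep) if k)
    X = X[:, keep]
    lo, hi = lo[keep], hi[keep]
    U = (X - lo) / (hi - lo)

    cols: list[np.ndarray] = []
    meta: list[FeatureMeta] = []

    if "linear" in classes:
        for k, name in enumerate(names):
            cols.append(U[:, k])
            meta.append(FeatureMeta("linear", (name,)))
    if "quadratic" in classes:
        for k, name in enumerate(names):
            cols.append(U[:, k] ** 2)
            meta.append(FeatureMeta("quadratic", (name,)))
    if "product" in classes:
        for a, b in combinations(range(len(names)), 2):
            cols.append(U[:, a] * U[:, b])
            meta.append(FeatureMeta("product", (names[a], names[b])))
    if "threshold" in classes or "hinge" in classes:
        for k, name in enumerate(names):
            qs = np.linspace(0, 1, knots_per_variable + 2)[1:-1]
            knots = np.unique(np.quantile(X[:, k], qs))
            knots = knots[(knots > lo[k]) & (knots < hi[k])]
            for knot in knots:
                if "threshold" in classes:
                    cols.append((X[:, k] > knot).astype(float))
                    meta.append(FeatureMeta("threshold", (name,), float(knot)))
                if "hinge" in classes:
                    cols.append(np.maximum(0.0, X[:, k] - knot) / (hi[k] - knot))
                    meta.append(FeatureMeta("hinge", (name,), float(knot)))

    design = np.column_stack(cols) if cols else np.empty((len(cells), 0))
    presence_rows = (
        _row_lookup(cells, presence_cells)
        if len(presence_cells)
        else np.empty(0, dtype=int)
    )
    return FeatureExpansion(design, meta, presence_rows, cells, names)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _log_raw(F: np.ndarray, lam: np.ndarray) -> tuple[np.ndarray, float]:
    eta = F @ lam
    logz = logsumexp(eta)
    return eta - logz, logz


def _mean_loglik(F: np.ndarray, lam: np.ndarray, fbar: np.ndarray) -> float:
    """(1/m) Σ_presence log p_λ = f̄·λ − log Z."""
    return float(fbar @ lam - logsumexp(F @ lam))


def fit_maxent(
    fe: FeatureExpansion,
    beta: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-5,
    presence_rows: np.ndarray | None = None,
    keep_trace: bool = True,
) -> MaxentFit:
    """Fit the L1-penalized maximum-entropy model by proximal gradient ascent.

    Maximizes ``f̄·λ − log Z(λ) − β Σ_j s_j |λ_j|`` with
    ``s_j = SD_background(f_j)/√m``; soft-thresholding produces exact zeros,
    so ``n_params`` counts genuinely active features.  Deterministic:
    identical inputs give bit-identical weights.  When ``max_iter`` is
    reached before the update falls below ``tol`` the fit is returned with
    ``converged=False``.
    """
    F = fe.design
    if not np.isfinite(F).all():
        raise ValueError("design matrix contains non-finite values")
    rows = fe.presence_rows if presence_rows is None else np.asarray(presence_rows, int)
    m = len(rows)
    if m < 1:
        raise ValueError("fit_maxent needs at least one presence")
    if fe.n_cells < 2:
        raise ValueError("fit_maxent needs at least two background cells")
    if beta < 0:
        raise ValueError("beta must be non-negative")

    fbar = F[rows].mean(axis=0)
    sd = F.std(axis=0)
    scale = sd / np.sqrt(m)
    thresh = beta * scale

    d = fe.n_features
    lam = np.zeros(d)
    ll = _mean_loglik(F, lam, fbar)
    step = 1.0
    gains: list[float] = []
    dlams: list[np.ndarray] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp, _ = _log_raw(F, lam)
        p = np.exp(logp)
        grad = fbar - F.T @ p
        # backtracking proximal step on the smooth part
        while True:
            cand = np.sign(lam + step * grad) * np.maximum(
                np.abs(lam + step * grad) - step * thresh, 0.0
            )
            delta = cand - lam
            ll_cand = _mean_loglik(F, cand, fbar)
            if ll_cand >= ll + grad @ delta - (delta @ delta) / (2 * step) - 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                cand, ll_cand, delta = lam, ll, np.zeros(d)
                break
        if keep_trace:
            gains.append(ll_cand - ll)
            dlams.append(np.abs(delta))
        max_delta = float(np.max(np.abs(delta))) if d else 0.0
        lam, ll = cand, ll_cand
        step = min(step * 2.0, 1e6)
        if max_delta < tol:
            converged = True
            break

    logp, _ = _log_raw(F, lam)
    raw = np.exp(logp)
    raw /= raw.sum()
    gain = ll + np.log(fe.n_cells)
    return MaxentFit(
        lambdas=lam,
        beta=beta,
        raw=raw,
        training_gain=float(gain),
        n_params=int(np.count_nonzero(lam)),
        iterations=it,
        converged=converged,
        penalty_scale=scale,
        gain_increments=np.array(gains) if keep_trace else np.empty(0),
        dlambda_trace=np.array(dlams) if keep_trace and dlams else np.empty((0, d)),
    )


def raw_distribution(fit: MaxentFit, fe: FeatureExpansion) -> np.ndarray:
    """Softmax of the linear predictor over background cells (sums to 1)."""
    logp, _ = _log_raw(fe.design, fit.lambdas)
    p = np.exp(logp)
    return p / p.sum()


def training_gain(
    fit: MaxentFit, fe: FeatureExpansion, presence_rows: np.ndarray | None = None
) -> float:
    """Mean presence log-probability relative to the uniform baseline (nats)."""
    rows = fe.presence_rows if presence_rows is None else np.asarray(presence_rows, int)
    fbar = fe.design[rows].mean(axis=0)
    return _mean_loglik(fe.design, fit.lambdas, fbar) + float(np.log(fe.n_cells))


# ---------------------------------------------------------------------------
# Cumulative output
# ---------------------------------------------------------------------------


def cumulative_scores(raw: np.ndarray) -> np.ndarray:
    """Cumulative transform of a raw distribution, scaled 0–100.

    ``cumulative(i) = 100 · Σ_{j: raw(j) ≤ raw(i)} raw(j)``; tied cells share
    a value and the most probable cell(s) score exactly 100.
    """
    raw = np.asarray(raw, dtype=float)
    order = np.argsort(raw, kind="stable")
    sorted_raw = raw[order]
    csum = np.cumsum(sorted_raw)
    # within a tie group every cell gets the group's top cumulative sum
    out_sorted = np.empty_like(csum)
    i = len(sorted_raw) - 1
    while i >= 0:
        j = i
        while j > 0 and sorted_raw[j - 1] == sorted_raw[i]:
            j -= 1
        out_sorted[j : i + 1] = csum[i]
        i = j - 1
    total = csum[-1]
    cum = np.empty_like(raw)
    cum[order] = 100.0 * out_sorted / total
    return cum


def cumulative_output(
    raw: np.ndarray,
    cells: np.ndarray | None = None,
    template: Grid | None = None,
) -> SuitabilityMap | np.ndarray:
    """Cumulative suitability; painted onto a grid when a template is given.

    Without ``cells``/``template`` the per-cell cumulative vector is returned;
    with them, a :class:`SuitabilityMap` whose grid is masked outside the
    background cells.
    """
    cum = cumulative_scores(raw)
    if template is None or cells is None:
        return cum
    values = np.full(template.shape, np.nan)
    mask = np.ones(template.shape, dtype=bool)
    cells = np.asarray(cells, dtype=int)
    values[cells[:, 0], cells[:, 1]] = cum
    mask[cells[:, 0], cells[:, 1]] = False
    return SuitabilityMap(cumulative=template.like(values, mask))
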