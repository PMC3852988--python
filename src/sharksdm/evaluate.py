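"""Model selection and evaluation: AICc over a regularization grid, ROC/AUC
against background pseudo-negatives, replicate fitting routines, and variable
importance.

The regularization multiplier β is chosen per month by small-sample AIC:
each candidate model is fitted on all presences, its raw distribution is
renormalized to sum to 1 over the landscape, the log-likelihood is the sum of
log raw probabilities at the presence cells, k is the number of nonzero
feature weights, and AICc = 2k − 2lnL + 2k(k+1)/(n − k − 1) with n the
presence count.  The β with the lowest AICc wins (ties go to the more
regularized, i.e. smaller-grid, candidate — here the smaller β since the grid
is ascending).

Presence-only data have no true absences, so ROC curves use background cells
as pseudo-negatives.  AUC is the Mann–Whitney concordance probability; the
habitat threshold is the score maximizing sensitivity + specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import EnvStack
from .maxent import (
    FeatureExpansion,
    MaxentFit,
    SuitabilityMap,
    build_features,
    cumulative_scores,
    fit_maxent,
    sample_background,
)

__all__ = [
    "AiccRecord",
    "RocResult",
    "SelectionResult",
    "EnsembleResult",
    "DEFAULT_BETA_GRID",
    "REPLICATE_CAP",
    "standardized_likelihood",
    "aicc",
    "select_regularization",
    "roc_auc",
    "classify_auc",
    "fit_replicates",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gain",
]

DEFAULT_BETA_GRID = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0)
REPLICATE_CAP = 100


@dataclass(frozen=True)
class AiccRecord:
    beta: float
    log_likelihood: float
    k: int
    n: int
    aicc: float | None
    defined: bool


def standardized_likelihood(raw: np.ndarray, presence_rows: np.ndarray) -> float:
    """Sum of log standardized (sum-to-1) cell probabilities at presences.

    Repeated presences in one cell count multiply.  A presence on a
    zero-probability cell yields −inf (flagged by the caller as undefined).
    """
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("raw distribution has non-positive total probability")
    p = raw / total
    rows = np.asarray(presence_rows, dtype=int)
    at = p[rows]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(at)))


def aicc(loglik: float, k: int, n: int, beta: float = float("nan")) -> AiccRecord:
    """Small-sample Akaike criterion; undefined (flagged) when n ≤ k + 1."""
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    if n - k - 1 <= 0:
        return AiccRecord(beta, loglik, k, n, None, False)
    value = 2 * k - 2 * loglik + (2 * k * (k + 1)) / (n - k - 1)
    return AiccRecord(beta, loglik, k, n, float(value), True)


@dataclass
class SelectionResult:
    best_beta: float
    table: pd.DataFrame
    fe: FeatureExpansion
    fits: dict[float, MaxentFit]

    @property
    def best_fit(self) -> MaxentFit:
        return self.fits[self.best_beta]


def select_regularization(
    stack: EnvStack,
    presence_cells: np.ndarray,
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    seed: int = 0,
    max_background: int = 10000,
    classes: tuple[str, ...] | None = None,
    knots_per_variable: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> SelectionResult:
    """Fit one model per candidate β on all presences and pick the AICc argmin.

    Ties go to the smaller β.  If no candidate has a defined AICc (presence
    count too small relative to active features), an error advises a larger
    sample or stronger regularization.
    """
    if len(beta_grid) == 0:
        raise ValueError("beta_grid must be nonempty")
    presence_cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
    bg = sample_background(stack, max_background, seed, presence_cells)
    kwargs = {} if classes is None else {"classes": classes}
    fe = build_features(stack, bg, presence_cells, knots_per_variable=knots_per_variable, **kwargs)
    n = len(fe.presence_rows)

    records: list[AiccRecord] = []
    fits: dict[float, MaxentFit] = {}
    for beta in beta_grid:
        fit = fit_maxent(fe, beta=beta, max_iter=max_iter, tol=tol, keep_trace=False)
        ll = standardized_likelihood(fit.raw, fe.presence_rows)
        records.append(aicc(ll, fit.n_params, n, beta=beta))
        fits[beta] = fit
    table = pd.DataFrame(
        {
            "beta": [r.beta for r in records],
            "log_likelihood": [r.log_likelihood for r in records],
            "k": [r.k for r in records],
            "n": [r.n for r in records],
            "aicc": [r.aicc if r.defined else np.nan for r in records],
            "defined": [r.defined for r in records],
        }
    )
    defined = [r for r in records if r.defined and np.isfinite(r.aicc)]
    if not defined:
        raise ValueError(
            "AICc undefined for every candidate beta; use more presences or a "
            "larger regularization (fewer active parameters)"
        )
    best = min(defined, key=lambda r: (r.aicc, r.beta))
    return SelectionResult(best.beta, table, fe, fits)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    max_ss_threshold: float


def roc_auc(presence_scores, background_scores) -> RocResult:
    """ROC curve of presences vs background pseudo-negatives.

    AUC is the concordance probability P(presence > background) + ½P(tie)
    (Mann–Whitney).  A cell is classified suitable when its score is ≥ the
    threshold; the threshold sweep runs over the distinct observed scores and
    ``max_ss_threshold`` maximizes sensitivity + specificity, ties resolved
    toward the lower threshold (more predicted habitat).
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if len(p) == 0 or len(b) == 0:
        raise ValueError("roc_auc needs nonempty presence and background scores")
    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(b))

    thresholds = np.unique(np.concatenate([p, b]))
    sens = np.array([(p >= t).mean() for t in thresholds])
    spec = np.array([(b < t).mean() for t in thresholds])
    ss = sens + spec
    best = int(np.argmax(ss))  # argmax returns the first (lowest) maximizer
    return RocResult(thresholds, sens, spec, float(auc), float(thresholds[best]))


def classify_auc(auc: float) -> str:
    """Discrimination label for an AUC value, per the conventional bins."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc == 1.0:
        return "perfect discrimination"
    if auc < 0.5:
        return "worse than random"
    if auc <= 0.7:
        return "no discrimination"
    return "better than random"


# ---------------------------------------------------------------------------
# Replicated model fitting
# ---------------------------------------------------------------------------

_MODES = ("crossvalidation", "bootstrap", "subsampling")


@dataclass
class EnsembleResult:
    mode: str
    beta: float
    auc: np.ndarray
    mean_auc: float
    sd_auc: float
    suitability: SuitabilityMap
    cumulative_matrix: np.ndarray  # (replicates, n_cells)
    fe: FeatureExpansion
    full_fit: MaxentFit
    full_roc: RocResult


def fit_replicates(
    stack: EnvStack,
    presence_cells: np.ndarray,
    beta: float,
    mode: str = "crossvalidation",
    replicates: int = REPLICATE_CAP,
    test_fraction: float = 0.25,
    seed: int = 0,
    max_background: int = 10000,
    classes: tuple[str, ...] | None = None,
    knots_per_variable: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> EnsembleResult:
    """Replicated fits by cross-validation, bootstrap, or subsampling.

    * crossvalidation — k = min(replicates, n) folds; each fold held out once
      and its AUC computed on the held-out presences vs background.
    * bootstrap — n-out-of-n resampling with replacement; AUC on the training
      presences.
    * subsampling — seeded random (1−test_fraction)/test_fraction splits;
      AUC on the test presences.

    Replicates above 100 are clipped to 100.  The ensemble mean and SD of the
    cumulative maps are painted onto the model grid; a full-data fit supplies
    the training ROC used for thresholding.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    replicates = int(min(replicates, REPLICATE_CAP))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    presence_cells = np.asarray(presence_cells, dtype=int).reshape(-1, 2)
    bg = sample_background(stack, max_background, seed, presence_cells)
    kwargs = {} if classes is None else {"classes": classes}
    fe = build_features(stack, bg, presence_cells, knots_per_variable=knots_per_variable, **kwargs)
    rows = fe.presence_rows
    n = len(rows)
    rng = np.random.default_rng(seed)

    splits: list[tuple[np.ndarray, np.ndarray]] = []  # (train, eval) row arrays
    if mode == "crossvalidation":
        if n < 2:
            raise ValueError("crossvalidation needs at least 2 presences")
        k = min(replicates, n)
        perm = rng.permutation(n)
        for fold in np.array_split(perm, k):
            train = np.setdiff1d(np.arange(n), fold)
            splits.append((rows[train], rows[fold]))
    elif mode == "bootstrap":
        for _ in range(replicates):
            idx = rng.integers(0, n, size=n)
            splits.append((rows[idx], rows[idx]))
    else:  # subsampling
        n_test = max(1, int(round(test_fraction * n)))
        if n_test >= n:
            raise ValueError("subsampling leaves no training presences")
        for _ in range(replicates):
            perm = rng.permutation(n)
            splits.append((rows[perm[n_test:]], rows[perm[:n_test]]))

    aucs = []
    cum_rows = []
    for train_rows, eval_rows in splits:
        fit = fit_maxent(fe, beta=beta, max_iter=max_iter, tol=tol,
                         presence_rows=train_rows, keep_trace=False)
        cum = cumulative_scores(fit.raw)
        roc = roc_auc(cum[eval_rows], cum)
        aucs.append(roc.auc)
        cum_rows.append(cum)
    aucs = np.array(aucs)
    cum_matrix = np.vstack(cum_rows)
    mean_cum = cum_matrix.mean(axis=0)
    sd_cum = cum_matrix.std(axis=0)

    full_fit = fit_maxent(fe, beta=beta, max_iter=max_iter, tol=tol)
    full_cum = cumulative_scores(full_fit.raw)
    full_roc = roc_auc(full_cum[rows], full_cum)

    template = stack.template
    smap = SuitabilityMap(
        cumulative=_paint(template, fe.cells, full_cum),
        replicate_mean=_paint(template, fe.cells, mean_cum),
        replicate_sd=_paint(template, fe.cells, sd_cum),
    )
    return EnsembleResult(
        mode=mode,
        beta=beta,
        auc=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=0)),
        suitability=smap,
        cumulative_matrix=cum_matrix,
        fe=fe,
        full_fit=full_fit,
        full_roc=full_roc,
    )


def _paint(template, cells: np.ndarray, values: np.ndarray):
    grid_vals = np.full(template.shape, np.nan)
    mask = np.ones(template.shape, dtype=bool)
    grid_vals[cells[:, 0], cells[:, 1]] = values
    mask[cells[:, 0], cells[:, 1]] = False
    return template.like(grid_vals, mask)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------


def _allocation_matrix(fe: FeatureExpansion) -> np.ndarray:
    """(n_features, n_variables) sharing matrix; product features split evenly."""
    A = np.zeros((fe.n_features, len(fe.variables)))
    index = {v: k for k, v in enumerate(fe.variables)}
    for j, meta in enumerate(fe.feature_meta):
        share = 1.0 / len(meta.variables)
        for v in meta.variables:
            A[j, index[v]] += share
    return A


def percent_contribution(fit: MaxentFit, fe: FeatureExpansion) -> pd.Series:
    """Percent contribution per variable, summing to 100.

    Each iteration's training-gain increase is allocated to variables in
    proportion to Σ_j |Δλ_j|·s_j over that variable's features (products split
    evenly between their two variables) — an attribution suited to
    simultaneous-update solvers.
    """
    if fit.gain_increments.size == 0 or fit.dlambda_trace.size == 0:
        raise ValueError("fit has no optimization trace; refit with keep_trace=True")
    A = _allocation_matrix(fe)
    weights = (fit.dlambda_trace * fit.penalty_scale) @ A  # (iters, nvar)
    increments = np.maximum(fit.gain_increments, 0.0)
    totals = weights.sum(axis=1)
    ok = totals > 0
    contrib = (weights[ok] * (increments[ok] / totals[ok])[:, None]).sum(axis=0)
    if contrib.sum() <= 0:
        warnings.warn("zero total contribution; splitting uniformly", stacklevel=2)
        contrib = np.ones(len(fe.variables))
    pct = 100.0 * contrib / contrib.sum()
    return pd.Series(pct, index=list(fe.variables), name="percent_contribution")


def permutation_importance(fit: MaxentFit, fe: FeatureExpansion, seed: int = 0) -> pd.Series:
    """Permutation importance per variable, normalized to sum to 100.

    Each variable's feature columns are permuted across all rows (one seeded
    permutation per variable), the training AUC recomputed from the linear
    predictor, and importance taken as max(0, AUC_orig − AUC_permuted).
    """
    rng = np.random.default_rng(seed)
    F = fe.design
    lam = fit.lambdas
    eta = F @ lam
    rows = fe.presence_rows
    base = roc_auc(eta[rows], eta).auc
    drops = np.zeros(len(fe.variables))
    for k, var in enumerate(fe.variables):
        cols = np.array(
            [j for j, m in enumerate(fe.feature_meta) if var in m.variables], dtype=int
        )
        active = cols[lam[cols] != 0]
        if active.size == 0:
            continue
        perm = rng.permutation(fe.n_cells)
        eta_perm = eta - F[:, active] @ lam[active] + F[perm][:, active] @ lam[active]
        auc_perm = roc_auc(eta_perm[rows], eta_perm).auc
        drops[k] = max(0.0, base - auc_perm)
    total = drops.sum()
    if total == 0:
        warnings.warn("degenerate permutation importance (no AUC drop); returning zeros",
                      stacklevel=2)
        return pd.Series(drops, index=list(fe.variables), name="permutation_importance")
    return pd.Series(100.0 * drops / total, index=list(fe.variables),
                     name="permutation_importance")


def jackknife_gain(
    fe: FeatureExpansion,
    beta: float,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Training gain with each variable alone and with each variable omitted.

    The full-model gain is stored in ``result.attrs['full_gain']``.  With a
    single variable the omitted-model gain is undefined (NaN).
    """
    full = fit_maxent(fe, beta=beta, max_iter=max_iter, tol=tol, keep_trace=False)
    rows = []
    all_vars = set(fe.variables)
    for var in fe.variables:
        alone = fit_maxent(fe.subset({var}), beta=beta, max_iter=max_iter, tol=tol,
                           keep_trace=False)
        others = all_vars - {var}
        if others:
            without = fit_maxent(fe.subset(others), beta=beta, max_iter=max_iter,
                                 tol=tol, keep_trace=False)
            gain_without = without.training_gain
        else:
            gain_without = np.nan
        rows.append({"variable": var, "gain_alone": alone.training_gain,
                     "gain_without": gain_without})
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["full_gain"] = full.training_gain
    return out
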