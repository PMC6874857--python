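"""All-subsets Gaussian linear model selection with AICc, collinearity
screening, repeated k-fold cross-validated R^2, and projection of the
selected model onto grids or microbasin tables.

The "Gaussian GLM" is ordinary least squares with the Gaussian
log-likelihood evaluated at the MLE variance — the identical estimator,
kept dependency-free and fast enough for exhaustive candidate scans.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionConfig",
    "ScalingRecord",
    "FitResult",
    "CVResult",
    "scale_predictors",
    "fit_ols",
    "aicc",
    "enumerate_candidates",
    "select_best",
    "cross_validate",
    "r_squared",
    "predict_surface",
    "predict_table",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Term limit and collinearity screen for all-subsets selection."""

    max_terms: int = 7
    collinearity_threshold: float = 0.7
    criterion: str = "aicc"

    def __post_init__(self) -> None:
        if self.max_terms < 0:
            raise ValueError("max_terms must be >= 0")
        if not (0 < self.collinearity_threshold <= 1):
            raise ValueError("collinearity threshold must be in (0, 1]")
        if self.criterion != "aicc":
            raise ValueError("only the AICc criterion is supported")


@dataclass
class ScalingRecord:
    """Per-column (min, max) used to scale predictors to [0, 1]."""

    bounds: dict[str, tuple[float, float]]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in table.columns:
            if col not in self.bounds:
                raise KeyError(f"no scaling recorded for column {col!r}")
            lo, hi = self.bounds[col]
            v = table[col].to_numpy(dtype=float)
            out[col] = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        return pd.DataFrame(out, index=table.index)

    def apply_value(self, column: str, value: float) -> float:
        lo, hi = self.bounds[column]
        return (value - lo) / (hi - lo) if hi > lo else 0.0


@dataclass
class FitResult:
    """An OLS fit of one predictor subset."""

    subset: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    coefficient_se: dict[str, float]
    intercept_se: float
    sigma2_mle: float
    loglik: float
    aicc: float
    r2_insample: float
    n: int
    k_params: int

    def predict(self, table: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
        cols = [np.asarray(table[name], dtype=float) for name in self.subset]
        out = np.full_like(
            cols[0] if cols else np.zeros(len(next(iter(table.values())) if isinstance(table, Mapping) else table)),
            self.intercept,
            dtype=float,
        )
        for name, col in zip(self.subset, cols):
            out = out + self.coefficients[name] * col
        return out


@dataclass
class CVResult:
    """Held-out R^2 of one predictor subset under repeated k-fold CV."""

    subset: tuple[str, ...]
    scores: np.ndarray  # shape (repeats, k)
    k: int
    repeats: int
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(self.scores.mean())

    @property
    def sd_r2(self) -> float:
        return float(self.scores.std(ddof=1))


# ---------------------------------------------------------------------------


def scale_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRecord]:
    """Column-wise min-max scaling to [0, 1], keeping the scaling record
    so the same transform can be projected onto new data."""
    bounds = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi == lo:
            warnings.warn(f"constant predictor column {col!r}: scaled to 0", stacklevel=2)
        bounds[col] = (lo, hi)
    record = ScalingRecord(bounds)
    return record.apply(table), record


def aicc(loglik: float, n: int, k_params: int) -> float:
    """AICc = -2*loglik + 2k + 2k(k+1)/(n - k - 1).

    ``k_params`` counts the intercept, the slopes, and the variance
    parameter.  Requires ``n - k_params - 1 > 0``.
    """
    if n - k_params - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k_params}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def fit_ols(
    y,
    predictors: pd.DataFrame,
    subset: Sequence[str] | None = None,
    check_rank: bool = True,
) -> FitResult:
    """Least-squares fit of ``y`` on an intercept plus ``subset`` columns.

    ``check_rank=False`` tolerates a rank-deficient design by taking the
    minimum-norm solution (used by CV refits, where a sparse predictor can
    degenerate to a constant within a training fold).
    """
    y = np.asarray(y, dtype=float)
    subset = tuple(predictors.columns) if subset is None else tuple(subset)
    n = y.size
    X = np.column_stack(
        [np.ones(n)] + [predictors[c].to_numpy(dtype=float) for c in subset]
    )
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p and check_rank:
        # name the offending columns for the error message
        bad = []
        for j, c in enumerate(subset, start=1):
            keep = [i for i in range(p) if i != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(c)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad or list(subset)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n  # MLE variance
    # floor the variance at numerical-noise level so exact fits of nested
    # subsets share one log-likelihood and tie-break on parsimony
    floor = (np.finfo(float).eps * n) ** 2 * max(1.0, float(y @ y) / n)
    sigma2 = max(sigma2, floor)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    s2_unbiased = rss / (n - p) if n > p else np.nan
    cov = s2_unbiased * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.abs(np.diag(cov)))
    k_params = p + 1  # + variance
    return FitResult(
        subset=subset,
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(subset, beta[1:])},
        coefficient_se={c: float(s) for c, s in zip(subset, se[1:])},
        intercept_se=float(se[0]),
        sigma2_mle=sigma2,
        loglik=float(loglik),
        aicc=aicc(loglik, n, k_params) if n - k_params - 1 > 0 else np.inf,
        r2_insample=r2,
        n=n,
        k_params=k_params,
    )


def enumerate_candidates(
    names: Sequence[str],
    config: SelectionConfig,
    correlation: pd.DataFrame | np.ndarray,
) -> list[tuple[str, ...]]:
    """All predictor subsets of size 0..max_terms containing no pair whose
    absolute Pearson correlation exceeds the threshold.

    Ordered deterministically by size then lexicographically.
    """
    names = list(names)
    corr = (
        correlation.loc[names, names].to_numpy()
        if isinstance(correlation, pd.DataFrame)
        else np.asarray(correlation, dtype=float)
    )
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix does not match predictor names")
    if not np.allclose(corr, corr.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    banned = {
        (i, j)
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(corr[i, j]) > config.collinearity_threshold
    }
    order = {name: i for i, name in enumerate(names)}
    out: list[tuple[str, ...]] = []
    for size in range(min(config.max_terms, len(names)) + 1):
        for combo in itertools.combinations(sorted(names), size):
            idx = [order[c] for c in combo]
            if any(
                (min(a, b), max(a, b)) in banned
                for a, b in itertools.combinations(idx, 2)
            ):
                continue
            out.append(combo)
    return out


def select_best(
    y,
    predictors: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[FitResult, pd.DataFrame]:
    """Fit every admissible candidate subset and return the lowest-AICc fit
    plus the full candidate table (for suboptimal-model reporting).

    Ties break toward fewer terms, then lexicographic subset order.
    """
    y = np.asarray(y, dtype=float)
    constant = [
        c for c in predictors.columns if predictors[c].nunique(dropna=False) <= 1
    ]
    if constant:
        warnings.warn(
            f"dropping constant predictor column(s) from selection: {constant}",
            stacklevel=2,
        )
    names = [c for c in predictors.columns if c not in constant]
    corr = predictors[names].corr()
    candidates = enumerate_candidates(names, config, corr)
    rows = []
    fits: dict[tuple[str, ...], FitResult] = {}
    for subset in candidates:
        k_params = len(subset) + 2
        if y.size - k_params - 1 <= 0:
            rows.append(
                {"subset": "+".join(subset) or "(intercept)", "n_terms": len(subset),
                 "aicc": np.nan, "loglik": np.nan, "r2_insample": np.nan,
                 "admissible": False}
            )
            continue
        fit = fit_ols(y, predictors, subset)
        fits[subset] = fit
        rows.append(
            {"subset": "+".join(subset) or "(intercept)", "n_terms": len(subset),
             "aicc": fit.aicc, "loglik": fit.loglik, "r2_insample": fit.r2_insample,
             "admissible": True}
        )
    if not fits:
        raise ValueError("no admissible candidate models")
    best_subset = min(fits, key=lambda s: (fits[s].aicc, len(s), s))
    table = pd.DataFrame(rows).sort_values(
        ["aicc", "n_terms", "subset"], na_position="last"
    )
    table["delta_aicc"] = table["aicc"] - fits[best_subset].aicc
    return fits[best_subset], table.reset_index(drop=True)


def r_squared(observed, predicted, method: str = "pearson") -> float:
    """Coefficient of determination between observed and predicted values.

    ``"pearson"`` (default): squared Pearson correlation, 0 when either
    vector is constant.  ``"ss"``: 1 - SSE/SST.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted differ in length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    if method == "pearson":
        if np.all(obs == obs[0]) or np.all(pred == pred[0]):
            return 0.0
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)
    if method == "ss":
        tss = float(np.sum((obs - obs.mean()) ** 2))
        if tss == 0:
            return 0.0
        return float(1.0 - np.sum((obs - pred) ** 2) / tss)
    raise ValueError(f"unknown R^2 method {method!r}")


def cross_validate(
    y,
    predictors: pd.DataFrame,
    subset: Sequence[str],
    k: int = 7,
    repeats: int = 20,
    seed: int = 0,
    method: str = "pearson",
) -> CVResult:
    """Repeated k-fold cross-validation of a fixed predictor subset.

    Each repeat randomly partitions the data into ``k`` near-equal folds
    (sizes differ by at most 1); each fold in turn is held out, the model
    is refit on the remaining folds, and held-out R^2 is recorded.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"n={n} too small for {k}-fold CV")
    subset = tuple(subset)
    rng = np.random.default_rng(seed)
    scores = np.empty((repeats, k))
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fi, fold in enumerate(folds):
            if fold.size < 2:
                raise ValueError("fold with fewer than 2 observations")
            train = np.setdiff1d(perm, fold)
            fit = fit_ols(y[train], predictors.iloc[train], subset, check_rank=False)
            pred = fit.predict(predictors.iloc[fold])
            scores[rep, fi] = r_squared(y[fold], pred, method=method)
    return CVResult(subset=subset, scores=scores, k=k, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# projection


def predict_surface(
    fit: FitResult,
    rasters: Mapping[str, np.ndarray],
    scaling: ScalingRecord | None = None,
) -> tuple[np.ndarray, int]:
    """Project a fitted model onto full-grid rasters.

    Each predictor raster is scaled with the stored scaling record (when
    given), combined linearly, and the prediction clamped to [0, 1];
    returns ``(grid, n_clamped)``.
    """
    missing = [name for name in fit.subset if name not in rasters]
    if missing:
        raise KeyError(f"missing predictor rasters: {missing}")
    shape = None
    out = None
    for name in fit.subset:
        v = np.asarray(rasters[name], dtype=float)
        if scaling is not None:
            lo, hi = scaling.bounds[name]
            v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        if out is None:
            shape = v.shape
            out = np.full(shape, fit.intercept)
        elif v.shape != shape:
            raise ValueError("predictor rasters differ in shape")
        out = out + fit.coefficients[name] * v
    if out is None:  # intercept-only model: need any raster for the shape
        ref = next(iter(rasters.values()))
        out = np.full(np.asarray(ref).shape, fit.intercept)
    clamped = (out < 0) | (out > 1)
    return np.clip(out, 0.0, 1.0), int(clamped.sum())


def predict_table(
    fit: FitResult,
    table: pd.DataFrame,
    scaling: ScalingRecord | None = None,
) -> tuple[np.ndarray, int]:
    """Project a fitted model onto a predictor table (e.g. microbasins)."""
    cols = {}
    for name in fit.subset:
        if name not in table.columns:
            raise KeyError(f"missing predictor column {name!r}")
        v = table[name].to_numpy(dtype=float)
        if scaling is not None:
            lo, hi = scaling.bounds[name]
            v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        cols[name] = v
    n = len(table)
    out = np.full(n, fit.intercept)
    for name in fit.subset:
        out = out + fit.coefficients[name] * cols[name]
    clamped = (out < 0) | (out > 1)
    return np.clip(out, 0.0, 1.0), int(clamped.sum())
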