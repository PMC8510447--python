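"""Comparator imputers: mean, half-minimum, sample-wise kNN, random forest.

All baselines share the NMF imputer's contract: observed entries pass
through bit-exactly and the returned matrix is complete.  The random-forest
imputer is a thin adapter over scikit-learn's iterative imputer with a
random-forest regressor (the missForest algorithm: each metabolite is
regressed on the others and the fill is refined over a few rounds).
"""

from __future__ import annotations

import numpy as np

from .matrixio import AbundanceMatrix
from .nmf_core import ImputationResult

__all__ = ["impute_mean", "impute_half_min", "impute_knn", "impute_rf"]


def _result(x: AbundanceMatrix, values: np.ndarray, method: str) -> ImputationResult:
    values = values.copy()
    values[x.observed] = x.values[x.observed]
    completed = AbundanceMatrix(
        values, np.ones_like(x.observed), list(x.metabolite_ids),
        list(x.sample_ids), x.scale,
    )
    return ImputationResult(completed, ~x.observed, method)


def _require_rows_observed(x: AbundanceMatrix) -> None:
    if not x.observed.any(axis=1).all():
        bad = [x.metabolite_ids[i] for i in np.where(~x.observed.any(axis=1))[0]]
        raise ValueError(f"metabolite(s) with no observed values: {bad}")


def impute_mean(x: AbundanceMatrix) -> ImputationResult:
    """Fill each NA with its metabolite's observed mean."""
    _require_rows_observed(x)
    fill = np.nanmean(x.values, axis=1, keepdims=True)
    return _result(x, np.where(x.observed, x.values, fill), "mean")


def impute_half_min(x: AbundanceMatrix) -> ImputationResult:
    """Fill each NA with half the metabolite's observed minimum (the
    classic left-censoring heuristic)."""
    _require_rows_observed(x)
    fill = np.nanmin(x.values, axis=1, keepdims=True) / 2.0
    return _result(x, np.where(x.observed, x.values, fill), "halfmin")


def impute_knn(x: AbundanceMatrix, k: int = 10) -> ImputationResult:
    """Sample-wise k-nearest-neighbour imputation.

    Distances between samples are pairwise-complete Euclidean (root mean
    squared difference over metabolites observed in both samples, so that
    varying overlap does not bias the ordering; ties broken by sample
    index).  An NA at (i, j) is filled with the unweighted mean of
    metabolite i over the k nearest samples in which it is observed, falling
    back to the metabolite's observed mean when no donor exists.
    """
    _require_rows_observed(x)
    J = x.n_samples
    if k >= J:
        raise ValueError(f"k={k} must be smaller than the number of samples {J}")
    V, obs = x.values, x.observed

    dist = np.full((J, J), np.inf)
    for a in range(J):
        for b in range(a + 1, J):
            shared = obs[:, a] & obs[:, b]
            if shared.any():
                diff = V[shared, a] - V[shared, b]
                dist[a, b] = dist[b, a] = float(np.sqrt(np.mean(diff**2)))

    row_mean = np.nanmean(V, axis=1)
    out = V.copy()
    for i, j in np.argwhere(~obs):
        donors = np.where(obs[i])[0]
        donors = donors[donors != j]
        d = dist[j, donors] if len(donors) else np.empty(0)
        donors = donors[np.isfinite(d)]
        if len(donors) == 0:
            out[i, j] = row_mean[i]
            continue
        d = dist[j, donors]
        order = np.lexsort((donors, d))  # distance, then sample index
        chosen = donors[order[:k]]
        out[i, j] = V[i, chosen].mean()
    return _result(x, out, "knn")


def impute_rf(
    x: AbundanceMatrix,
    max_iter: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> ImputationResult:
    """Iterative random-forest imputation (missForest-style adapter).

    Each metabolite with NAs is regressed on the other metabolites across
    samples by a random forest, and the fills are refined for up to
    ``max_iter`` rounds or until the change stabilizes.
    """
    _require_rows_observed(x)
    try:
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError(
            "random-forest imputation needs scikit-learn; install the "
            "package with its default dependencies"
        ) from exc

    est = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    imputer = IterativeImputer(
        estimator=est,
        max_iter=max_iter,
        random_state=seed,
        initial_strategy="mean",
        skip_complete=True,
        keep_empty_features=True,
        sample_posterior=False,
    )
    # samples are observations, metabolites are the variables being imputed
    filled = imputer.fit_transform(x.values.T).T
    if x.scale == "raw":
        # forests average observed values, but guard the positivity contract
        filled = np.maximum(filled, np.nanmin(x.values) * 1e-6)
    return _result(x, filled, "rf")
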