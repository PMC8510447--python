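"""Masked non-negative matrix factorization and ensemble imputation.

The imputation model
--------------------
An abundance matrix ``X`` (I metabolites × J samples) with observed index
set Ω is approximated by a product of non-negative factors, ``X ≈ B C`` with
``B ≥ 0`` (I × K basis) and ``C ≥ 0`` (K × J weights), by minimizing the
observed squared loss

    L(B, C) = Σ_{(i,j) ∈ Ω} (x_ij − Σ_k b_ik c_kj)²,   B, C ≥ 0.

Missing cells contribute nothing to the loss; they are read off the
reconstruction afterwards.  Because the best single component count K is
unknown — too few components miss local structure, too many overfit — the
imputer fits an ensemble of N models at consecutive K values centred on the
numerical rank of the (mean-filled) data and averages their reconstructions
with softmax weights ``w_K = exp(−d_K) / Σ exp(−d_K)``, where ``d_K`` is the
model's mean absolute reconstruction error on Ω.  Better-fitting models
therefore dominate the average, but no single K is trusted outright.

The full pipeline (:func:`nmf_impute`) is:

1. mean-fill NAs per metabolite (for rank estimation only), log10-transform
   with a recorded non-negative offset;
2. fit a masked NMF for every K in the schedule;
3. form the softmax-weighted ensemble reconstruction;
4. keep observed entries exactly, fill NAs from the ensemble, and invert the
   log transform.

Observed entries pass through bit-exactly; only NAs are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .matrixio import AbundanceMatrix, inverse_log10, log10_transform

__all__ = [
    "FactorPair",
    "EnsembleModel",
    "EnsembleReconstruction",
    "ImputationResult",
    "observed_loss",
    "masked_nmf",
    "estimate_rank",
    "k_schedule",
    "reconstruction_error",
    "weighted_reconstruction",
    "nmf_impute",
    "DEFAULT_N_MODELS",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

DEFAULT_N_MODELS = 20  # empirical ensemble size
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
_EPS = 1e-12  # multiplicative-update denominator guard


@dataclass
class FactorPair:
    """Result of one masked NMF fit: ``X ≈ B C`` at component count K."""

    B: np.ndarray
    C: np.ndarray
    K: int
    converged: bool
    n_iter: int
    final_loss: float
    loss_history: np.ndarray

    def reconstruction(self) -> np.ndarray:
        return self.B @ self.C


class EnsembleModel(NamedTuple):
    K: int
    x_hat: np.ndarray  # log-scale reconstruction B C
    d: float  # mean absolute error on Ω


@dataclass
class EnsembleReconstruction:
    """Softmax-weighted average over per-K reconstructions."""

    models: list[EnsembleModel]
    weights: np.ndarray
    x_hat: np.ndarray
    n_iters: list[int] | None = None  # per-model iteration counts, if known

    @property
    def ks(self) -> list[int]:
        return [m.K for m in self.models]

    @property
    def ds(self) -> np.ndarray:
        return np.array([m.d for m in self.models])


@dataclass
class ImputationResult:
    """A completed matrix: observed entries untouched, NAs estimated.

    ``x_tilde`` is the completed raw-scale matrix; ``imputed_mask`` marks the
    cells that were missing in the input.  ``ensemble`` and ``offset`` are
    populated by the NMF imputer only.
    """

    x_tilde: AbundanceMatrix
    imputed_mask: np.ndarray
    method: str = "nmf"
    ensemble: EnsembleReconstruction | None = None
    offset: float = 0.0
    seed: int | None = None

    @property
    def values(self) -> np.ndarray:
        return self.x_tilde.values

    def model_imputation(self, k: int, x_raw: AbundanceMatrix) -> np.ndarray:
        """Raw-scale completion using the single ensemble member at K = k."""
        if self.ensemble is None:
            raise ValueError("no ensemble attached to this result")
        for m in self.ensemble.models:
            if m.K == k:
                out = 10.0 ** (m.x_hat - self.offset)
                out[x_raw.observed] = x_raw.values[x_raw.observed]
                return out
        raise KeyError(f"no model with K={k} in the ensemble")


# ----------------------------------------------------------------------


def observed_loss(x: AbundanceMatrix, f) -> float:
    """Squared reconstruction error restricted to the observed set Ω."""
    if isinstance(f, FactorPair):
        recon = f.reconstruction()
    else:
        B, C = f
        recon = np.asarray(B) @ np.asarray(C)
    if x.n_observed == 0:
        raise ValueError("empty observed set")
    resid = (x.values - recon)[x.observed]
    return float(np.sum(resid**2))


def masked_nmf(
    x: AbundanceMatrix,
    k: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FactorPair:
    """Fit ``X ≈ B C`` under B, C ≥ 0 on the observed cells only.

    Uses multiplicative updates with a binary observation mask W
    (the Lee–Seung rules adapted to the Ω-restricted loss):

        B ← B ∘ [(W∘X) Cᵀ] / [(W∘(BC)) Cᵀ],
        C ← C ∘ [Bᵀ (W∘X)] / [Bᵀ (W∘(BC))],

    which keep the observed loss non-increasing.  Entries of B and C are
    initialized i.i.d. uniform on (0, 1] scaled by sqrt(mean observed / k).
    Stops when the relative loss change drops below ``tol`` or after
    ``max_iter`` iterations.  Deterministic given ``seed``.
    """
    I, J = x.shape
    if not 1 <= k <= min(I, J):
        raise ValueError(f"k={k} out of range [1, {min(I, J)}]")
    obs_vals = x.values[x.observed]
    if np.any(obs_vals < 0):
        raise ValueError("masked_nmf requires non-negative observed values")
    if not x.observed.any(axis=1).all():
        bad = [x.metabolite_ids[i] for i in np.where(~x.observed.any(axis=1))[0]]
        raise ValueError(f"metabolite(s) with no observed entries: {bad}")

    W = x.observed.astype(float)
    X0 = np.where(x.observed, x.values, 0.0)
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(float(obs_vals.mean()), _EPS) / k)
    B = (1.0 - rng.random((I, k))) * scale  # uniform on (0, 1]
    C = (1.0 - rng.random((k, J))) * scale

    WX = W * X0
    losses = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WBC = W * (B @ C)
        B *= (WX @ C.T) / (WBC @ C.T + _EPS)
        WBC = W * (B @ C)
        C *= (B.T @ WX) / (B.T @ WBC + _EPS)
        resid = (X0 - B @ C)[x.observed]
        loss = float(np.sum(resid**2))
        losses.append(loss)
        if np.isfinite(prev) and prev > 0 and (prev - loss) / prev < tol:
            converged = True
            break
        if loss == 0.0:
            converged = True
            break
        prev = loss
    return FactorPair(B, C, k, converged, it, losses[-1], np.asarray(losses))


def estimate_rank(x: AbundanceMatrix) -> int:
    """Numerical rank of the (mean-filled) log-scale data matrix.

    Counts singular values above ``max(I, J) · eps · s_max`` (the standard
    numpy tolerance).  Missing cells, if any remain, are filled with the
    metabolite's observed mean first.
    """
    vals = x.values
    if not x.observed.all():
        vals = vals.copy()
        for i in range(x.n_metabolites):
            row_obs = x.observed[i]
            if not row_obs.any():
                raise ValueError("metabolite with no observed entries")
            vals[i, ~row_obs] = vals[i, row_obs].mean()
    r = int(np.linalg.matrix_rank(vals))
    return max(1, min(r, min(x.shape)))


def k_schedule(
    rank: int, n_models: int = DEFAULT_N_MODELS, i: int = None, j: int = None
) -> list[int]:
    """Consecutive component counts centred on the data rank.

    Returns exactly ``min(n_models, min(i, j))`` distinct consecutive K
    values starting at ``max(rank − n_models // 2, 1)``, shifted down when
    the top would exceed ``min(i, j)`` and truncated only when the matrix is
    smaller than the ensemble.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if i is None or j is None:
        raise ValueError("matrix dimensions i, j are required")
    lim = min(i, j)
    if lim <= n_models:
        return list(range(1, lim + 1))
    k1 = max(rank - n_models // 2, 1)
    if k1 + n_models - 1 > lim:
        k1 = lim - n_models + 1
    return list(range(k1, k1 + n_models))


def reconstruction_error(x: AbundanceMatrix, x_hat: np.ndarray) -> float:
    """d_K: mean absolute deviation |x̂_ij − x_ij| over the observed set Ω."""
    if x.n_observed == 0:
        raise ValueError("empty observed set")
    x_hat = np.asarray(x_hat, dtype=float)
    return float(np.abs(x_hat - x.values)[x.observed].mean())


def weighted_reconstruction(
    models: Sequence[EnsembleModel | tuple],
) -> EnsembleReconstruction:
    """Softmax-weighted average: w_K = exp(−d_K) / Σ exp(−d_K).

    Computed with max-subtraction so large d_K cannot underflow every weight
    simultaneously; weights are strictly positive and sum to 1.
    """
    if len(models) == 0:
        raise ValueError("need at least one model")
    models = [EnsembleModel(*m) for m in models]
    d = np.array([m.d for m in models], dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite reconstruction errors")
    w = np.exp(-(d - d.min()))
    w /= w.sum()
    x_hat = np.tensordot(w, np.stack([m.x_hat for m in models]), axes=1)
    return EnsembleReconstruction(models, w, x_hat)


def nmf_impute(
    x_raw: AbundanceMatrix,
    n_models: int = DEFAULT_N_MODELS,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ImputationResult:
    """Ensemble NMF imputation of a raw-scale abundance matrix.

    Runs the four-step pipeline described in the module docstring.  Observed
    entries are preserved bit-exactly; per-model seeds are derived as
    ``seed + K`` so the whole run is a pure function of ``seed``.
    """
    if x_raw.scale != "raw":
        raise ValueError("nmf_impute expects a raw-scale matrix")
    if not x_raw.observed.any(axis=1).all():
        raise ValueError("every metabolite needs at least one observed value")

    x_log, offset = log10_transform(x_raw)

    # Step 1: per-metabolite raw-mean fill, for rank estimation only
    filled = x_raw.values.copy()
    for i in range(x_raw.n_metabolites):
        row_obs = x_raw.observed[i]
        filled[i, ~row_obs] = filled[i, row_obs].mean()
    filled_log = np.log10(filled) + offset
    rank = max(1, min(int(np.linalg.matrix_rank(filled_log)), min(x_raw.shape)))

    ks = k_schedule(rank, n_models, x_raw.n_metabolites, x_raw.n_samples)

    # Step 2: one masked factorization per K
    models = []
    n_iters = []
    for k in ks:
        f = masked_nmf(x_log, k, seed=seed + k, tol=tol, max_iter=max_iter)
        x_hat_k = f.reconstruction()
        if not np.all(np.isfinite(x_hat_k)):
            raise ArithmeticError(
                f"non-finite reconstruction at K={k} "
                f"(n_iter={f.n_iter}, loss={f.final_loss})"
            )
        models.append(EnsembleModel(k, x_hat_k, reconstruction_error(x_log, x_hat_k)))
        n_iters.append(f.n_iter)

    # Step 3: softmax-weighted ensemble
    ens = weighted_reconstruction(models)
    ens.n_iters = n_iters

    # Step 4: keep observed cells, fill NAs from the ensemble, back-transform
    x_tilde_log = np.where(x_raw.observed, x_log.values, ens.x_hat)
    x_tilde_raw = 10.0 ** (x_tilde_log - offset)
    x_tilde_raw[x_raw.observed] = x_raw.values[x_raw.observed]
    if not np.all(np.isfinite(x_tilde_raw)) or not np.all(x_tilde_raw > 0):
        raise ArithmeticError("invalid completed matrix (non-finite or non-positive)")

    completed = AbundanceMatrix(
        x_tilde_raw,
        np.ones_like(x_raw.observed),
        list(x_raw.metabolite_ids),
        list(x_raw.sample_ids),
        "raw",
    )
    return ImputationResult(
        completed, ~x_raw.observed, "nmf", ens, offset, seed
    )
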