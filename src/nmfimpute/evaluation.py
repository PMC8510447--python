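"""Imputation accuracy metrics: NRMSE, correlation-network recovery, MSR.

Three complementary surfaces:

* **NRMSE** — root mean square of *relative* errors over the simulated
  missing set Θs,

      NRMSE = sqrt( |Θs|⁻¹ Σ_{(i,j)∈Θs} ((x_ij − x̃_ij) / x_ij)² ),

  measuring pointwise imputation accuracy (scale-free because of the
  division by the true value).

* **Correlation-coefficient network (CCN) recovery** — build the network of
  significantly correlated metabolite pairs (|r| ≥ r_min and BH-adjusted
  p < α, Pearson on log10 abundances) on the complete reference data and on
  the imputed data, then score the predicted edge set against the reference
  with precision / recall / F1.  Measures preservation of the data's
  association structure rather than individual values.

* **MSR (mean score of ranking)** — for each simulated NA, rank the
  competing methods by absolute error (rank 1 = closest, ties averaged);
  a method's MSR is its mean rank over Θs.  A non-parametric head-to-head
  comparison insensitive to the error magnitudes themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrixio import AbundanceMatrix
from .nmf_core import ImputationResult

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSet",
    "NetworkScores",
    "nrmse",
    "build_ccn",
    "network_scores",
    "sparsity",
    "msr",
]


@dataclass
class EdgeSet:
    """Undirected metabolite network with per-edge correlation statistics."""

    nodes: list[str]
    edges: set[tuple[str, str]]
    stats: pd.DataFrame  # columns: a, b, r, p, q

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon

    def sparsity(self) -> float:
        n = len(self.nodes)
        if n < 2:
            raise ValueError("sparsity needs at least 2 nodes")
        return len(self.edges) / (n * (n - 1) / 2)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_edgelist(self, path) -> None:
        self.stats.to_csv(path, sep="\t", index=False)


@dataclass
class NetworkScores:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # an empty-denominator case was zero-filled

    def __iter__(self):
        return iter((self.precision, self.recall, self.f1))


def _imputed_values(imputed) -> np.ndarray:
    if isinstance(imputed, ImputationResult):
        return imputed.x_tilde.values
    if isinstance(imputed, AbundanceMatrix):
        return imputed.values
    return np.asarray(imputed, dtype=float)


def _theta_tuple(theta_s) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta_s, dtype=int)
    if theta.ndim != 2 or theta.shape[1] != 2:
        raise ValueError("theta_s must be an (n, 2) index array")
    return theta[:, 0], theta[:, 1]


# ----------------------------------------------------------------------


def nrmse(truth: AbundanceMatrix, imputed, theta_s, scale: str = "raw") -> float:
    """Normalized RMSE over the simulated missing set Θs (relative errors)."""
    rows, cols = _theta_tuple(theta_s)
    if len(rows) == 0:
        raise ValueError("theta_s is empty")
    xt = truth.values[rows, cols]
    xi = _imputed_values(imputed)[rows, cols]
    if not np.all(np.isfinite(xt)):
        raise ValueError("truth is not complete on theta_s")
    if scale == "log10":
        if np.any(xt <= 0) or np.any(xi <= 0):
            raise ValueError("log10 NRMSE needs strictly positive values")
        xt, xi = np.log10(xt), np.log10(xi)
    if np.any(xt == 0):
        raise ValueError("true value of 0 in the NRMSE denominator")
    return float(np.sqrt(np.mean(((xt - xi) / xt) ** 2)))


def build_ccn(
    m: AbundanceMatrix,
    r_min: float = 0.6,
    alpha: float = 0.05,
    method: str = "pearson",
) -> EdgeSet:
    """Correlation-coefficient network over metabolites.

    Metabolites containing any NA are dropped first (the reference network
    must be computed on complete rows).  Correlations are taken on log10
    abundances across samples; an edge is kept iff |r| ≥ ``r_min`` and its
    Benjamini–Hochberg-adjusted p-value is below ``alpha``.  Constant
    metabolites have undefined correlations; their pairs are skipped.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation networks")
    complete = m.observed.all(axis=1)
    if not complete.all():
        logger.info(
            "build_ccn: dropping %d metabolite(s) with NAs", int((~complete).sum())
        )
    ids = [mid for mid, c in zip(m.metabolite_ids, complete) if c]
    if m.scale == "raw":
        data = np.log10(m.values[complete])
    else:
        data = m.values[complete]

    const = data.std(axis=1) == 0
    if const.any():
        import warnings

        warnings.warn(
            f"skipping correlations for {int(const.sum())} constant metabolite(s)"
        )
    usable = np.where(~const)[0]
    n = data.shape[1]

    if method == "pearson":
        corr = np.corrcoef(data[usable]) if len(usable) >= 2 else np.empty((0, 0))
    elif method == "spearman":
        if len(usable) >= 2:
            corr = stats.spearmanr(data[usable], axis=1).statistic
            corr = np.atleast_2d(corr)
        else:
            corr = np.empty((0, 0))
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    rows_a, rows_b, rvals = [], [], []
    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            rows_a.append(usable[ai])
            rows_b.append(usable[bi])
            rvals.append(corr[ai, bi])
    rvals = np.clip(np.asarray(rvals, dtype=float), -1.0, 1.0)

    if len(rvals):
        # p-value of r under the null via the exact t transform, df = n - 2
        with np.errstate(divide="ignore"):
            tstat = rvals * np.sqrt((n - 2) / np.maximum(1.0 - rvals**2, 1e-300))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        keep = (np.abs(rvals) >= r_min) & (qvals < alpha)
    else:
        pvals = qvals = np.empty(0)
        keep = np.zeros(0, dtype=bool)

    edges = set()
    records = []
    for idx in np.where(keep)[0]:
        a, b = ids[rows_a[idx]], ids[rows_b[idx]]
        pair = (a, b) if a <= b else (b, a)
        edges.add(pair)
        records.append(
            {"a": pair[0], "b": pair[1], "r": rvals[idx], "p": pvals[idx],
             "q": qvals[idx]}
        )
    stats_df = pd.DataFrame(records, columns=["a", "b", "r", "p", "q"])
    return EdgeSet(ids, edges, stats_df)


def network_scores(predicted: EdgeSet, original: EdgeSet) -> NetworkScores:
    """Precision, recall and F1 of a predicted edge set against a reference."""
    pred_nodes, orig_nodes = set(predicted.nodes), set(original.nodes)
    if pred_nodes != orig_nodes:
        shared = pred_nodes & orig_nodes
        logger.info(
            "network_scores: node universes differ; scoring on the %d shared nodes",
            len(shared),
        )
        pred = {e for e in predicted.edges if e[0] in shared and e[1] in shared}
        orig = {e for e in original.edges if e[0] in shared and e[1] in shared}
    else:
        pred, orig = predicted.edges, original.edges
    tp = len(pred & orig)
    fp = len(pred - orig)
    fn = len(orig - pred)
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return NetworkScores(precision, recall, f1, degenerate)


def sparsity(e: EdgeSet) -> float:
    """Fraction of possible metabolite pairs that are edges."""
    return e.sparsity()


def msr(
    truth: AbundanceMatrix,
    imputations: Mapping[str, ImputationResult] | Mapping[str, np.ndarray],
    theta_s,
) -> dict[str, float]:
    """Mean score of ranking per method over Θs.

    For each simulated NA the P methods are ranked ascending by absolute
    error (rank 1 = best; ties receive the average of the tied ranks); the
    MSR of a method is its mean rank.  With no ties, Σ_p MSR_p = P(P+1)/2.
    """
    if len(imputations) < 2:
        raise ValueError("MSR needs at least two methods")
    rows, cols = _theta_tuple(theta_s)
    if len(rows) == 0:
        raise ValueError("theta_s is empty")
    names = list(imputations.keys())
    xt = truth.values[rows, cols]
    errs = np.stack(
        [np.abs(_imputed_values(imputations[name])[rows, cols] - xt) for name in names]
    )
    ranks = stats.rankdata(errs, method="average", axis=0)
    return {name: float(r) for name, r in zip(names, ranks.mean(axis=1))}
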