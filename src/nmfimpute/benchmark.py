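"""Benchmark orchestration: repeated simulation → imputation → metrics.

A single :class:`BenchmarkConfig` describes the full experimental grid —
missingness patterns × target percentages × outlier levels × repeats — and
:func:`run_benchmark` executes it for every registered imputer, producing a
tidy per-repeat table plus aggregated summaries.  The whole run is a pure
function of (input data, config, master seed): every sub-seed is derived
deterministically from the master seed via a counter, so any cell of the
grid can be recomputed independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from . import baselines, evaluation, missingness_sim, nmf_core
from .matrixio import (
    AbundanceMatrix,
    filter_by_missing_fraction,
    generate_fixture,
    load_matrix,
    missingness_profile,
)

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "parse_config", "run_benchmark", "paired_significance"]

_DEFAULT_X = {
    "MCAR": [5.0, 10.0, 15.0, 20.0, 25.0, 30.0],
    "MNAR": [15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0],
    "MM": [15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0],
}
_PATTERNS = ("MCAR", "MNAR", "MM")
_KNOWN_METHODS = ("nmf", "rf", "knn", "mean", "halfmin")


@dataclass
class BenchmarkConfig:
    """Validated benchmark description; see :func:`parse_config`."""

    fixture: dict | None = None  # {i, j, rank, noise_sd, seed}
    input: str | None = None  # path to a CSV/TSV abundance table
    patterns: list[str] = field(default_factory=lambda: list(_PATTERNS))
    x_pct: dict = field(default_factory=lambda: {k: list(v) for k, v in _DEFAULT_X.items()})
    outlier_levels: list[float] = field(default_factory=lambda: [0.0, 0.01, 0.03, 0.05])
    methods: list[str] = field(default_factory=lambda: ["nmf", "rf", "knn", "mean", "halfmin"])
    n_repeats: int = 50
    seed: int = 0
    lod_q: float = missingness_sim.DEFAULT_LOD_QUANTILE
    filter_threshold: float = 0.30
    knn_k: int = 10
    rf_max_iter: int = 10
    rf_n_estimators: int = 100
    nmf_n_models: int = nmf_core.DEFAULT_N_MODELS
    nmf_tol: float = nmf_core.DEFAULT_TOL
    nmf_max_iter: int = nmf_core.DEFAULT_MAX_ITER
    ccn_r_min: float = 0.6
    ccn_alpha: float = 0.05
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.fixture is None) == (self.input is None):
            raise ValueError("exactly one of 'fixture' or 'input' must be set")
        for p in self.patterns:
            if p not in _PATTERNS:
                raise ValueError(f"patterns: unknown pattern {p!r}")
        if not self.patterns:
            raise ValueError("patterns: empty")
        if isinstance(self.x_pct, (list, tuple)):
            self.x_pct = {p: list(self.x_pct) for p in self.patterns}
        for p in self.patterns:
            if p not in self.x_pct or not self.x_pct[p]:
                raise ValueError(f"x_pct: no grid for pattern {p!r}")
        for m in self.methods:
            if m not in _KNOWN_METHODS:
                raise ValueError(
                    f"methods: unknown imputer {m!r} (registered: {_KNOWN_METHODS})"
                )
        if not self.methods:
            raise ValueError("methods: empty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


_CONFIG_KEYS = {f.name for f in BenchmarkConfig.__dataclass_fields__.values()}


def parse_config(path) -> BenchmarkConfig:
    """Load a YAML/JSON benchmark config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return BenchmarkConfig(**raw)


def _sub_seed(master: int, counter: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


def _load_truth(cfg: BenchmarkConfig) -> AbundanceMatrix:
    if cfg.fixture is not None:
        fx = dict(cfg.fixture)
        return generate_fixture(
            int(fx["i"]), int(fx["j"]), int(fx.get("rank", 5)),
            float(fx.get("noise_sd", 0.01)), int(fx.get("seed", cfg.seed)),
        )
    m = load_matrix(cfg.input)
    return filter_by_missing_fraction(m, cfg.filter_threshold)


def _impute(method: str, masked: AbundanceMatrix, cfg: BenchmarkConfig, seed: int):
    if method == "nmf":
        return nmf_core.nmf_impute(
            masked, cfg.nmf_n_models, seed=seed, tol=cfg.nmf_tol,
            max_iter=cfg.nmf_max_iter,
        )
    if method == "rf":
        return baselines.impute_rf(
            masked, cfg.rf_max_iter, seed=seed, n_estimators=cfg.rf_n_estimators
        )
    if method == "knn":
        return baselines.impute_knn(masked, cfg.knn_k)
    if method == "mean":
        return baselines.impute_mean(masked)
    if method == "halfmin":
        return baselines.impute_half_min(masked)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Execute the full grid; returns the tidy per-repeat metric table.

    Columns: pattern, x_pct, outlier_frac, repeat, method, nrmse, precision,
    recall, f1, msr, seed, error.  Method failures are recorded per cell and
    skipped, never fatal.  When ``cfg.out_dir`` is set, writes
    ``results.csv`` (tidy table) and ``summary.json`` (mean ± SD aggregates
    plus the resolved configuration).
    """
    truth = _load_truth(cfg)
    profile = missingness_profile(truth)
    lod = missingness_sim.determine_lod(truth, cfg.lod_q)
    original_ccn = evaluation.build_ccn(truth, cfg.ccn_r_min, cfg.ccn_alpha)

    rows = []
    counter = 0
    for pattern in cfg.patterns:
        for x in cfg.x_pct[pattern]:
            for level in cfg.outlier_levels:
                for rep in range(cfg.n_repeats):
                    s_sim = _sub_seed(cfg.seed, counter)
                    s_out = _sub_seed(cfg.seed, counter + 1)
                    s_imp = _sub_seed(cfg.seed, counter + 2)
                    counter += 3
                    if pattern == "MCAR":
                        sim = missingness_sim.simulate_mcar(truth, x, seed=s_sim)
                    elif pattern == "MNAR":
                        sim = missingness_sim.simulate_mnar(
                            truth, x, lod=lod, profile=profile, seed=s_sim
                        )
                    else:
                        sim = missingness_sim.simulate_mm(
                            truth, x, lod=lod, profile=profile, seed=s_sim
                        )
                    masked = sim.masked
                    if level > 0:
                        masked, _ = missingness_sim.inject_outliers(
                            masked, level, seed=s_out
                        )
                    results = {}
                    errors = {}
                    for method in cfg.methods:
                        try:
                            results[method] = _impute(method, masked, cfg, s_imp)
                        except Exception as exc:  # recorded, not fatal
                            logger.warning(
                                "%s failed (pattern=%s x=%s outliers=%s rep=%d): %s",
                                method, pattern, x, level, rep, exc,
                            )
                            errors[method] = str(exc)
                    msr_vals = (
                        evaluation.msr(truth, results, sim.theta_s)
                        if len(results) >= 2
                        else {}
                    )
                    for method in cfg.methods:
                        row = {
                            "pattern": pattern, "x_pct": x, "outlier_frac": level,
                            "repeat": rep, "method": method, "seed": s_sim,
                            "nrmse": np.nan, "precision": np.nan, "recall": np.nan,
                            "f1": np.nan, "msr": np.nan, "error": errors.get(method, ""),
                        }
                        if method in results:
                            res = results[method]
                            row["nrmse"] = evaluation.nrmse(truth, res, sim.theta_s)
                            pred = evaluation.build_ccn(
                                res.x_tilde, cfg.ccn_r_min, cfg.ccn_alpha
                            )
                            sc = evaluation.network_scores(pred, original_ccn)
                            row["precision"] = sc.precision
                            row["recall"] = sc.recall
                            row["f1"] = sc.f1
                            row["msr"] = msr_vals.get(method, np.nan)
                        rows.append(row)
    table = pd.DataFrame(rows)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        agg = (
            table.groupby(["pattern", "x_pct", "outlier_frac", "method"])[
                ["nrmse", "precision", "recall", "f1", "msr"]
            ]
            .agg(["mean", "std"])
            .round(6)
        )
        agg.columns = ["_".join(c) for c in agg.columns]
        summary = {
            "config": {
                k: v for k, v in vars(cfg).items() if not k.startswith("_")
            },
            "original_ccn_sparsity": original_ccn.sparsity(),
            "lod": lod,
            "aggregates": [
                {**dict(zip(["pattern", "x_pct", "outlier_frac", "method"], idx)), **rec}
                for idx, rec in agg.to_dict("index").items()
            ],
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return table


def paired_significance(
    table: pd.DataFrame, metric: str = "nrmse", reference: str = "nmf"
) -> pd.DataFrame:
    """Paired t-tests of each method against a reference, BH-adjusted.

    For every grid cell, the per-repeat ``metric`` values of each non-
    reference method are compared with the reference via a paired t-test;
    p-values are Benjamini–Hochberg adjusted across all comparisons.
    Reported for inspection only — no downstream decision consumes it.
    """
    recs = []
    for (pattern, x, level), cell in table.groupby(
        ["pattern", "x_pct", "outlier_frac"]
    ):
        ref = cell[cell.method == reference].sort_values("repeat")[metric].to_numpy()
        for method, sub in cell.groupby("method"):
            if method == reference:
                continue
            other = sub.sort_values("repeat")[metric].to_numpy()
            ok = np.isfinite(ref) & np.isfinite(other)
            if ok.sum() < 2 or np.allclose(ref[ok], other[ok]):
                p = np.nan
            else:
                p = float(_sstats.ttest_rel(other[ok], ref[ok]).pvalue)
            recs.append(
                {"pattern": pattern, "x_pct": x, "outlier_frac": level,
                 "method": method, "mean_diff": float(np.nanmean(other - ref)),
                 "p_value": p}
            )
    out = pd.DataFrame(recs)
    if len(out):
        finite = np.isfinite(out.p_value)
        adj = np.full(len(out), np.nan)
        if finite.any():
            adj[finite] = multipletests(out.p_value[finite], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out
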