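"""Reading, filtering and transforming metabolite abundance matrices.

Conventions
-----------
The canonical in-memory container is :class:`AbundanceMatrix`: a metabolite ×
sample grid of strictly positive intensities together with a boolean
observed-mask.  Missing cells (NAs) carry ``NaN`` in ``values`` and ``False``
in ``observed``.  Zeros in input files are coerced to missing on load — on a
log-intensity scale a true zero is not representable, and in LC–MS practice a
reported zero almost always means "not detected".

Matrices exist on two scales: ``raw`` (positive intensities) and ``log10``
(decadic log plus a recorded non-negative offset so that the NMF
non-negativity constraint also holds on the log scale).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan", "na", "N/A")

__all__ = [
    "AbundanceMatrix",
    "IntervalProfile",
    "load_matrix",
    "save_matrix",
    "filter_by_missing_fraction",
    "log10_transform",
    "inverse_log10",
    "missingness_profile",
    "generate_fixture",
    "DEFAULT_NA_TOKENS",
]


@dataclass
class AbundanceMatrix:
    """Metabolite × sample abundance matrix with an observed-mask.

    Parameters
    ----------
    values
        I × J float array; unobserved cells are ``NaN``.
    observed
        I × J boolean mask, ``True`` where the value was measured.
    metabolite_ids, sample_ids
        Unique row and column identifiers.
    scale
        ``"raw"`` (strictly positive intensities) or ``"log10"``.
    """

    values: np.ndarray
    observed: np.ndarray
    metabolite_ids: list[str]
    sample_ids: list[str]
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.observed = np.array(self.observed, dtype=bool)
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed shapes differ")
        i, j = self.values.shape
        if i < 2 or j < 2:
            raise ValueError("need at least 2 metabolites and 2 samples")
        if len(self.metabolite_ids) != i or len(self.sample_ids) != j:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.metabolite_ids)) != i:
            raise ValueError("duplicate metabolite identifiers")
        if len(set(self.sample_ids)) != j:
            raise ValueError("duplicate sample identifiers")
        if self.scale not in ("raw", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.observed.sum() < 1:
            raise ValueError("matrix has no observed entries")
        obs_vals = self.values[self.observed]
        if not np.all(np.isfinite(obs_vals)):
            raise ValueError("non-finite observed values")
        if self.scale == "raw" and not np.all(obs_vals > 0):
            raise ValueError("raw-scale observed values must be strictly positive")
        # canonicalize: unobserved cells carry NaN
        self.values[~self.observed] = np.nan

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        """|Ω|, the number of observed cells."""
        return int(self.observed.sum())

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_observed / self.values.size

    @property
    def is_complete(self) -> bool:
        return bool(self.observed.all())

    def log_values(self) -> np.ndarray:
        """log10 abundances (NaN at unobserved cells), whatever the scale."""
        if self.scale == "log10":
            return self.values.copy()
        with np.errstate(invalid="ignore"):
            return np.log10(self.values)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.observed.copy(),
            list(self.metabolite_ids),
            list(self.sample_ids),
            self.scale,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = "raw") -> "AbundanceMatrix":
        values = df.to_numpy(dtype=float)
        return cls(
            values,
            np.isfinite(values),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            scale,
        )


@dataclass
class IntervalProfile:
    """Per-interval missingness along the log10-abundance axis.

    ``bin_edges`` has ``n_intervals + 1`` ascending values that partition the
    observed log10-abundance range evenly.  ``missing_pct[b]`` is the
    percentage of entries attributed to bin ``b`` that are missing;
    ``counts[b]`` and ``missing_counts[b]`` are the corresponding totals.
    """

    n_intervals: int
    bin_edges: np.ndarray
    missing_pct: np.ndarray
    counts: np.ndarray
    missing_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.missing_pct = np.asarray(self.missing_pct, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.missing_counts is None:
            self.missing_counts = np.round(
                self.missing_pct / 100.0 * self.counts
            ).astype(int)
        else:
            self.missing_counts = np.asarray(self.missing_counts, dtype=int)
        if len(self.bin_edges) != self.n_intervals + 1:
            raise ValueError("bin_edges must have n_intervals + 1 entries")
        if self.n_intervals > 1 and not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(self.missing_pct < 0) or np.any(self.missing_pct > 100):
            raise ValueError("missing_pct out of [0, 100]")


# ----------------------------------------------------------------------
# I/O


def load_matrix(
    path,
    orientation: str = "metabolites_in_rows",
    na_tokens=DEFAULT_NA_TOKENS,
) -> AbundanceMatrix:
    """Load a delimited abundance table into canonical orientation.

    The file must have one header row and one identifier column; the
    delimiter (comma or tab) is sniffed.  Cells matching ``na_tokens`` or
    numerically equal to zero become unobserved.  A short load report is
    logged.

    Raises
    ------
    ValueError
        On a non-numeric cell that is not an NA token (named by row/column),
        duplicate identifiers, or negative values.
    """
    if orientation not in ("metabolites_in_rows", "metabolites_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not na_tokens:
        raise ValueError("na_tokens must be non-empty")
    df = pd.read_csv(
        path, sep=None, engine="python", index_col=0, dtype=str, keep_default_na=False
    )
    if orientation == "metabolites_in_columns":
        df = df.T
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate metabolite identifiers: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample identifiers: {dups}")

    tokens = {str(t).strip() for t in na_tokens}
    values = np.empty(df.shape, dtype=float)
    n_zero = 0
    for r, (rid, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            cell = "" if cell is None else str(cell).strip()
            if cell in tokens:
                values[r, c] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at metabolite {rid!r}, "
                    f"sample {df.columns[c]!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative value {v} at metabolite {rid!r}, "
                    f"sample {df.columns[c]!r} violates non-negativity"
                )
            if v == 0.0:
                values[r, c] = np.nan
                n_zero += 1
            else:
                values[r, c] = v
    observed = np.isfinite(values)
    m = AbundanceMatrix(
        values, observed, [str(i) for i in df.index], [str(c) for c in df.columns]
    )
    logger.info(
        "loaded %d metabolites x %d samples; NA fraction %.4f; %d zero(s) coerced "
        "to missing",
        m.n_metabolites,
        m.n_samples,
        m.missing_fraction,
        n_zero,
    )
    return m


def save_matrix(m: AbundanceMatrix, path, sidecar: dict | None = None) -> None:
    """Write ``m`` as CSV (empty cells for NAs); optional JSON sidecar."""
    m.to_dataframe().to_csv(path, na_rep="")
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("scale", m.scale)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


# ----------------------------------------------------------------------
# Preprocessing


def filter_by_missing_fraction(
    m: AbundanceMatrix, threshold: float = 0.30
) -> AbundanceMatrix:
    """Apply the "30% deletion" rule: drop metabolites whose missing fraction
    is strictly above ``threshold``; the sample axis is untouched."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = (~m.observed).sum(axis=1) / m.n_samples
    keep = frac <= threshold + 1e-12
    if not keep.any():
        raise ValueError("empty matrix after 30% deletion")
    removed = [mid for mid, k in zip(m.metabolite_ids, keep) if not k]
    if removed:
        logger.info("30%%-deletion removed %d metabolite(s): %s", len(removed), removed)
    return AbundanceMatrix(
        m.values[keep],
        m.observed[keep],
        [mid for mid, k in zip(m.metabolite_ids, keep) if k],
        list(m.sample_ids),
        m.scale,
    )


def log10_transform(m: AbundanceMatrix) -> tuple[AbundanceMatrix, float]:
    """log10-transform a raw matrix, shifting by a recorded offset.

    The offset ``max(0, -floor(min observed log10))`` guarantees all observed
    log values are non-negative, so the B,C ≥ 0 factorization constraint is
    meaningful on the log scale.  Invert with :func:`inverse_log10`.
    """
    if m.scale != "raw":
        raise ValueError("log10_transform expects a raw-scale matrix")
    logv = m.log_values()
    min_log = np.nanmin(logv)
    offset = max(0.0, -np.floor(min_log))
    out = AbundanceMatrix(
        logv + offset, m.observed.copy(), list(m.metabolite_ids),
        list(m.sample_ids), "log10",
    )
    return out, float(offset)


def inverse_log10(m: AbundanceMatrix, offset: float) -> AbundanceMatrix:
    """Entrywise 10**(value − offset); inverse of :func:`log10_transform`."""
    if m.scale != "log10":
        raise ValueError("inverse_log10 expects a log10-scale matrix")
    return AbundanceMatrix(
        10.0 ** (m.values - offset), m.observed.copy(), list(m.metabolite_ids),
        list(m.sample_ids), "raw",
    )


# ----------------------------------------------------------------------
# Missingness profiling


def missingness_profile(
    m: AbundanceMatrix,
    n_intervals: int = 20,
    reference: AbundanceMatrix | None = None,
) -> IntervalProfile:
    """Percentage of missing entries per log10-abundance interval.

    The observed log10-abundance range is split into ``n_intervals`` equal
    bins.  Observed cells fall into the bin of their own value.  Missing
    cells are attributed to the bin of their *true* value when a complete
    ``reference`` matrix is supplied (simulation mode); for real data the bin
    of the metabolite's median observed log-abundance is used as a proxy.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    logv = m.log_values()
    obs = m.observed
    lo = float(np.nanmin(logv))
    hi = float(np.nanmax(logv))
    if hi - lo <= 0:
        warnings.warn("constant matrix: degenerate single-interval profile")
        n_intervals = 1
        edges = np.array([lo, lo])
    else:
        edges = np.linspace(lo, hi, n_intervals + 1)

    def _bin_of(vals: np.ndarray) -> np.ndarray:
        if hi - lo <= 0:
            return np.zeros(vals.shape, dtype=int)
        b = np.floor((vals - lo) / (hi - lo) * n_intervals).astype(int)
        return np.clip(b, 0, n_intervals - 1)

    counts = np.zeros(n_intervals, dtype=int)
    missing_counts = np.zeros(n_intervals, dtype=int)
    np.add.at(counts, _bin_of(logv[obs]), 1)

    miss_idx = np.argwhere(~obs)
    if miss_idx.size:
        if reference is not None:
            if reference.shape != m.shape:
                raise ValueError("reference shape mismatch")
            ref_log = reference.log_values()
            attr = ref_log[~obs]
        else:
            # proxy: metabolite's median observed log abundance
            med = np.full(m.n_metabolites, np.nan)
            for i in range(m.n_metabolites):
                if obs[i].any():
                    med[i] = np.nanmedian(logv[i, obs[i]])
            attr = med[miss_idx[:, 0]]
        ok = np.isfinite(attr)
        b = _bin_of(attr[ok])
        np.add.at(counts, b, 1)
        np.add.at(missing_counts, b, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(counts > 0, 100.0 * missing_counts / np.maximum(counts, 1), 0.0)
    return IntervalProfile(n_intervals, edges, pct, counts, missing_counts)


# ----------------------------------------------------------------------
# Synthetic fixtures


def generate_fixture(
    i: int, j: int, rank: int, noise_sd: float = 0.0, seed: int = 0
) -> AbundanceMatrix:
    """Complete, strictly positive low-rank synthetic abundance matrix.

    Built as ``X = 10**(A @ S + ε)`` with non-negative factors: the first
    component carries each metabolite's mean log10 abundance (drawn from
    N(3.5, 0.75), i.e. a log-normal spread of base abundances over roughly
    two decades), the remaining ``rank − 1`` components are 0.3·|N(0,1)|
    loadings against |N(0,1)| sample scores, and ``ε ~ N(0, noise_sd²)`` is
    measurement noise on the log scale.  With ``noise_sd = 0`` the log10
    matrix has numerical rank exactly ``rank``.  Deterministic per seed.
    """
    if not 1 <= rank <= min(i, j):
        raise ValueError(f"rank must be in [1, {min(i, j)}]")
    rng = np.random.default_rng(seed)
    S = np.abs(rng.standard_normal((rank, j)))
    S[0, :] = 1.0
    A = 0.3 * np.abs(rng.standard_normal((i, rank)))
    A[:, 0] = rng.normal(3.5, 0.75, size=i)
    L = A @ S
    if noise_sd > 0:
        L = L + rng.normal(0.0, noise_sd, size=(i, j))
    values = 10.0 ** L
    return AbundanceMatrix(
        values,
        np.ones((i, j), dtype=bool),
        [f"M{k:04d}" for k in range(i)],
        [f"S{k:03d}" for k in range(j)],
        "raw",
    )
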