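"""Simulation of missingness patterns and artificial outliers.

Three missingness mechanisms are generated on top of a ground-truth matrix:

* **MCAR/MAR** — artificial NAs placed uniformly at random among observed
  cells (no dependence on abundance).
* **MNAR** — left-censoring: artificial NAs placed only among cells whose
  true log10 abundance lies below a limit of detection (LOD), distributed
  across the below-LOD abundance intervals proportionally to the original
  data's per-interval missingness (uniform when the original data carry no
  missingness there).  Intervals above the LOD keep their NA percentage
  unchanged.
* **MM (mixed)** — of the artificial NAs, 20% are MCAR above the LOD and the
  remaining 80% MNAR below it.

Percentages are grid-relative: a target of x% total missingness over an
I × J matrix that already has r% original NAs adds
``round((x − r)/100 · I·J)`` artificial NAs (the set Θs).  The true values
at Θs are known, which is what makes the downstream accuracy metrics
computable.

The LOD is a quantile of the observed log10 abundances (the instrument's
signal-to-noise censoring threshold is rarely published, so a dataset-
adaptive surrogate is used; see ``DEFAULT_LOD_QUANTILE``).

Outlier injection replaces a fraction of observed cells of metabolite i with
draws from Normal(μ_i, (5σ_i)²), where μ_i and σ_i are the metabolite's
observed mean and standard deviation on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrixio import AbundanceMatrix, IntervalProfile, missingness_profile

__all__ = [
    "MissingnessScenario",
    "SimulatedDataset",
    "OutlierSpec",
    "simulate_mcar",
    "simulate_mnar",
    "simulate_mm",
    "determine_lod",
    "inject_outliers",
    "draw_outlier_values",
    "DEFAULT_LOD_QUANTILE",
]

# Fraction of observed log10 abundances treated as below the limit of
# detection.  Untargeted LC–MS routinely censors the bottom third of the
# intensity range, and the default must leave enough below-LOD cells to
# support MNAR/MM simulation up to 30% total missingness (0.8 × 30% = 24%
# of the grid must sit below the LOD).
DEFAULT_LOD_QUANTILE = 0.30


@dataclass
class MissingnessScenario:
    pattern: str  # MCAR | MNAR | MM
    x_pct: float  # target total missing percentage
    r_pct: float  # original missing percentage
    lod: float | None  # log10-abundance threshold (None for MCAR)
    seed: int

    def __post_init__(self) -> None:
        if self.pattern not in ("MCAR", "MNAR", "MM"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 <= self.r_pct <= self.x_pct <= 100:
            raise ValueError("need 0 <= r_pct <= x_pct <= 100")
        if self.pattern in ("MNAR", "MM") and (
            self.lod is None or not np.isfinite(self.lod)
        ):
            raise ValueError(f"{self.pattern} requires a finite LOD")


@dataclass
class SimulatedDataset:
    """Ground truth + masked copy + the artificial missing set Θs."""

    truth: AbundanceMatrix
    masked: AbundanceMatrix
    theta_s: np.ndarray  # (n, 2) int indices of artificial NAs
    scenario: MissingnessScenario

    @property
    def theta_mask(self) -> np.ndarray:
        m = np.zeros(self.truth.shape, dtype=bool)
        if len(self.theta_s):
            m[self.theta_s[:, 0], self.theta_s[:, 1]] = True
        return m


@dataclass
class OutlierSpec:
    fraction: float
    sd_multiplier: float
    seed: int
    replaced: np.ndarray  # (n, 2) int indices
    original_values: np.ndarray


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _mask_with(truth: AbundanceMatrix, theta: np.ndarray) -> AbundanceMatrix:
    observed = truth.observed.copy()
    if len(theta):
        observed[theta[:, 0], theta[:, 1]] = False
    return AbundanceMatrix(
        np.where(observed, truth.values, np.nan),
        observed,
        list(truth.metabolite_ids),
        list(truth.sample_ids),
        truth.scale,
    )


def _n_artificial(truth: AbundanceMatrix, x_pct: float, r_pct: float | None) -> tuple[int, float]:
    if r_pct is None:
        r_pct = 100.0 * (1.0 - truth.n_observed / truth.values.size)
    n = _round_half_up((x_pct - r_pct) / 100.0 * truth.values.size)
    if n < 0:
        raise ValueError("x_pct below the original missing percentage")
    return n, r_pct


# ----------------------------------------------------------------------


def simulate_mcar(
    truth: AbundanceMatrix, x_pct: float, r_pct: float | None = None, seed: int = 0
) -> SimulatedDataset:
    """Uniformly random artificial NAs among observed cells (MCAR/MAR)."""
    n_art, r_pct = _n_artificial(truth, x_pct, r_pct)
    obs_idx = np.argwhere(truth.observed)
    if n_art > len(obs_idx):
        raise ValueError(
            f"requested {n_art} artificial NAs but only {len(obs_idx)} observed cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(obs_idx), size=n_art, replace=False)
    theta = obs_idx[np.sort(pick)]
    scen = MissingnessScenario("MCAR", x_pct, r_pct, None, seed)
    return SimulatedDataset(truth, _mask_with(truth, theta), theta, scen)


def determine_lod(truth: AbundanceMatrix, q: float = DEFAULT_LOD_QUANTILE) -> float:
    """LOD surrogate: the q-quantile of observed log10 abundances."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    logv = truth.log_values()
    return float(np.nanquantile(logv[truth.observed], q))


def _largest_remainder(weights: np.ndarray, total: int, capacity: np.ndarray) -> np.ndarray:
    """Apportion ``total`` across bins ∝ weights, respecting capacities.

    Largest-remainder rounding so counts sum exactly to ``total``; quota
    overflow beyond a bin's capacity is redistributed to bins with room.
    """
    weights = np.asarray(weights, dtype=float)
    capacity = np.asarray(capacity, dtype=int)
    if capacity.sum() < total:
        raise ValueError(
            f"insufficient capacity: requested {total}, attainable {capacity.sum()}"
        )
    if weights.sum() <= 0:
        weights = capacity.astype(float)
    counts = np.zeros(len(weights), dtype=int)
    remaining = total
    active = capacity > 0
    while remaining > 0:
        w = np.where(active, weights, 0.0)
        if w.sum() <= 0:
            w = np.where(active, capacity - counts, 0).astype(float)
        quota = remaining * w / w.sum()
        base = np.minimum(np.floor(quota).astype(int), capacity - counts)
        counts += base
        remaining -= int(base.sum())
        if remaining <= 0:
            break
        frac = np.where(capacity - counts > 0, quota - np.floor(quota), -1.0)
        order = np.argsort(-frac, kind="stable")
        gave = 0
        for b in order:
            if remaining == 0:
                break
            if counts[b] < capacity[b] and frac[b] >= 0:
                counts[b] += 1
                remaining -= 1
                gave += 1
        if gave == 0:  # every weighted bin full: spill to any remaining room
            active = (capacity - counts) > 0
            if not active.any():
                raise ValueError("insufficient capacity during apportionment")
    return counts


def _below_lod_allocation(
    truth: AbundanceMatrix,
    n_below: int,
    lod: float,
    profile: IntervalProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick ``n_below`` observed cells with true log10 value < LOD,
    distributed over abundance intervals ∝ the profile's missingness."""
    logv = truth.log_values()
    eligible = truth.observed & (logv < lod)
    if n_below > eligible.sum():
        raise ValueError(
            f"insufficient below-LOD observed cells: requested {n_below}, "
            f"attainable {int(eligible.sum())}"
        )
    edges = profile.bin_edges
    nb = profile.n_intervals
    lo, hi = edges[0], edges[-1]
    span = hi - lo

    def _bin_of(vals: np.ndarray) -> np.ndarray:
        if span <= 0:
            return np.zeros(vals.shape, dtype=int)
        b = np.floor((vals - lo) / span * nb).astype(int)
        return np.clip(b, 0, nb - 1)

    elig_idx = np.argwhere(eligible)
    elig_bins = _bin_of(logv[eligible])
    capacity = np.bincount(elig_bins, minlength=nb)
    weights = np.where(capacity > 0, profile.missing_pct, 0.0)
    counts = _largest_remainder(weights, n_below, capacity)

    picks = []
    for b in range(nb):
        if counts[b] == 0:
            continue
        pool = elig_idx[elig_bins == b]
        sel = rng.choice(len(pool), size=counts[b], replace=False)
        picks.append(pool[sel])
    if not picks:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(picks, axis=0)


def simulate_mnar(
    truth: AbundanceMatrix,
    x_pct: float,
    r_pct: float | None = None,
    lod: float | None = None,
    profile: IntervalProfile | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Left-censored artificial NAs: every member of Θs lies below the LOD."""
    if lod is None:
        lod = determine_lod(truth)
    if profile is None:
        profile = missingness_profile(truth)
    n_art, r_pct = _n_artificial(truth, x_pct, r_pct)
    rng = np.random.default_rng(seed)
    theta = _below_lod_allocation(truth, n_art, lod, profile, rng)
    scen = MissingnessScenario("MNAR", x_pct, r_pct, lod, seed)
    return SimulatedDataset(truth, _mask_with(truth, theta), theta, scen)


def simulate_mm(
    truth: AbundanceMatrix,
    x_pct: float,
    r_pct: float | None = None,
    lod: float | None = None,
    profile: IntervalProfile | None = None,
    seed: int = 0,
    mcar_share: float = 0.20,
) -> SimulatedDataset:
    """Mixed missingness: 20% of Θs MCAR above the LOD, 80% MNAR below it."""
    if lod is None:
        lod = determine_lod(truth)
    if profile is None:
        profile = missingness_profile(truth)
    n_art, r_pct = _n_artificial(truth, x_pct, r_pct)
    n_above = _round_half_up(mcar_share * n_art)
    n_below = n_art - n_above
    rng = np.random.default_rng(seed)

    logv = truth.log_values()
    above = truth.observed & (logv >= lod)
    above_idx = np.argwhere(above)
    if n_above > len(above_idx):
        raise ValueError(
            f"insufficient above-LOD observed cells: requested {n_above}, "
            f"attainable {len(above_idx)}"
        )
    pick = rng.choice(len(above_idx), size=n_above, replace=False)
    theta_above = above_idx[np.sort(pick)]
    theta_below = _below_lod_allocation(truth, n_below, lod, profile, rng)
    theta = (
        np.concatenate([theta_above, theta_below], axis=0)
        if n_art
        else np.empty((0, 2), dtype=int)
    )
    scen = MissingnessScenario("MM", x_pct, r_pct, lod, seed)
    return SimulatedDataset(truth, _mask_with(truth, theta), theta, scen)


# ----------------------------------------------------------------------
# Outliers


def draw_outlier_values(
    mu: float,
    sigma: float,
    n: int,
    sd_multiplier: float = 5.0,
    rng: np.random.Generator | None = None,
    reject_nonpositive: bool = True,
) -> np.ndarray:
    """Draw replacement values from Normal(μ, (sd_multiplier·σ)²).

    Non-positive draws are redrawn (abundances must stay strictly positive)
    unless ``reject_nonpositive`` is False.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = rng.normal(mu, sd_multiplier * sigma, size=n)
    if reject_nonpositive:
        for _ in range(1000):
            bad = out <= 0
            if not bad.any():
                break
            out[bad] = rng.normal(mu, sd_multiplier * sigma, size=int(bad.sum()))
        else:
            raise RuntimeError("could not draw positive outlier values")
    return out


def inject_outliers(
    truth: AbundanceMatrix,
    fraction: float,
    sd_multiplier: float = 5.0,
    seed: int = 0,
) -> tuple[AbundanceMatrix, OutlierSpec]:
    """Replace ``round(fraction · |Ω|)`` observed cells with inflated-variance
    draws from each metabolite's own abundance distribution.

    Metabolites with fewer than two observed values have no defined σ_i and
    are skipped with a warning.  Original values are kept in the returned
    :class:`OutlierSpec` for audit.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_target = _round_half_up(fraction * truth.n_observed)
    obs_idx = np.argwhere(truth.observed)
    if n_target == 0:
        spec = OutlierSpec(
            fraction, sd_multiplier, seed,
            np.empty((0, 2), dtype=int), np.empty(0),
        )
        return truth.copy(), spec

    pick = rng.choice(len(obs_idx), size=n_target, replace=False)
    cells = obs_idx[np.sort(pick)]

    n_obs_per_met = truth.observed.sum(axis=1)
    usable = n_obs_per_met[cells[:, 0]] >= 2
    if not usable.all():
        skipped = sorted({truth.metabolite_ids[i] for i in cells[~usable, 0]})
        warnings.warn(
            f"skipping outlier injection for metabolite(s) with < 2 observed "
            f"values: {skipped}"
        )
        cells = cells[usable]

    values = truth.values.copy()
    originals = values[cells[:, 0], cells[:, 1]].copy()
    for i in np.unique(cells[:, 0]):
        row_obs = truth.observed[i]
        mu = float(truth.values[i, row_obs].mean())
        sigma = float(truth.values[i, row_obs].std(ddof=1))
        sel = cells[:, 0] == i
        values[i, cells[sel, 1]] = draw_outlier_values(
            mu, sigma, int(sel.sum()), sd_multiplier, rng
        )
    out = AbundanceMatrix(
        values, truth.observed.copy(), list(truth.metabolite_ids),
        list(truth.sample_ids), truth.scale,
    )
    return out, OutlierSpec(fraction, sd_multiplier, seed, cells, originals)
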