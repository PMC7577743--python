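"""Per-lineage fitness from double-barcode count trajectories.

A lineage's per-generation log-fitness ``s`` is estimated jointly with the
population mean-fitness trajectory ``sbar(t)``: over an interval of
``dt`` generations the expected frequency of lineage ``i`` is

    x_i(t + dt) = x_i(t) * exp((s_i - sbar(t)) * dt)

with ``sbar(t)`` defined self-consistently so the predicted frequencies
stay on the simplex.  Estimation alternates between updating ``sbar`` from
the current fitness assignments and re-maximising each lineage's
quasi-likelihood, a dispersion-weighted squared error on one-step-ahead
predicted frequencies.  Working on frequencies makes the estimates exactly
invariant to rescaling all counts at any one timepoint (sequencing depth is
arbitrary), and a constant dispersion factor ``kappa`` then drops out of
the per-lineage argmax; it is retained for uncertainty bookkeeping.

Low-information lineages are merged into one aggregate trajectory before
estimation, and lineages whose trajectory the fitted model reproduces
poorly (d-statistic >= ``d_max``, default 19) are flagged and excluded
downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LineageTrajectory",
    "FitnessEstimate",
    "MERGED_LINEAGE_ID",
    "D_MAX_DEFAULT",
    "merge_low_info_lineages",
    "estimate_fitness",
    "fit_deviation_d",
]

MERGED_LINEAGE_ID = "_merged"
D_MAX_DEFAULT = 19.0

# merging criteria for low-information trajectories
MIN_NONZERO_TIMEPOINTS = 3
MIN_MAX_COUNT = 5  # at least one timepoint with count > 4
MIN_TOTAL_COUNT = 10


@dataclass(frozen=True)
class LineageTrajectory:
    """Counts of one double-barcode lineage over cumulative generations."""

    lineage_id: str
    counts: tuple[float, ...]
    generations: tuple[float, ...]
    pair_id: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.generations) or len(self.counts) < 2:
            raise ValueError("counts and generations must align with length >= 2")
        if any(b <= a for a, b in zip(self.generations, self.generations[1:])):
            raise ValueError("generations must be strictly increasing")


@dataclass(frozen=True)
class FitnessEstimate:
    lineage_id: str
    s: float
    d: float
    status: str  # kept | merged | filtered_poor_fit


def merge_low_info_lineages(counts: pd.DataFrame):
    """Split a lineage x timepoint count matrix into kept lineages and one
    aggregate of low-information lineages.

    A lineage is merged when any of these holds: fewer than three
    timepoints with a positive count; no timepoint with more than four
    reads; fewer than 10 reads in total.  The aggregate (row label
    ``_merged``) participates in estimation but yields no per-lineage
    fitness.

    Returns ``(kept, merged_row)`` where ``merged_row`` is a one-row frame
    (or ``None`` when nothing merges).
    """
    x = counts.to_numpy(dtype=float)
    low = (
        ((x > 0).sum(axis=1) < MIN_NONZERO_TIMEPOINTS)
        | (x.max(axis=1) < MIN_MAX_COUNT)
        | (x.sum(axis=1) < MIN_TOTAL_COUNT)
    )
    kept = counts.loc[~low]
    if not low.any():
        return kept, None
    merged = pd.DataFrame(
        [counts.loc[low].sum(axis=0)], index=pd.Index([MERGED_LINEAGE_ID], name=counts.index.name)
    )
    return kept, merged


def _mean_fitness(freqs: np.ndarray, s: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """sbar per interval such that predicted frequencies renormalise:
    sbar_t = log(sum_i x_i(t) exp(s_i dt)) / dt."""
    smax = s.max()
    w = freqs[:, :-1] * np.exp((s - smax)[:, None] * dts[None, :])
    return np.log(w.sum(axis=0)) / dts + smax


def _lineage_loss(s_grid: np.ndarray, freqs: np.ndarray, sbar: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """Vectorised per-lineage objective at per-lineage candidate fitnesses.

    ``s_grid`` holds one candidate s per lineage.  The loss is the sum over
    transitions (with a positive source frequency) of
    ``(x_obs - x_pred)^2 / x_pred`` — a chi-square-style quasi-likelihood
    whose variance model is proportional to the predicted frequency.
    """
    src = freqs[:, :-1]
    obs = freqs[:, 1:]
    pred = src * np.exp((s_grid[:, None] - sbar[None, :]) * dts[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(src > 0, (obs - pred) ** 2 / np.where(pred > 0, pred, 1.0), 0.0)
    return contrib.sum(axis=1)


def _golden_section(loss_fn, n_lineages: int, lo: float, hi: float, n_iter: int = 60) -> np.ndarray:
    """Vectorised golden-section minimisation: one bracket per lineage."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_lineages, lo)
    b = np.full(n_lineages, hi)
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc = loss_fn(c)
    fd = loss_fn(d)
    for _ in range(n_iter):
        lower = fc < fd
        b = np.where(lower, d, b)
        a = np.where(lower, a, c)
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        fc = loss_fn(c)
        fd = loss_fn(d)
    return (a + b) / 2.0


def estimate_fitness(
    counts: pd.DataFrame,
    generations,
    kappa: float = 2.5,
    neutral_lineages=None,
    d_max: float = D_MAX_DEFAULT,
    max_iter: int = 50,
    tol: float = 1e-4,
    s_bounds: tuple[float, float] = (-2.0, 2.0),
    merge: bool = True,
) -> pd.DataFrame:
    """Estimate per-generation fitness for every kept lineage.

    Parameters
    ----------
    counts
        Lineage x timepoint count matrix (index: lineage_id).
    generations
        Cumulative generations per timepoint column, strictly increasing.
    kappa
        Count dispersion (variance/mean); scales reported uncertainty but
        not the point estimates.
    neutral_lineages
        Lineage ids whose mean fitness anchors s = 0 (DHFR(-) controls).
        When empty or absent, no re-anchoring is applied (logged).
    merge
        Apply the low-information merging rules first.

    Returns a frame indexed by lineage_id with columns ``s``, ``d``,
    ``status`` (kept / merged / filtered_poor_fit).
    """
    gens = np.asarray(list(generations), dtype=float)
    if counts.shape[1] != len(gens) or counts.shape[1] < 2:
        raise ValueError("counts must have one column per generation, >= 2 timepoints")
    if np.any(np.diff(gens) <= 0):
        raise ValueError("generations must be strictly increasing")
    totals = counts.to_numpy(dtype=float).sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every timepoint needs a positive total count")

    merged_row = None
    work = counts
    if merge:
        work, merged_row = merge_low_info_lineages(counts)
        if merged_row is not None:
            work = pd.concat([work, merged_row])
    if len(work) < 2:
        raise ValueError("need at least two lineages to identify relative fitness")

    x = work.to_numpy(dtype=float)
    col_tot = x.sum(axis=0)
    freqs = x / col_tot
    dts = np.diff(gens)

    # init: log-linear regression of log-frequency (pseudocounted) on generations
    logf = np.log((x + 0.5) / (col_tot + 0.5 * len(work)))
    gc = gens - gens.mean()
    s = (logf @ gc) / (gc @ gc)
    s = np.clip(s, *s_bounds)

    # a uniform shift of all s is a flat (gauge) direction of the model;
    # pin it by recentering on the initial-frequency-weighted mean
    w0 = freqs[:, 0] / freqs[:, 0].sum()
    s = s - s @ w0
    converged = False
    for _ in range(max_iter):
        sbar = _mean_fitness(freqs, s, dts)
        s_new = _golden_section(
            lambda cand: _lineage_loss(cand, freqs, sbar, dts), len(work), *s_bounds
        )
        s_new = s_new - s_new @ w0
        delta = np.max(np.abs(s_new - s))
        s = s_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fitness estimation did not converge; returning best iterate")

    # anchor to the neutral set when present
    neutral_lineages = list(neutral_lineages or [])
    anchor_idx = work.index.isin(neutral_lineages)
    if anchor_idx.any():
        s = s - s[anchor_idx].mean()
    elif neutral_lineages:
        logger.info("neutral set absent from data; fitness left unanchored")
    else:
        logger.info("no neutral set supplied; fitness left unanchored")

    # d statistic on counts: one-step-ahead predicted counts
    sbar = _mean_fitness(freqs, s, dts)
    pred_freq = freqs[:, :-1] * np.exp((s[:, None] - sbar[None, :]) * dts[None, :])
    pred_counts = pred_freq * col_tot[1:]
    obs_counts = x[:, 1:]
    d = np.array(
        [
            fit_deviation_d(obs_counts[i][x[i, :-1] > 0], pred_counts[i][x[i, :-1] > 0])
            for i in range(len(work))
        ]
    )

    out = pd.DataFrame({"s": s, "d": d}, index=work.index)
    out["status"] = np.where(out["d"] >= d_max, "filtered_poor_fit", "kept")
    out.loc[out.index == MERGED_LINEAGE_ID, "status"] = "merged"
    if merge and merged_row is not None:
        dropped = counts.index.difference(work.index)
        extra = pd.DataFrame(
            {"s": np.nan, "d": np.nan, "status": "merged"}, index=dropped
        )
        out = pd.concat([out.loc[out.index != MERGED_LINEAGE_ID], extra])
    else:
        out = out.loc[out.index != MERGED_LINEAGE_ID]
    out.index.name = "lineage_id"
    out.attrs["kappa"] = kappa
    out.attrs["converged"] = converged
    return out.reindex(counts.index)


def fit_deviation_d(observed, predicted) -> float:
    """Summed squared relative deviation between observed and predicted
    counts: ``d = sum_i ((pred_i - obs_i) / obs_i)^2`` over timepoints with
    a positive observed count."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    mask = obs > 0
    return float((((pred[mask] - obs[mask]) / obs[mask]) ** 2).sum())
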