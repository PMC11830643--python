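"""Disparity rarefaction: variance and cumulative range versus sample size.

Groups of unequal diversity (here, bivalve families) are compared by
repeatedly subsampling each group's trait values at increasing sample
sizes and tracking a disparity statistic — the sample variance (n-1
denominator) or the cumulative range (max - min).  The median and the
2.5/97.5 percentile envelope over the replicates form a rarefaction curve;
the sample size at which two groups' envelopes separate (and stay
separated) estimates how many species are needed to tell their disparity
apart.

Subsampling is without replacement, so at the full group size every
replicate equals the full-sample statistic and the curve pins to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RarefactionCurve",
    "IncomparableCurvesError",
    "rarefy",
    "divergence_threshold",
    "range_stabilization",
    "curves_to_frame",
]

DEFAULT_N_MIN = 5
DEFAULT_REPS = 1000


class IncomparableCurvesError(ValueError):
    """Curves measure different things or share no subsample sizes."""


@dataclass(frozen=True)
class RarefactionCurve:
    """Median and 95% envelope of a disparity statistic along a size grid."""

    group: str
    metric: str               # "variance" | "range"
    variable: str             # e.g. "pSV", "logSL", "XS"
    n_grid: np.ndarray        # subsample sizes, n_min .. group size
    median: np.ndarray
    ci_low: np.ndarray        # 2.5th percentile
    ci_high: np.ndarray       # 97.5th percentile
    mean: np.ndarray          # per-n mean of the statistic over replicates
    reps: int
    seed: int

    @property
    def full_sample_size(self) -> int:
        return int(self.n_grid[-1])

    @property
    def full_sample_value(self) -> float:
        return float(self.median[-1])


def _statistic(subsamples: np.ndarray, metric: str) -> np.ndarray:
    """Disparity statistic along the last axis of a (reps, n) array."""
    if metric == "variance":
        return subsamples.var(axis=-1, ddof=1)
    if metric == "range":
        return subsamples.max(axis=-1) - subsamples.min(axis=-1)
    raise ValueError(f"unknown disparity metric {metric!r}")


def rarefy(values, metric: str, *, group: str = "", variable: str = "",
           n_min: int = DEFAULT_N_MIN, reps: int = DEFAULT_REPS,
           seed: int = 0) -> "RarefactionCurve | None":
    """Rarefaction curve of a disparity statistic for one group.

    For each subsample size ``n`` from ``n_min`` to the group size, ``reps``
    subsamples are drawn without replacement and the statistic's median and
    2.5/97.5 percentiles recorded.  Fully reproducible from ``seed``.
    Returns ``None`` (with a warning) for groups smaller than ``n_min``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    size = len(values)
    if size < n_min:
        warnings.warn(f"group {group!r} has {size} < n_min = {n_min} values; "
                      "skipped", stacklevel=2)
        return None

    rng = np.random.default_rng(seed)
    n_grid = np.arange(n_min, size + 1)
    med = np.empty(len(n_grid))
    lo = np.empty(len(n_grid))
    hi = np.empty(len(n_grid))
    avg = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        if n == size:
            # only one distinct subsample exists
            stat = _statistic(values[None, :], metric)
            med[i] = lo[i] = hi[i] = avg[i] = stat[0]
            continue
        # reps subsamples without replacement, vectorised via argsort trick
        idx = np.argsort(rng.random((reps, size)), axis=1)[:, :n]
        stats = _statistic(values[idx], metric)
        med[i] = np.median(stats)
        lo[i], hi[i] = np.percentile(stats, [2.5, 97.5])
        avg[i] = stats.mean()
    return RarefactionCurve(group=group, metric=metric, variable=variable,
                            n_grid=n_grid, median=med, ci_low=lo, ci_high=hi,
                            mean=avg, reps=reps, seed=seed)


def divergence_threshold(curve_a: RarefactionCurve,
                         curve_b: RarefactionCurve) -> "int | None":
    """Smallest shared subsample size at which the two 95% envelopes are
    disjoint and remain disjoint at every larger shared size; ``None`` if
    the envelopes never persistently separate.
    """
    if curve_a.metric != curve_b.metric or curve_a.variable != curve_b.variable:
        raise IncomparableCurvesError(
            "curves measure different metrics or variables")
    shared = np.intersect1d(curve_a.n_grid, curve_b.n_grid)
    if len(shared) == 0:
        raise IncomparableCurvesError("curves share no subsample sizes")
    ia = np.searchsorted(curve_a.n_grid, shared)
    ib = np.searchsorted(curve_b.n_grid, shared)
    disjoint = ((curve_a.ci_high[ia] < curve_b.ci_low[ib])
                | (curve_b.ci_high[ib] < curve_a.ci_low[ia]))
    # smallest n from which disjointness persists to the end of the grid
    persist = np.flip(np.logical_and.accumulate(np.flip(disjoint)))
    hits = np.nonzero(persist)[0]
    return int(shared[hits[0]]) if len(hits) else None


def range_stabilization(curve: RarefactionCurve, tol: float = 0.01) -> int:
    """Sample size at which the median cumulative range flattens.

    Returns the smallest ``n`` whose median range is at least ``(1 - tol)``
    of the full-sample range and stays so for all larger ``n``.  Always at
    most the group size.
    """
    if curve.metric != "range":
        raise ValueError("range_stabilization requires a range curve")
    target = (1.0 - tol) * curve.full_sample_value
    ok = curve.median >= target
    persist = np.flip(np.logical_and.accumulate(np.flip(ok)))
    return int(curve.n_grid[np.nonzero(persist)[0][0]])


def curves_to_frame(curves) -> pd.DataFrame:
    """Long-format table (group, variable, metric, n, median, lo, hi)."""
    rows = []
    for c in curves:
        if c is None:
            continue
        for n, m, lo, hi in zip(c.n_grid, c.median, c.ci_low, c.ci_high):
            rows.append({"group": c.group, "variable": c.variable,
                         "metric": c.metric, "n": int(n), "median": m,
                         "lo": lo, "hi": hi})
    return pd.DataFrame(rows)
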