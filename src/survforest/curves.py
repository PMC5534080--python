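"""Right-continuous step-function survival curves and product-limit estimators.

The same sequential product-limit routine serves both the event survival
function S(t) and the censoring survival function G(t): ties between events
and censorings at the same observed time are broken by processing events
first, so that a subject censored at t is still at risk for an event at t,
and an event at t does not count a simultaneous censoring as already removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SurvivalCurve:
    """Non-increasing right-continuous step function with value 1 before the
    first knot.

    Parameters
    ----------
    knots : strictly increasing times at which the curve drops.
    values : curve value at and after each knot (before ``knots[0]`` the
        value is 1).
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)
        if knots.shape != values.shape or knots.ndim != 1:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if values.size and (np.any(values < -1e-12) or np.any(values > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        if values.size and np.any(np.diff(values) > 1e-12):
            raise ValueError("survival values must be non-increasing")

    @classmethod
    def _trusted(cls, knots: np.ndarray, values: np.ndarray) -> "SurvivalCurve":
        """Constructor bypassing validation for internally-built curves."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "knots", knots)
        object.__setattr__(obj, "values", values)
        return obj

    def __call__(self, t) -> np.ndarray:
        """Evaluate the step function at times ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right")
        padded = np.concatenate(([1.0], self.values))
        return padded[idx]

    def left_limit(self, t) -> np.ndarray:
        """Evaluate the left limit S(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="left")
        padded = np.concatenate(([1.0], self.values))
        return padded[idx]


def _tie_order(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Stable ordering by time with events preceding censorings at ties."""
    return np.lexsort((1 - event, time))


def product_limit(time, event, reverse: bool = False) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    With ``reverse=True`` the roles of events and censorings are swapped,
    yielding the censoring survival function G(t); the events-first tie
    convention is kept, so tied events are still in the risk set of a
    censoring at the same time but not vice versa.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one observation")
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    order = _tie_order(time, event)
    t_sorted = time[order]
    d_sorted = event[order] if not reverse else 1 - event[order]
    n = time.size
    # sequential risk sets n, n-1, ...: grouped (1 - d/Y) factors emerge as
    # products of per-subject factors within a tie group
    at_risk = n - np.arange(n)
    factors = np.where(d_sorted == 1, 1.0 - 1.0 / at_risk, 1.0)
    surv = np.cumprod(factors)
    # collapse to knots where the curve actually drops, at the last position
    # of each tied time
    drop = d_sorted == 1
    if not np.any(drop):
        return SurvivalCurve._trusted(np.empty(0), np.empty(0))
    knots_mask = np.zeros(n, dtype=bool)
    # value at a dropping time = survival after processing the whole tie group
    drop_times = np.unique(t_sorted[drop])
    idx_last = np.searchsorted(t_sorted, drop_times, side="right") - 1
    knots_mask[idx_last] = True
    return SurvivalCurve._trusted(t_sorted[knots_mask], surv[knots_mask])


def nelson_aalen_cumhaz(time, event, grid: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated on ``grid``.

    Returns H(t) = sum_{t_k <= t} d_k / Y_k over distinct event times t_k.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = _tie_order(time, event)
    t_sorted = time[order]
    d_sorted = event[order]
    n = time.size
    # grouped d/Y at a tied event time: all tied subjects (events and
    # censorings) are at risk, so Y = count with T >= t
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    Y = n - first_idx
    d = np.add.reduceat(d_sorted, first_idx)
    increments = np.where(Y > 0, d / Y, 0.0)
    cumhaz = np.cumsum(increments)
    idx = np.searchsorted(uniq, np.asarray(grid, dtype=float), side="right")
    padded = np.concatenate(([0.0], cumhaz))
    return padded[idx]


def weighted_kaplan_meier(
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Weighted Kaplan-Meier curves for one or many weight vectors.

    ``weights`` has shape (n_curves, n_subjects); each row defines one curve
    S_w(t) = prod_{event times <= t} (1 - wd_k / wY_k) where wd and wY are
    weighted event counts and weighted numbers at risk. Uniform weights
    recover the ordinary Kaplan-Meier estimate.

    Returns an array of shape (n_curves, len(grid)).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    order = _tie_order(time, event)
    t_sorted = time[order]
    d_sorted = event[order]
    w = weights[:, order]
    # weighted number at risk just before each position (ties events-first)
    wY = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where((d_sorted == 1) & (wY > 0), w / np.where(wY > 0, wY, 1.0), 0.0)
    factors = 1.0 - frac
    surv_seq = np.cumprod(factors, axis=1)
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(t_sorted, grid, side="right") - 1
    out = np.ones((weights.shape[0], grid.size))
    valid = idx >= 0
    out[:, valid] = surv_seq[:, idx[valid]]
    return np.clip(out, 0.0, 1.0)
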