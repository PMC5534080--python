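"""Random survival forests: bootstrap ensembles of survival trees.

RSF1 grows trees under the log-rank split rule, RSF2 under the log-rank
score split rule. Each tree is grown on an independent bootstrap sample
(with replacement, size N) with per-node random candidate selection; the
ensemble survival prediction averages terminal-node Nelson-Aalen cumulative
hazards across trees and exponentiates, so every prediction is a proper
non-increasing curve starting at 1. Out-of-bag machinery supports honest
prediction error and permutation variable importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import nelson_aalen_cumhaz
from .datagen import SurvivalDataset
from .survtree import ColumnSet, SurvivalTree, _grow_tree_arrays

RSF_RULES = ("logrank", "logrank_score")
MODEL_RULES = {"rsf1": "logrank", "rsf2": "logrank_score"}


@dataclass
class Forest:
    """Ensemble of survival trees plus their resampling bookkeeping.

    ``in_bag`` holds the per-tree sampled index arrays (a multiset for the
    bootstrap used by RSF, a subsample without replacement for conditional
    inference forests); ``oob`` holds the complementary out-of-bag index
    sets.
    """

    trees: list[SurvivalTree]
    in_bag: list[np.ndarray]
    oob: list[np.ndarray]
    rule: str  # "logrank" | "logrank_score" | "cif"
    n_trees: int
    seed: int
    data: SurvivalDataset = field(repr=False)
    params: dict = field(default_factory=dict)


def fit_rsf(
    data: SurvivalDataset,
    rule: str = "logrank",
    n_trees: int = 100,
    mtry: int | None = None,
    min_node_size: int = 15,
    min_events: int = 3,
    seed: int = 0,
) -> Forest:
    """Fit a random survival forest (RSF1: ``logrank``, RSF2: ``logrank_score``)."""
    if rule == "cif":
        raise ValueError("rule 'cif' belongs to the conditional inference module")
    if rule not in RSF_RULES:
        raise ValueError(f"unknown RSF rule {rule!r}")
    if data.event.sum() == 0:
        raise ValueError("dataset contains no events")
    n = data.n
    cols = ColumnSet.from_frame(data.covariates, data.kinds)
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(n_trees)
    trees: list[SurvivalTree] = []
    in_bag: list[np.ndarray] = []
    oob: list[np.ndarray] = []
    for b in range(n_trees):
        rng = np.random.default_rng(tree_seeds[b])
        idx = np.sort(rng.integers(0, n, size=n))
        if data.event[idx].sum() == 0:  # degenerate bootstrap: keep original data
            idx = np.arange(n)
        tree = _grow_tree_arrays(
            data.time[idx],
            data.event[idx],
            cols.take(idx),
            rule,
            mtry,
            min_node_size,
            min_events,
            rng,
        )
        trees.append(tree)
        in_bag.append(idx)
        oob.append(np.setdiff1d(np.arange(n), idx))
    return Forest(
        trees=trees,
        in_bag=in_bag,
        oob=oob,
        rule=rule,
        n_trees=n_trees,
        seed=seed,
        data=data,
        params=dict(mtry=mtry, min_node_size=min_node_size, min_events=min_events),
    )


def _tree_cumhaz(tree: SurvivalTree, X, grid: np.ndarray) -> np.ndarray:
    """Per-row Nelson-Aalen cumulative hazard of the routed terminal node."""
    leaf_ids = tree.apply(X)
    H = np.empty((leaf_ids.size, grid.size))
    for leaf in tree.leaves():
        rows = leaf_ids == leaf.node_id
        if not rows.any():
            continue
        members = leaf.members
        H[rows] = nelson_aalen_cumhaz(
            tree.time[members], tree.event[members], grid
        )
    return H


def predict_survival(
    forest: Forest, x_new: pd.DataFrame, eval_times
) -> np.ndarray:
    """Ensemble survival probabilities, shape (n_subjects, len(eval_times)).

    For RSF rules the per-tree terminal cumulative hazards are averaged and
    exponentiated; for conditional inference forests the weighted
    Kaplan-Meier prediction of the cif module is used.
    """
    grid = np.asarray(eval_times, dtype=float)
    if forest.rule == "cif":
        from .cif import predict_cif_survival

        return predict_cif_survival(forest, x_new, grid)
    cols = ColumnSet.from_frame(x_new, forest.data.kinds)
    H = np.zeros((len(x_new), grid.size))
    for tree in forest.trees:
        H += _tree_cumhaz(tree, cols, grid)
    return np.exp(-H / forest.n_trees)


def oob_predict(
    forest: Forest,
    data: SurvivalDataset | None = None,
    eval_times=None,
    x_override: pd.DataFrame | None = None,
) -> np.ndarray:
    """Out-of-bag ensemble predictions for the training subjects.

    Each subject is predicted using only the trees in which it is
    out-of-bag. Subjects that are in-bag in every tree receive NaN rows and
    trigger a warning. ``x_override`` substitutes a covariate frame (same
    row order) for permutation-importance computations.
    """
    if data is None:
        data = forest.data
    grid = np.asarray(eval_times, dtype=float)
    X = forest.data.covariates if x_override is None else x_override
    n = len(X)
    if forest.rule == "cif":
        from .cif import _cif_weights

        w, n_oob = _cif_weights(forest, X, oob_only=True)
        from .curves import weighted_kaplan_meier

        surv = weighted_kaplan_meier(
            forest.data.time, forest.data.event, w, grid
        )
        surv[n_oob == 0] = np.nan
        if (n_oob == 0).any():
            warnings.warn(
                f"{int((n_oob == 0).sum())} subject(s) in-bag in every tree: "
                "no OOB prediction"
            )
        return surv
    cols = ColumnSet.from_frame(X, forest.data.kinds)
    H = np.zeros((n, grid.size))
    count = np.zeros(n)
    for tree, oob_idx in zip(forest.trees, forest.oob):
        if oob_idx.size == 0:
            continue
        H[oob_idx] += _tree_cumhaz(tree, cols.take(oob_idx), grid)
        count[oob_idx] += 1
    uncovered = count == 0
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} subject(s) in-bag in every tree: "
            "no OOB prediction"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        surv = np.exp(-H / np.where(count > 0, count, 1)[:, None])
    surv[uncovered] = np.nan
    return surv


def _oob_ibs(forest: Forest, grid: np.ndarray, x_override=None) -> float:
    """Integrated Brier score of OOB predictions (covered subjects only)."""
    from .evalmetrics import brier_curve, censoring_km, integrated_brier

    data = forest.data
    surv = oob_predict(forest, data, grid, x_override=x_override)
    covered = ~np.isnan(surv[:, 0])
    G = censoring_km(data.time, data.event)
    bs = brier_curve(
        surv[covered], data.time[covered], data.event[covered], grid, G
    )
    return integrated_brier(bs, grid)


def permutation_vimp(
    forest: Forest,
    data: SurvivalDataset | None = None,
    eval_times=None,
    n_perm: int = 1,
    seed: int = 0,
    permute=None,
) -> pd.DataFrame:
    """Permutation variable importance under the integrated Brier score.

    Importance of a covariate = mean increase of the out-of-bag IBS after
    permuting that covariate's column, over ``n_perm`` permutations. Larger
    values mean the forest relies more on the covariate. ``permute`` may
    override the permutation draw (callable (rng, n) -> index array), mainly
    for diagnostics.

    Returns a DataFrame with columns covariate, importance, rank.
    """
    if data is None:
        data = forest.data
    if eval_times is None:
        eval_times = default_eval_grid(data)
    grid = np.asarray(eval_times, dtype=float)
    if permute is None:
        permute = lambda rng, n: rng.permutation(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = _oob_ibs(forest, grid)
        rng = np.random.default_rng(seed)
        rows = []
        for col in data.covariates.columns:
            deltas = []
            for _ in range(n_perm):
                Xp = data.covariates.copy()
                perm = permute(rng, data.n)
                Xp[col] = Xp[col].array[perm]  # .array keeps Categorical dtype
                deltas.append(_oob_ibs(forest, grid, x_override=Xp) - base)
            rows.append((col, float(np.mean(deltas))))
    out = pd.DataFrame(rows, columns=["covariate", "importance"])
    out["rank"] = (
        out["importance"].rank(ascending=False, method="min").astype(int)
    )
    return out


def default_eval_grid(
    data: SurvivalDataset, q: float = 0.95, max_points: int = 100
) -> np.ndarray:
    """Unique event times truncated at the q-th follow-up percentile.

    Grids larger than ``max_points`` are thinned to quantile-spaced event
    times, which leaves trapezoidal time integrals essentially unchanged
    while bounding the prediction cost on large datasets.
    """
    ev = np.unique(data.time[data.event == 1])
    cutoff = np.quantile(data.time, q)
    grid = ev[ev <= cutoff]
    if grid.size < 2:
        grid = ev[: max(2, ev.size)]
    if grid.size > max_points:
        qs = np.linspace(0, 1, max_points)
        grid = np.unique(np.quantile(grid, qs))
    return grid
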