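"""Conditional inference survival trees and forests.

The conditional inference procedure separates the choice of the split
*variable* from the search for the split *point*: at every node each
candidate covariate is tested for association with the censored outcome by
a linear rank test on the node's log-rank scores, within the permutation
framework (statistics standardized by their conditional mean and variance
given the data). The covariate with the minimum multiplicity-adjusted
p-value is selected; if even that adjusted p-value exceeds ``alpha`` the
node becomes terminal. Only then is the best binary split point on the
selected covariate searched. This removes the selection bias towards
covariates with many candidate split points that plain exhaustive split
search exhibits.

Forests aggregate trees grown on subsamples drawn without replacement and
predict through a weighted Kaplan-Meier estimate over the training set: a
training subject's weight accumulates over trees in which it shares a
terminal node with the query point, normalized by terminal-node size, so
terminals with many subjects at risk contribute greater total weight.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .curves import weighted_kaplan_meier
from .datagen import SurvivalDataset
from .rsf import Forest
from .survtree import (
    ColumnSet,
    LogrankScores,
    SurvivalTree,
    TreeNode,
    _best_split_arrays,
    kaplan_meier,
    logrank_scores,
)

EXACT_NODE_SIZE = 20  # below this, Monte-Carlo permutation p-values
EXACT_DRAWS = 1999


@dataclass(frozen=True)
class AssociationTestResult:
    variable: str
    statistic: float  # quadratic-form linear rank statistic (z^2 if univariate)
    p_value: float
    adjusted_p: float = 1.0


def _components(
    arr: np.ndarray, kind: str, a: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """(T_obs, mu, Sigma, level_indicators) of the linear rank statistic.

    A numeric x contributes the single component sum(x_i a_i); a
    categorical x with L observed levels one per-level component
    sum_{x=l} a_i. Moments are the conditional (permutation) mean vector
    and covariance matrix given the observed scores: Sigma = S_a^2 *
    (diag(n_l) - n_l n_m / n), with S_a^2 the (N-1)-denominator variance
    of the scores.
    """
    n = a.size
    abar = a.mean()
    s2 = a.var(ddof=1) if n > 1 else 0.0
    if kind == "polytomous":
        levels = np.unique(arr)
        levels = levels[levels >= 0]
        ind = arr[None, :] == levels[:, None]
        T = ind @ a
        n_l = ind.sum(axis=1).astype(float)
        mu = n_l * abar
        Sigma = s2 * (np.diag(n_l) - np.outer(n_l, n_l) / n)
        return T, mu, Sigma, ind
    x = arr.astype(float)
    T = np.array([x @ a])
    mu = np.array([n * x.mean() * abar])
    Sigma = np.array([[np.sum((x - x.mean()) ** 2) * s2]])
    return T, mu, Sigma, None


def _rank_test_arrays(
    arr: np.ndarray,
    kind: str,
    a: np.ndarray,
    rng: np.random.Generator | None,
    exact_node_size: int,
    exact_draws: int,
) -> tuple[float, float]:
    """(statistic, p_value) of the linear rank independence test.

    The statistic is the quadratic form (T - mu)' Sigma^+ (T - mu), which
    for a single component reduces to the squared standardized statistic;
    its asymptotic reference is chi-square with df = rank(Sigma), so
    p-values are comparable across covariates with different numbers of
    levels — the property that removes split-point-cardinality bias.
    """
    n = a.size
    T, mu, Sigma, ind = _components(arr, kind, a)
    Sigma = np.atleast_2d(Sigma)
    # pseudo-inverse: the level components are sum-constrained (rank L-1)
    eigval, eigvec = np.linalg.eigh(Sigma)
    tol = max(Sigma.shape[0], 1) * np.finfo(float).eps * max(eigval.max(), 0.0)
    keep = eigval > tol
    df = int(keep.sum())
    if df == 0:
        raise ValueError("degenerate test: zero permutation variance")
    P = (eigvec[:, keep] / eigval[keep]) @ eigvec[:, keep].T

    def quad(Tm: np.ndarray) -> np.ndarray:
        d = Tm - mu
        return np.einsum("...i,ij,...j->...", d, P, d)

    c = float(quad(T))
    if n < exact_node_size:
        if rng is None:
            rng = np.random.default_rng(0)
        perms = rng.permuted(np.tile(a, (exact_draws, 1)), axis=1)
        if ind is not None:
            Tp = perms @ ind.T.astype(float)
        else:
            Tp = (perms @ arr.astype(float))[:, None]
        cp = quad(Tp)
        p = (1.0 + np.sum(cp >= c - 1e-12)) / (exact_draws + 1.0)
    else:
        # chi2.sf(c, df) via the regularized upper incomplete gamma ufunc
        p = float(gammaincc(df / 2.0, c / 2.0))
    return c, float(min(max(p, 0.0), 1.0))


def linear_rank_test(
    x: pd.Series,
    scores: LogrankScores | np.ndarray,
    rng: np.random.Generator | None = None,
    exact_node_size: int = EXACT_NODE_SIZE,
    exact_draws: int = EXACT_DRAWS,
) -> AssociationTestResult:
    """Permutation-framework test of independence between x and the scores.

    The statistic is the quadratic form of the linear rank statistic,
    standardized by its conditional (permutation) mean and covariance;
    for a binary or numeric x it is the squared standardized statistic.
    P-values come from the asymptotic chi-square reference with df equal
    to the number of free contrast components; for nodes smaller than
    ``exact_node_size`` a seeded Monte-Carlo permutation p-value is used
    instead.
    """
    a = scores.scores if isinstance(scores, LogrankScores) else np.asarray(scores, float)
    if x.nunique() <= 1:
        raise ValueError("constant covariate: association test undefined")
    if isinstance(x.dtype, pd.CategoricalDtype):
        arr, kind = x.cat.codes.to_numpy().astype(np.int64), "polytomous"
    else:
        arr, kind = x.to_numpy(dtype=float), "numeric"
    c, p = _rank_test_arrays(arr, kind, a, rng, exact_node_size, exact_draws)
    return AssociationTestResult(variable=str(x.name or ""), statistic=c, p_value=p)


def _select_arrays(
    time: np.ndarray,
    event: np.ndarray,
    cols: ColumnSet,
    candidate_positions: list[int],
    alpha: float,
    rng: np.random.Generator | None,
    exact_node_size: int = EXACT_NODE_SIZE,
    exact_draws: int = EXACT_DRAWS,
) -> tuple[int | None, list[AssociationTestResult]]:
    try:
        scores = logrank_scores(time, event)
    except ValueError:
        return None, []
    if scores.variance <= 0:
        return None, []
    a = scores.scores
    tested: list[tuple[int, float, float]] = []
    for j in candidate_positions:
        arr, kind = cols.arrays[j], cols.kinds[j]
        kind = "polytomous" if kind == "polytomous" else "numeric"
        if np.unique(arr).size <= 1:
            continue
        try:
            c, p = _rank_test_arrays(arr, kind, a, rng, exact_node_size, exact_draws)
        except ValueError:
            continue
        tested.append((j, c, p))
    if not tested:
        return None, []
    m = len(tested)
    results = [
        AssociationTestResult(cols.names[j], c, p, min(1.0, p * m))
        for j, c, p in tested
    ]
    # select on the raw p-value: the Bonferroni map p -> min(1, m*p) is
    # monotone but its clipping at 1 would create artificial ties that a
    # positional tie-break could turn into selection bias
    k = int(np.argmin([r.p_value for r in results]))
    if results[k].adjusted_p <= alpha:
        return tested[k][0], results
    return None, results


def select_split_variable(
    node_data: SurvivalDataset,
    alpha: float = 0.05,
    candidate_vars: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str | None, list[AssociationTestResult]]:
    """Test every candidate covariate, Bonferroni-adjust, pick the minimum.

    Returns ``(variable, results)``; variable is None (stop signal) when no
    adjusted p-value reaches ``alpha`` or no covariate is testable.
    """
    cols = ColumnSet.from_frame(node_data.covariates, node_data.kinds)
    if candidate_vars is None:
        candidate_vars = list(cols.names)
    positions = [cols.names.index(v) for v in candidate_vars]
    j, results = _select_arrays(
        node_data.time, node_data.event, cols, positions, alpha, rng
    )
    return (cols.names[j] if j is not None else None), results


def _grow_ctree_arrays(
    time: np.ndarray,
    event: np.ndarray,
    cols: ColumnSet,
    alpha: float,
    mtry: int | None,
    min_node_size: int,
    min_events: int,
    rng: np.random.Generator,
) -> SurvivalTree:
    n = time.size
    if n == 0:
        raise ValueError("empty dataset")
    p = cols.n_cols
    if mtry is None:
        mtry = p  # a single conditional tree tests every covariate
    mtry = min(max(1, mtry), p)
    counter = itertools.count()

    def build(idx: np.ndarray) -> TreeNode:
        node = TreeNode(node_id=next(counter), members=idx)
        n_events = int(event[idx].sum())
        if idx.size >= 2 * min_node_size and n_events >= 2 * min_events:
            cand = sorted(rng.choice(p, size=mtry, replace=False).tolist())
            sub_cols = cols.take(idx)
            t_sub, e_sub = time[idx], event[idx]
            j, _ = _select_arrays(t_sub, e_sub, sub_cols, cand, alpha, rng)
            if j is not None:
                split = _best_split_arrays(
                    t_sub, e_sub, sub_cols, [j], "logrank_score", min_events
                )
                if split is not None:
                    mask = split.left_mask_codes(
                        sub_cols.arrays[j], sub_cols.cats[j]
                    )
                    node.split = split
                    node.left = build(idx[mask])
                    node.right = build(idx[~mask])
                    return node
        node.curve = kaplan_meier(time[idx], event[idx])
        return node

    root = build(np.arange(n))
    return SurvivalTree(
        root=root,
        rule="cif",
        mtry=mtry,
        min_node_size=min_node_size,
        min_events=min_events,
        time=time,
        event=event,
        cols=cols,
    )


def grow_ctree(
    data: SurvivalDataset,
    alpha: float = 0.05,
    mtry: int | None = None,
    min_node_size: int = 15,
    min_events: int = 3,
    rng: np.random.Generator | int | None = None,
) -> SurvivalTree:
    """Grow one conditional inference survival tree.

    Recursion at each node: draw mtry candidate covariates, select the
    split variable by the adjusted association test (stop on
    non-rejection), then find the best binary split point on that variable
    by maximizing the two-sample linear rank statistic on the node's
    log-rank scores.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cols = ColumnSet.from_frame(data.covariates, data.kinds)
    return _grow_ctree_arrays(
        data.time, data.event, cols, alpha, mtry, min_node_size, min_events, rng
    )


def fit_cif(
    data: SurvivalDataset,
    n_trees: int = 100,
    alpha: float = 1.0,
    mtry: int | None = None,
    min_node_size: int = 10,
    min_events: int = 2,
    subsample_fraction: float = 0.632,
    seed: int = 0,
) -> Forest:
    """Fit a conditional inference forest on subsamples without replacement.

    Within a forest the trees are grown without the p-value stopping rule
    (``alpha=1``): every node still selects its split variable by the
    minimum adjusted p-value — keeping variable selection unbiased — but
    recursion is limited by node size only, mirroring the reference
    conditional-forest defaults (single interpretable trees use
    ``alpha=0.05``; pass it explicitly to restore early stopping). The
    node-size floors are likewise the conditional-forest ones (a node
    needs 2 * min_node_size = 20 subjects of the subsample to be split),
    slightly smaller than the RSF defaults because conditional trees see a
    0.632-subsample where RSF trees see a size-N bootstrap, and the
    default candidate draw is the conditional-forest constant mtry = 5.
    """
    if data.event.sum() == 0:
        raise ValueError("dataset contains no events")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if mtry is None:
        mtry = 5  # reference conditional-forest default
    n = data.n
    m = max(2, int(round(subsample_fraction * n)))
    if m >= n:
        warnings.warn("subsample_fraction leaves no out-of-bag subjects")
        m = n
    cols = ColumnSet.from_frame(data.covariates, data.kinds)
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(n_trees)
    trees: list[SurvivalTree] = []
    in_bag: list[np.ndarray] = []
    oob: list[np.ndarray] = []
    for b in range(n_trees):
        rng = np.random.default_rng(tree_seeds[b])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        if data.event[idx].sum() == 0:
            idx = np.arange(n)
        tree = _grow_ctree_arrays(
            data.time[idx],
            data.event[idx],
            cols.take(idx),
            alpha,
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
        rule="cif",
        n_trees=n_trees,
        seed=seed,
        data=data,
        params=dict(
            alpha=alpha,
            mtry=mtry,
            min_node_size=min_node_size,
            min_events=min_events,
            subsample_fraction=subsample_fraction,
        ),
    )


def _cif_weights(
    forest: Forest, X: pd.DataFrame | ColumnSet, oob_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(query, training-subject) co-membership weights.

    weight[q, i] = number of trees in which training subject i shares the
    terminal node query q is routed to. Terminals holding many subjects at
    risk therefore contribute more total weight to the ensemble
    Kaplan-Meier, which is the aggregation behaviour of the reference
    conditional-forest implementation. With ``oob_only`` (training
    queries, rows aligned with the training data) only trees where the
    query row is out-of-bag contribute; the second return value counts
    contributing trees per query.
    """
    cols = (
        X if isinstance(X, ColumnSet) else ColumnSet.from_frame(X, forest.data.kinds)
    )
    n_train = forest.data.n
    nq = cols.arrays[0].shape[0]
    w = np.zeros((nq, n_train))
    n_used = np.zeros(nq)
    for tree, bag, oob_idx in zip(forest.trees, forest.in_bag, forest.oob):
        allowed = np.zeros(nq, dtype=bool)
        if oob_only:
            allowed[oob_idx[oob_idx < nq]] = True
            if not allowed.any():
                continue
        else:
            allowed[:] = True
        leaf_ids = tree.apply(cols)
        for leaf in tree.leaves():
            rows = np.flatnonzero((leaf_ids == leaf.node_id) & allowed)
            if rows.size == 0:
                continue
            orig = bag[leaf.members]  # subsample indices -> training rows
            w[np.ix_(rows, orig)] += 1.0
        n_used += allowed
    return w, n_used


def predict_cif_survival(
    forest: Forest, x_new: pd.DataFrame, eval_times
) -> np.ndarray:
    """Weighted Kaplan-Meier ensemble prediction over the training set."""
    grid = np.asarray(eval_times, dtype=float)
    w, _ = _cif_weights(forest, x_new)
    return weighted_kaplan_meier(forest.data.time, forest.data.event, w, grid)
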