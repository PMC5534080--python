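"""Survival trees by recursive binary partitioning of right-censored data.

Two split rules are implemented:

* ``logrank`` — the standardized two-sample log-rank statistic between the
  candidate daughter nodes (observed minus expected events over the pooled
  event times, divided by the square root of the hypergeometric variance);
  the squared statistic is maximized.

* ``logrank_score`` — the linear rank statistic on per-subject log-rank
  scores

      a_l = delta_l - sum_{k=1}^{gamma_l} delta_k / (N - gamma_k + 1),

  where gamma_l counts subjects with observed time <= T_l (events ordered
  before censorings at ties). For a candidate left group of size R1 the
  statistic is

      i = (sum_{left} a_j - R1 * abar) / sqrt(R1 (1 - R1/N) S_a^2)

  with abar, S_a^2 the node-level mean and (N-1)-denominator sample
  variance of the scores; |i| is maximized.

Binary and continuous covariates split as X <= c; unordered categorical
covariates split on level subsets, searched exhaustively (up to 8 levels).
Terminal nodes carry the Kaplan-Meier curve of their member subjects.

Internally covariates are held as plain numpy arrays (float values for
ordered columns, integer level codes for categorical ones) so the
recursion never touches pandas objects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .curves import SurvivalCurve, product_limit
from .datagen import SurvivalDataset

MAX_SUBSET_LEVELS = 8


class ZeroEventsError(ValueError):
    """Statistic undefined: the compared groups contain no events."""


class DegenerateScoresError(ValueError):
    """Statistic undefined: all log-rank scores in the node are equal."""


# ---------------------------------------------------------------------------
# numpy column store


@dataclass
class ColumnSet:
    """Covariate matrix as per-column numpy arrays.

    Ordered columns (binary / continuous) are float arrays; polytomous
    columns are integer code arrays with the level labels kept in ``cats``.
    """

    names: list[str]
    kinds: list[str]
    arrays: list[np.ndarray]
    cats: list[pd.Index | None]

    @classmethod
    def from_frame(cls, X: pd.DataFrame, kinds: dict[str, str]) -> "ColumnSet":
        names, ks, arrays, cats = [], [], [], []
        for c in X.columns:
            col = X[c]
            kind = kinds.get(c, "continuous")
            if isinstance(col.dtype, pd.CategoricalDtype):
                arrays.append(col.cat.codes.to_numpy().astype(np.int64))
                cats.append(col.cat.categories)
                kind = "polytomous"
            else:
                arrays.append(col.to_numpy(dtype=float))
                cats.append(None)
            names.append(c)
            ks.append(kind)
        return cls(names, ks, arrays, cats)

    def take(self, idx: np.ndarray) -> "ColumnSet":
        return ColumnSet(
            self.names, self.kinds, [a[idx] for a in self.arrays], self.cats
        )

    @property
    def n_cols(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# statistics


def _logrank_precompute(time: np.ndarray, event: np.ndarray):
    """Node-level quantities of the log-rank statistic, shared across all
    candidate splits of the node: time ordering, distinct-event-time risk
    sets Y and event counts d."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    n = t.size
    _, first_idx = np.unique(t, return_index=True)
    Y_all = n - first_idx
    d_all = np.add.reduceat(d, first_idx)
    keep = d_all > 0
    return order, d, first_idx, Y_all[keep], d_all[keep], keep


def _logrank_terms_pre(pre, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(O1-E1, V) per left-mask (S x n), given node precomputation."""
    order, d, first_idx, Y, d_k, keep = pre
    if Y.size == 0:
        return np.zeros(masks.shape[0]), np.zeros(masks.shape[0])
    m = masks[:, order]
    fi = first_idx[keep]
    rev_cum_m = np.cumsum(m[:, ::-1], axis=1)[:, ::-1]
    Y1 = rev_cum_m[:, fi]
    d1 = np.add.reduceat(m * d, first_idx, axis=1)[:, keep]
    frac = Y1 / Y
    o_minus_e = np.sum(d1 - d_k * frac, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d_k * frac * (1 - frac) * (Y - d_k) / np.where(Y > 1, Y - 1, 1)
    v_terms = np.where(Y > 1, v_terms, 0.0)
    return o_minus_e, np.sum(v_terms, axis=1)


def _logrank_terms(
    time: np.ndarray, event: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(O1-E1, V) of the two-sample log-rank for each left-mask (S x n)."""
    return _logrank_terms_pre(_logrank_precompute(time, event), masks)


def logrank_statistic(time, event, membership) -> float:
    """Standardized two-sample log-rank statistic (O1 - E1) / sqrt(V).

    ``membership`` is a boolean mask selecting group 1. Symmetric in the
    group labels up to sign; the squared value is the usual chi-square(1)
    statistic.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(membership, dtype=bool)
    if not g1.any() or g1.all():
        raise ValueError("both groups must be non-empty")
    if event.sum() == 0:
        raise ZeroEventsError("no events: log-rank statistic undefined")
    o_minus_e, var = _logrank_terms(time, event, g1[None, :])
    if var[0] <= 0:
        raise ZeroEventsError("zero variance: log-rank statistic undefined")
    return float(o_minus_e[0] / np.sqrt(var[0]))


@dataclass(frozen=True)
class LogrankScores:
    """Per-subject log-rank scores of a node."""

    scores: np.ndarray
    ranks: np.ndarray  # gamma_l: number of observed times <= T_l (tie-aware)
    at_risk_counts: np.ndarray
    mean: float
    variance: float  # sample variance, N-1 denominator


def logrank_scores(time, event) -> LogrankScores:
    """Log-rank scores a_l for every subject.

    Events are ordered before censorings at tied times; gamma is the rank
    of the last member of each tie class on that ordering, so tied subjects
    of the same status receive identical scores. For fully uncensored data
    with distinct times the scores sum to zero.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    n = time.size
    order = np.lexsort((1 - event, time))
    t_s = time[order]
    d_s = event[order]
    new_class = np.ones(n, dtype=bool)
    new_class[1:] = (t_s[1:] != t_s[:-1]) | (d_s[1:] != d_s[:-1])
    class_id = np.cumsum(new_class) - 1
    n_classes = class_id[-1] + 1
    last_pos = np.zeros(n_classes, dtype=int)
    np.maximum.at(last_pos, class_id, np.arange(n))
    gamma_sorted = last_pos[class_id] + 1
    terms = d_s / (n - gamma_sorted + 1.0)
    cum_terms = np.cumsum(terms)
    a_sorted = d_s - cum_terms[last_pos[class_id]]
    scores = np.empty(n)
    scores[order] = a_sorted
    gamma = np.empty(n, dtype=int)
    gamma[order] = gamma_sorted
    return LogrankScores(
        scores=scores,
        ranks=gamma,
        at_risk_counts=n - gamma + 1,
        mean=float(scores.mean()),
        variance=float(scores.var(ddof=1)) if n > 1 else 0.0,
    )


def logrank_score_statistic(scores: LogrankScores, left_mask) -> float:
    """|i| for a candidate left group, given node-level log-rank scores."""
    left = np.asarray(left_mask, dtype=bool)
    n = scores.scores.size
    r1 = int(left.sum())
    if r1 == 0 or r1 == n:
        raise ValueError("improper split: both groups must be non-empty")
    if scores.variance <= 0:
        raise DegenerateScoresError("all scores equal: statistic undefined")
    num = scores.scores[left].sum() - r1 * scores.mean
    den = np.sqrt(r1 * (1 - r1 / n) * scores.variance)
    return abs(float(num / den))


# ---------------------------------------------------------------------------
# split search


@dataclass(frozen=True)
class SplitCandidate:
    variable: str
    kind: str  # "binary" | "continuous" | "polytomous"
    threshold: float | None  # ordered split X <= threshold
    left_levels: frozenset | None  # categorical split X in left_levels
    statistic: float
    left_size: int
    seen_levels: frozenset | None = None  # levels observed in the training node
    # fast-path integer codes, valid only for the categories object the
    # split was created against (held in _cats_ref)
    left_codes: tuple = ()
    seen_codes: tuple = ()
    _cats_ref: object = None

    def _code_table(self, cats: pd.Index, levels: frozenset, codes: tuple) -> np.ndarray:
        """code -> membership lookup, cached per categories object."""
        cache = self.__dict__.setdefault("_table_cache", {})
        key = (id(cats), id(levels))
        table = cache.get(key)
        if table is None:
            table = np.zeros(len(cats) + 1, dtype=bool)
            if cats is self._cats_ref and codes:
                table[list(codes)] = True
            else:
                idx = cats.get_indexer(list(levels))
                table[idx[idx >= 0]] = True
            cache[key] = table
        return table

    def left_mask_codes(self, arr: np.ndarray, cats: pd.Index | None) -> np.ndarray:
        """Left mask from a ColumnSet array (codes or floats)."""
        if self.left_levels is not None:
            # code -1 (unseen) hits the trailing False slot
            return self._code_table(cats, self.left_levels, self.left_codes)[arr]
        return arr <= self.threshold

    def left_mask(self, column: pd.Series) -> np.ndarray:
        if isinstance(column.dtype, pd.CategoricalDtype):
            return self.left_mask_codes(
                column.cat.codes.to_numpy(), column.cat.categories
            )
        return self.left_mask_codes(column.to_numpy(dtype=float), None)


@lru_cache(maxsize=32)
def _subset_matrix(n_levels: int) -> np.ndarray:
    """All two-block partitions of {0..L-1} as left-subset indicator rows.

    Canonical enumeration: proper subsets containing level 0, by growing
    size then lexicographic order.
    """
    rows = []
    for r in range(0, n_levels - 1):
        for combo in itertools.combinations(range(1, n_levels), r):
            v = np.zeros(n_levels, dtype=bool)
            v[0] = True
            v[list(combo)] = True
            rows.append(v)
    return np.array(rows)


def _enumerate_splits(arr: np.ndarray, kind: str):
    """Candidate left masks for one covariate plus descriptor metadata.

    Returns (masks S x n, thresholds or None, (subset_matrix, observed
    codes) or None). Ordered covariates yield X <= v for each interior
    unique value; unordered categorical ones each two-block level partition
    once.
    """
    if kind == "polytomous":
        counts = np.bincount(arr[arr >= 0])
        observed = np.flatnonzero(counts > 0)
        if observed.size > MAX_SUBSET_LEVELS:
            raise ValueError(
                f"categorical covariate with {observed.size} observed levels "
                f"exceeds the exhaustive subset-search limit of {MAX_SUBSET_LEVELS}"
            )
        if observed.size < 2:
            return None, None, None
        level_ind = arr[None, :] == observed[:, None]
        SM = _subset_matrix(observed.size)
        masks = (SM.astype(np.uint8) @ level_ind.astype(np.uint8)) > 0
        return masks, None, (SM, observed)
    vals = np.unique(arr)
    if vals.size < 2:
        return None, None, None
    thresholds = vals[:-1]
    masks = arr[None, :] <= thresholds[:, None]
    return masks, thresholds, None


def _candidate_left_masks(
    arr: np.ndarray, kind: str, cats: pd.Index | None
) -> list[tuple[np.ndarray, float | None, frozenset | None]]:
    """Candidate left groups with explicit descriptors (inspection helper)."""
    masks, thresholds, subset_meta = _enumerate_splits(arr, kind)
    if masks is None:
        return []
    out = []
    for k in range(masks.shape[0]):
        if thresholds is not None:
            out.append((masks[k], float(thresholds[k]), None))
        else:
            SM, observed = subset_meta
            subset = frozenset(cats[c] for c in observed[SM[k]])
            out.append((masks[k], None, subset))
    return out


def _best_split_arrays(
    time: np.ndarray,
    event: np.ndarray,
    cols: ColumnSet,
    candidate_positions: list[int],
    rule: str,
    min_events: int,
) -> SplitCandidate | None:
    n = time.size
    total_events = int(event.sum())
    scores = None
    lr_pre = None
    if rule == "logrank_score":
        try:
            scores = logrank_scores(time, event)
        except ValueError:
            return None
        if scores.variance <= 0:
            return None
    elif rule != "logrank":
        raise ValueError(f"unknown split rule {rule!r}")
    best: SplitCandidate | None = None
    for j in candidate_positions:
        arr, kind, cats = cols.arrays[j], cols.kinds[j], cols.cats[j]
        masks, thresholds, subset_meta = _enumerate_splits(arr, kind)
        if masks is None:
            continue
        r1 = masks.sum(axis=1)
        ev_left = masks @ event
        admissible = (
            (r1 > 0)
            & (r1 < n)
            & (ev_left >= min_events)
            & (total_events - ev_left >= min_events)
        )
        if not admissible.any():
            continue
        if rule == "logrank":
            if lr_pre is None:
                lr_pre = _logrank_precompute(time, event)
            o_minus_e, var_hat = _logrank_terms_pre(lr_pre, masks)
            with np.errstate(invalid="ignore", divide="ignore"):
                stat = np.where(
                    var_hat > 0,
                    o_minus_e**2 / np.where(var_hat > 0, var_hat, 1.0),
                    np.nan,
                )
        else:
            num = masks @ scores.scores - r1 * scores.mean
            with np.errstate(invalid="ignore", divide="ignore"):
                den = np.sqrt(r1 * (1 - r1 / n) * scores.variance)
                stat = np.where(den > 0, np.abs(num) / np.where(den > 0, den, 1.0), np.nan)
        stat = np.where(admissible & np.isfinite(stat), stat, -np.inf)
        k = int(np.argmax(stat))  # first maximum: canonical-order tie-break
        if stat[k] == -np.inf:
            continue
        if best is None or stat[k] > best.statistic + 1e-12:
            threshold = subset = seen = None
            left_codes = seen_codes = ()
            if thresholds is not None:
                threshold = float(thresholds[k])
            else:
                SM, observed = subset_meta
                left_codes = tuple(int(c) for c in observed[SM[k]])
                seen_codes = tuple(int(c) for c in observed)
                subset = frozenset(cats[c] for c in left_codes)
                seen = frozenset(cats[c] for c in seen_codes)
            best = SplitCandidate(
                variable=cols.names[j],
                kind=kind,
                threshold=threshold,
                left_levels=subset,
                statistic=float(stat[k]),
                left_size=int(r1[k]),
                seen_levels=seen,
                left_codes=left_codes,
                seen_codes=seen_codes,
                _cats_ref=cats,
            )
    return best


def best_split(
    node_data: SurvivalDataset,
    candidate_vars: list[str],
    rule: str,
    min_node_size: int = 15,
    min_events: int = 3,
    rng: np.random.Generator | None = None,
) -> SplitCandidate | None:
    """Best admissible split over the candidate variables under ``rule``.

    Admissibility: both children non-empty and each containing at least
    ``min_events`` events. Ties in the statistic break to the earlier
    variable in ``candidate_vars`` order, then the earlier split in
    canonical enumeration order. Returns None when no admissible split
    exists.
    """
    if not candidate_vars:
        raise ValueError("candidate_vars must not be empty")
    cols = ColumnSet.from_frame(node_data.covariates, node_data.kinds)
    positions = [cols.names.index(v) for v in candidate_vars]
    return _best_split_arrays(
        node_data.time, node_data.event, cols, positions, rule, min_events
    )


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    node_id: int
    members: np.ndarray  # indices into the training data
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    curve: SurvivalCurve | None = None  # terminal Kaplan-Meier

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class SurvivalTree:
    root: TreeNode
    rule: str
    mtry: int
    min_node_size: int
    min_events: int
    time: np.ndarray = field(repr=False, default=None)
    event: np.ndarray = field(repr=False, default=None)
    cols: ColumnSet = field(repr=False, default=None)

    @property
    def kinds(self) -> dict[str, str]:
        return dict(zip(self.cols.names, self.cols.kinds))

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def apply(self, X: pd.DataFrame | ColumnSet) -> np.ndarray:
        """Leaf node id for every row of X (vectorized routing).

        Categorical levels unseen in a split's training node follow the
        child with more training subjects.
        """
        cols = (
            X
            if isinstance(X, ColumnSet)
            else ColumnSet.from_frame(X, self.kinds)
        )
        n = cols.arrays[0].shape[0]
        leaf_of = np.full(n, -1, dtype=int)
        stack: list[tuple[TreeNode, np.ndarray]] = [(self.root, np.arange(n))]
        name_pos = {nm: i for i, nm in enumerate(cols.names)}
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf:
                leaf_of[idx] = node.node_id
                continue
            j = name_pos[node.split.variable]
            arr = cols.arrays[j][idx]
            mask = node.split.left_mask_codes(arr, cols.cats[j])
            if node.split.left_levels is not None and node.split.seen_levels:
                seen_table = node.split._code_table(
                    cols.cats[j], node.split.seen_levels, node.split.seen_codes
                )
                unseen = ~seen_table[arr]
                if unseen.any():
                    bigger_left = node.left.members.size >= node.right.members.size
                    mask = np.where(unseen, bigger_left, mask)
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
        return leaf_of

    def to_text(self) -> str:
        """Line-oriented serialization: one line per node."""
        lines: list[str] = []

        def walk(node: TreeNode, depth: int) -> None:
            indent = "  " * depth
            if node.is_leaf:
                knots = " ".join(
                    f"{t:.6g}:{v:.6g}"
                    for t, v in zip(node.curve.knots, node.curve.values)
                )
                lines.append(
                    f"{indent}leaf id={node.node_id} n={node.members.size} km=[{knots}]"
                )
            else:
                s = node.split
                desc = (
                    f"{s.variable} in {sorted(s.left_levels)}"
                    if s.left_levels is not None
                    else f"{s.variable} <= {s.threshold:.6g}"
                )
                lines.append(
                    f"{indent}node id={node.node_id} n={node.members.size} "
                    f"split=({desc}) stat={s.statistic:.6g}"
                )
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines) + "\n"


def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit estimate of the event survival function S(t)."""
    return product_limit(time, event, reverse=False)


def _grow_tree_arrays(
    time: np.ndarray,
    event: np.ndarray,
    cols: ColumnSet,
    rule: str,
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
        mtry = int(np.ceil(np.sqrt(p)))
    mtry = min(max(1, mtry), p)
    if event.sum() == 0:
        warnings.warn("all subjects censored: returning a root-only tree")
    counter = itertools.count()

    def build(idx: np.ndarray) -> TreeNode:
        node = TreeNode(node_id=next(counter), members=idx)
        n_events = int(event[idx].sum())
        if idx.size >= 2 * min_node_size and n_events >= 2 * min_events:
            cand = sorted(rng.choice(p, size=mtry, replace=False).tolist())
            sub_cols = cols.take(idx)
            split = _best_split_arrays(
                time[idx], event[idx], sub_cols, cand, rule, min_events
            )
            if split is not None:
                j = cols.names.index(split.variable)
                mask = split.left_mask_codes(sub_cols.arrays[j], sub_cols.cats[j])
                node.split = split
                node.left = build(idx[mask])
                node.right = build(idx[~mask])
                return node
        node.curve = kaplan_meier(time[idx], event[idx])
        return node

    root = build(np.arange(n))
    return SurvivalTree(
        root=root,
        rule=rule,
        mtry=mtry,
        min_node_size=min_node_size,
        min_events=min_events,
        time=time,
        event=event,
        cols=cols,
    )


def grow_tree(
    data: SurvivalDataset,
    rule: str = "logrank",
    mtry: int | None = None,
    min_node_size: int = 15,
    min_events: int = 3,
    rng: np.random.Generator | int | None = None,
) -> SurvivalTree:
    """Grow one survival tree by recursive binary partitioning.

    At each node ``mtry`` covariates are drawn without replacement as split
    candidates (default ceil(sqrt(p))). A node is terminal when it has
    fewer than ``2 * min_node_size`` subjects, fewer than
    ``2 * min_events`` events, or no admissible split among the sampled
    candidates.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cols = ColumnSet.from_frame(data.covariates, data.kinds)
    return _grow_tree_arrays(
        data.time, data.event, cols, rule, mtry, min_node_size, min_events, rng
    )
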