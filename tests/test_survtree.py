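"""Split statistics and tree growth, checked against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as ll_logrank_test

import survforest as sf
from survforest.survtree import (
    DegenerateScoresError,
    ZeroEventsError,
    grow_tree,
)

from conftest import make_dataset, random_censored_data


# ---------------------------------------------------------------------------
# independent oracles


def logrank_oracle(time, event, g1):
    """Two-sample log-rank by direct summation over pooled event times."""
    time, event, g1 = map(np.asarray, (time, event, g1))
    o_minus_e, var = 0.0, 0.0
    for tk in np.unique(time[event == 1]):
        at_risk = time >= tk
        Y, Y1 = at_risk.sum(), (at_risk & g1).sum()
        d = ((time == tk) & (event == 1)).sum()
        d1 = ((time == tk) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * Y1 / Y
        if Y > 1:
            var += d * (Y1 / Y) * (1 - Y1 / Y) * (Y - d) / (Y - 1)
    return o_minus_e / np.sqrt(var)


def scores_oracle(time, event):
    """Log-rank scores by literal evaluation of the defining sum."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    n = time.size
    order = np.lexsort((1 - event, time))
    t_s, d_s = time[order], event[order]
    # gamma_l: count of (time, status-ordered) positions <= l's tie class
    a = np.empty(n)
    for li in range(n):
        gamma_l = sum(
            1
            for k in range(n)
            if (t_s[k], 1 - d_s[k]) <= (t_s[li], 1 - d_s[li])
        )
        s = 0.0
        for k in range(gamma_l):
            gamma_k = sum(
                1
                for m in range(n)
                if (t_s[m], 1 - d_s[m]) <= (t_s[k], 1 - d_s[k])
            )
            s += d_s[k] / (n - gamma_k + 1)
        a[li] = d_s[li] - s
    out = np.empty(n)
    out[order] = a
    return out


# ---------------------------------------------------------------------------
# log-rank statistic


class TestLogrankStatistic:
    def test_matches_hand_summation_oracle(self):
        time = [1, 2, 3, 4]
        event = [1, 1, 1, 1]
        g1 = [True, True, False, False]
        ours = sf.logrank_statistic(time, event, g1)
        assert np.isclose(ours, logrank_oracle(time, event, g1))

    def test_matches_lifelines_chi2(self, rng):
        time, event = random_censored_data(rng, n=60)
        g1 = rng.random(60) < 0.5
        ours = sf.logrank_statistic(time, event, g1) ** 2
        ref = ll_logrank_test(time[g1], time[~g1], event[g1], event[~g1])
        assert np.isclose(ours, ref.test_statistic, rtol=1e-10)

    def test_identical_groups_give_zero(self):
        time = [1.0, 1.0, 2.5, 2.5, 4.0, 4.0]
        event = [1, 1, 0, 0, 1, 1]
        g1 = [True, False, True, False, True, False]
        assert abs(sf.logrank_statistic(time, event, g1)) < 1e-12

    def test_sign_flips_with_group_labels(self, rng):
        time, event = random_censored_data(rng, n=40)
        g1 = rng.random(40) < 0.4
        a = sf.logrank_statistic(time, event, g1)
        b = sf.logrank_statistic(time, event, ~g1)
        assert np.isclose(a, -b)

    def test_no_events_signalled_distinctly(self):
        with pytest.raises(ZeroEventsError):
            sf.logrank_statistic([1, 2], [0, 0], [True, False])

    def test_null_squared_statistic_is_chi2_1(self):
        rng = np.random.default_rng(99)
        stats = []
        for _ in range(500):
            time, event = random_censored_data(rng, n=200)
            g1 = rng.random(200) < 0.5
            stats.append(sf.logrank_statistic(time, event, g1) ** 2)
        from scipy import stats as sps

        _, p = sps.kstest(stats, sps.chi2(df=1).cdf)
        assert p > 0.01


# ---------------------------------------------------------------------------
# log-rank scores


class TestLogrankScores:
    def test_three_uncensored_subjects_hand_values(self):
        res = sf.logrank_scores([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(res.scores, [2 / 3, 1 / 6, -5 / 6])
        assert abs(res.scores.sum()) < 1e-12

    def test_single_censored_subject_scores_zero(self):
        res = sf.logrank_scores([5.0], [0])
        assert res.scores[0] == 0.0

    def test_matches_literal_oracle_with_ties_and_censoring(self, rng):
        time = rng.integers(1, 6, size=12).astype(float)  # forced ties
        event = rng.integers(0, 2, size=12)
        assert np.allclose(sf.logrank_scores(time, event).scores,
                           scores_oracle(time, event))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=25, unique=True))
    def test_uncensored_distinct_scores_sum_to_zero(self, times):
        res = sf.logrank_scores(times, [1] * len(times))
        assert abs(res.scores.sum()) < 1e-9

    def test_rank_based_invariance_under_monotone_time_transform(self, rng):
        time, event = random_censored_data(rng, n=30)
        a = sf.logrank_scores(time, event).scores
        b = sf.logrank_scores(np.exp(time), event).scores
        assert np.allclose(a, b)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sf.logrank_scores([-1.0, 2.0], [1, 1])


class TestLogrankScoreStatistic:
    def test_hand_evaluation_on_three_subject_fixture(self):
        res = sf.logrank_scores([1.0, 2.0, 3.0], [1, 1, 1])
        # scores (2/3, 1/6, -5/6): abar = 0, S^2 = (4/9+1/36+25/36)/2 = 7/12
        left = np.array([True, False, False])
        expected = (2 / 3) / np.sqrt(1 * (1 - 1 / 3) * 7 / 12)
        assert np.isclose(sf.logrank_score_statistic(res, left), expected)

    def test_improper_split_rejected(self):
        res = sf.logrank_scores([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError):
            sf.logrank_score_statistic(res, [True, True, True])

    def test_degenerate_scores_signalled(self):
        res = sf.logrank_scores([3.0, 3.0], [0, 0])
        with pytest.raises(DegenerateScoresError):
            sf.logrank_score_statistic(res, [True, False])

    def test_relabeling_invariance(self, rng):
        time, event = random_censored_data(rng, n=20)
        res = sf.logrank_scores(time, event)
        left = rng.random(20) < 0.5
        perm = rng.permutation(20)
        res_p = sf.logrank_scores(time[perm], event[perm])
        assert np.isclose(
            sf.logrank_score_statistic(res, left),
            sf.logrank_score_statistic(res_p, left[perm]),
        )


# ---------------------------------------------------------------------------
# best split vs exhaustive search


def brute_force_best(data, rule, min_events=1):
    """Enumerate every variable and every two-block partition directly."""
    best_stat, best = -np.inf, None
    scores = None
    if rule == "logrank_score":
        scores = sf.logrank_scores(data.time, data.event)
    for var in data.covariates.columns:
        col = data.covariates[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            lv = [c for c in col.cat.categories if (col == c).any()]
            partitions = []
            for r in range(1, len(lv)):
                for combo in itertools.combinations(lv, r):
                    if lv[0] in combo:  # each partition once
                        partitions.append(col.isin(combo).to_numpy())
        else:
            vals = np.unique(col.to_numpy(float))
            partitions = [col.to_numpy(float) <= v for v in vals[:-1]]
        for mask in partitions:
            if mask.all() or not mask.any():
                continue
            ev_l, ev_r = data.event[mask].sum(), data.event[~mask].sum()
            if ev_l < min_events or ev_r < min_events:
                continue
            try:
                if rule == "logrank":
                    stat = sf.logrank_statistic(data.time, data.event, mask) ** 2
                else:
                    stat = sf.logrank_score_statistic(scores, mask)
            except ValueError:
                continue
            if stat > best_stat + 1e-12:
                best_stat, best = stat, (var, mask)
    return best_stat, best


def random_fixture(rng, n):
    time = np.round(rng.exponential(1.0, n), 2) + 0.01
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    cov = pd.DataFrame(
        {
            "b": rng.integers(0, 2, n),
            "u": np.round(rng.random(n), 2),
            "c": pd.Categorical(
                rng.choice(list("vwxyz"), n), categories=list("vwxyz")
            ),
        }
    )
    return sf.SurvivalDataset(time, event, cov,
                              {"b": "binary", "u": "continuous", "c": "polytomous"})


class TestBestSplit:
    @pytest.mark.parametrize("rule", ["logrank", "logrank_score"])
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_search_on_small_fixtures(self, rule, seed):
        rng = np.random.default_rng(seed)
        data = random_fixture(rng, n=rng.integers(6, 13))
        oracle_stat, _ = brute_force_best(data, rule)
        found = sf.best_split(
            data, list(data.covariates.columns), rule, min_node_size=1, min_events=1
        )
        if oracle_stat == -np.inf:
            assert found is None
        else:
            assert found is not None
            assert np.isclose(found.statistic, oracle_stat, rtol=1e-9)

    def test_perfectly_separating_binary_covariate_selected(self, ten_subject_fixture):
        # all events fall on one side, so the per-child event floor must be 0
        found = sf.best_split(
            ten_subject_fixture, ["signal", "noise"], "logrank",
            min_node_size=1, min_events=0,
        )
        assert found.variable == "signal"

    def test_constant_covariates_yield_no_split(self):
        data = make_dataset([1, 2, 3, 4], [1, 1, 1, 0], {"x": [1, 1, 1, 1]})
        assert sf.best_split(data, ["x"], "logrank", 1, 1) is None

    def test_five_level_subset_matches_enumeration(self):
        rng = np.random.default_rng(42)
        n = 12
        time = rng.exponential(1, n)
        event = np.ones(n, dtype=int)
        cov = pd.DataFrame(
            {"c": pd.Categorical(rng.choice(list("abcde"), n),
                                 categories=list("abcde"))}
        )
        data = sf.SurvivalDataset(time, event, cov, {"c": "polytomous"})
        oracle_stat, _ = brute_force_best(data, "logrank")
        found = sf.best_split(data, ["c"], "logrank", 1, 1)
        assert np.isclose(found.statistic, oracle_stat, rtol=1e-9)

    def test_too_many_levels_refused(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = [f"L{i}" for i in range(9)]
        cov = pd.DataFrame(
            {"c": pd.Categorical(rng.choice(labels, n), categories=labels)}
        )
        data = sf.SurvivalDataset(
            rng.exponential(1, n), np.ones(n, int), cov, {"c": "polytomous"}
        )
        with pytest.raises(ValueError, match="subset-search limit"):
            sf.best_split(data, ["c"], "logrank", 1, 1)


# ---------------------------------------------------------------------------
# tree growth


class TestGrowTree:
    def test_large_min_node_size_gives_root_only_tree(self, binary_data2):
        tree = grow_tree(binary_data2, min_node_size=10**6, rng=0)
        assert tree.root.is_leaf
        km = sf.kaplan_meier(binary_data2.time, binary_data2.event)
        grid = np.linspace(0, binary_data2.time.max(), 20)
        assert np.allclose(tree.root.curve(grid), km(grid))

    def test_terminal_members_partition_training_set(self, binary_data2):
        tree = grow_tree(binary_data2, min_node_size=5, min_events=1, rng=1)
        members = np.concatenate([lf.members for lf in tree.leaves()])
        assert np.array_equal(np.sort(members), np.arange(binary_data2.n))

    def test_deterministic_replay(self, binary_data2):
        t1 = grow_tree(binary_data2, rule="logrank_score", rng=7)
        t2 = grow_tree(binary_data2, rule="logrank_score", rng=7)
        assert t1.to_text() == t2.to_text()

    def test_apply_routes_training_data_to_own_leaves(self, poly_small):
        tree = grow_tree(poly_small, min_node_size=8, min_events=1, rng=3)
        leaf_ids = tree.apply(poly_small.covariates)
        for leaf in tree.leaves():
            assert np.array_equal(
                np.flatnonzero(leaf_ids == leaf.node_id), np.sort(leaf.members)
            )

    def test_all_censored_warns_and_returns_flat_root(self):
        data = make_dataset([1, 2, 3, 4], [0, 0, 0, 0], {"x": [0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="censored"):
            tree = grow_tree(data, rng=0)
        assert tree.root.is_leaf
        assert np.allclose(tree.root.curve([0, 2, 5]), 1.0)

    def test_structure_invariant_under_monotone_time_transform(self, binary_data2):
        t1 = grow_tree(binary_data2, rng=11)
        data2 = sf.SurvivalDataset(
            np.log1p(binary_data2.time), binary_data2.event,
            binary_data2.covariates, dict(binary_data2.kinds),
        )
        t2 = grow_tree(data2, rng=11)
        s1 = [(n.split.variable, n.split.threshold) for n in _internal(t1)]
        s2 = [(n.split.variable, n.split.threshold) for n in _internal(t2)]
        assert s1 == s2


def _internal(tree):
    out, stack = [], [tree.root]
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            out.append(n)
            stack.extend([n.left, n.right])
    return out
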