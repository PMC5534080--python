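"""Conditional inference machinery: rank tests, variable selection, forests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import survforest as sf
from survforest.rsf import default_eval_grid

from conftest import random_censored_data


def scores_of(time, event):
    return sf.logrank_scores(time, event)


class TestLinearRankTest:
    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(800):
            time, event = random_censored_data(rng, n=100)
            x = pd.Series(rng.integers(0, 2, 100), name="x")
            res = sf.linear_rank_test(x, scores_of(time, event))
            pvals.append(res.p_value)
        _, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_strong_association_detected(self):
        rng = np.random.default_rng(8)
        time, event = random_censored_data(rng, n=100, cens_rate=5.0)
        # indicator of the earliest-event half
        x = pd.Series((time < np.median(time)).astype(int), name="x")
        res = sf.linear_rank_test(x, scores_of(time, event))
        assert res.p_value < 1e-3

    def test_duplicated_covariate_identical_result(self, rng):
        time, event = random_censored_data(rng, n=60)
        x = pd.Series(rng.integers(0, 3, 60).astype(float), name="x")
        s = scores_of(time, event)
        r1 = sf.linear_rank_test(x, s)
        r2 = sf.linear_rank_test(x.rename("x2"), s)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_constant_covariate_rejected(self, rng):
        time, event = random_censored_data(rng, n=20)
        with pytest.raises(ValueError, match="constant"):
            sf.linear_rank_test(pd.Series(np.ones(20), name="x"),
                                scores_of(time, event))

    def test_small_node_uses_seeded_permutation_p(self, rng):
        time, event = random_censored_data(rng, n=12)
        x = pd.Series(np.r_[np.zeros(6), np.ones(6)], name="x")
        s = scores_of(time, event)
        r1 = sf.linear_rank_test(x, s, rng=np.random.default_rng(1))
        r2 = sf.linear_rank_test(x, s, rng=np.random.default_rng(1))
        assert r1.p_value == r2.p_value
        assert 0.0 < r1.p_value <= 1.0
        # permutation p-values have resolution 1/(draws+1)
        assert r1.p_value >= 1.0 / 2000

    def test_categorical_statistic_is_quadratic_form(self, rng):
        time, event = random_censored_data(rng, n=90)
        x = pd.Series(pd.Categorical(rng.choice(list("abc"), 90)), name="x")
        s = scores_of(time, event)
        res = sf.linear_rank_test(x, s)
        a = s.scores
        n = 90
        T = np.array([a[(x == lev).to_numpy()].sum() for lev in "abc"])
        n_l = np.array([(x == lev).sum() for lev in "abc"], dtype=float)
        mu = n_l * a.mean()
        Sigma = a.var(ddof=1) * (np.diag(n_l) - np.outer(n_l, n_l) / n)
        d = T - mu
        expected = d @ np.linalg.pinv(Sigma) @ d
        assert np.isclose(res.statistic, expected)
        # and the p-value sits on the chi-square(2) reference
        from scipy import stats as sps

        assert np.isclose(res.p_value, sps.chi2.sf(expected, df=2))

    def test_binary_statistic_is_squared_standardized_component(self, rng):
        time, event = random_censored_data(rng, n=80)
        x = pd.Series(rng.integers(0, 2, 80).astype(float), name="x")
        s = scores_of(time, event)
        res = sf.linear_rank_test(x, s)
        a, xv = s.scores, x.to_numpy()
        z = (xv @ a - 80 * xv.mean() * a.mean()) / np.sqrt(
            np.sum((xv - xv.mean()) ** 2) * a.var(ddof=1)
        )
        assert np.isclose(res.statistic, z**2)


class TestSelectSplitVariable:
    def test_null_stop_rate_matches_alpha(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            n = 100
            time, event = random_censored_data(rng, n=n)
            cov = pd.DataFrame(
                {
                    "b": rng.integers(0, 2, n),
                    "c": pd.Categorical(rng.choice(list("pqrst"), n)),
                }
            )
            data = sf.SurvivalDataset(time, event, cov)
            var, _ = sf.select_split_variable(data, alpha=0.05, rng=rng)
            rejections += var is not None
        rate = rejections / n_rep
        # Bonferroni keeps the familywise rate at or below alpha
        assert rate < 0.10

    def test_strong_effect_variable_selected(self, rng):
        hits = 0
        for rep in range(10):
            rng2 = np.random.default_rng(100 + rep)
            n = 250
            x_sig = rng2.integers(0, 2, n)
            lam = np.exp(-(-3.0) * x_sig)  # beta=-3 effect
            time = rng2.exponential(1.0 / lam)
            event = np.ones(n, int)
            cov = pd.DataFrame(
                {"noise": rng2.integers(0, 2, n), "sig": x_sig}
            )
            data = sf.SurvivalDataset(time, event, cov)
            var, _ = sf.select_split_variable(data, alpha=0.05, rng=rng2)
            hits += var == "sig"
        assert hits >= 9

    def test_adjusted_p_at_least_raw_p(self, rng):
        time, event = random_censored_data(rng, n=80)
        cov = pd.DataFrame(
            {f"x{j}": rng.integers(0, 2, 80) for j in range(4)}
        )
        data = sf.SurvivalDataset(time, event, cov)
        _, results = sf.select_split_variable(data, alpha=1.0, rng=rng)
        for r in results:
            assert r.p_value <= r.adjusted_p <= 1.0


class TestGrowCtree:
    def test_tiny_alpha_gives_root_only_tree(self, binary_data2):
        tree = sf.grow_ctree(binary_data2, alpha=1e-12, rng=0)
        assert tree.root.is_leaf

    def test_deterministic_replay(self, binary_data2):
        t1 = sf.grow_ctree(binary_data2, alpha=0.5, rng=5)
        t2 = sf.grow_ctree(binary_data2, alpha=0.5, rng=5)
        assert t1.to_text() == t2.to_text()

    def test_alpha_one_depth_comparable_to_rsf_tree(self, binary_data2):
        ct = sf.grow_ctree(binary_data2, alpha=1.0, rng=3)
        rt = sf.grow_tree(binary_data2, rule="logrank_score", rng=3)
        n_ct, n_rt = len(ct.leaves()), len(rt.leaves())
        assert n_ct >= max(2, n_rt - 3)


class TestFitPredictCIF:
    def test_subsample_full_warns_and_empties_oob(self, binary_data2):
        with pytest.warns(UserWarning, match="out-of-bag"):
            f = sf.fit_cif(binary_data2, n_trees=3, subsample_fraction=1.0, seed=0)
        assert all(o.size == 0 for o in f.oob)

    def test_same_seed_identical_forest(self, binary_data2):
        f1 = sf.fit_cif(binary_data2, n_trees=6, seed=11)
        f2 = sf.fit_cif(binary_data2, n_trees=6, seed=11)
        assert all(a.to_text() == b.to_text() for a, b in zip(f1.trees, f2.trees))

    def test_root_only_tree_predicts_training_km(self, binary_data2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = sf.fit_cif(
                binary_data2, n_trees=1, min_node_size=10**6,
                subsample_fraction=1.0, seed=1,
            )
        grid = default_eval_grid(binary_data2)
        S = sf.predict_cif_survival(f, binary_data2.covariates.iloc[:4], grid)
        km = sf.kaplan_meier(binary_data2.time, binary_data2.event)
        assert np.allclose(S, km(grid))

    def test_predictions_are_proper_curves(self, poly_small):
        f = sf.fit_cif(poly_small, n_trees=30, seed=2)
        grid = default_eval_grid(poly_small)
        S = sf.predict_cif_survival(f, poly_small.covariates, grid)
        assert (S >= 0).all() and (S <= 1).all()
        assert (np.diff(S, axis=1) <= 1e-12).all()

    def test_cif_and_rsf_agree_on_strong_binary_signal(self, registry):
        data = sf.gen_dataset(registry["binary_2"], seed=41)
        grid = default_eval_grid(data)
        fr = sf.fit_rsf(data, n_trees=100, seed=3)
        fc = sf.fit_cif(data, n_trees=100, seed=3)
        Sr = sf.predict_survival(fr, data.covariates, grid)
        Sc = sf.predict_cif_survival(fc, data.covariates, grid)
        sup = np.abs(Sr - Sc).max(axis=1)
        assert sup.mean() < 0.1
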