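"""Bivariate random walk, stepping-stone evidence and the correlation grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leafstem import bayes_correlation as bc
from leafstem import phylo_core as pc
from leafstem import synthetic_data as sd
from tests.conftest import star_tree


class TestRwLoglik:
    def test_rho_zero_separates(self, yule60):
        rng = np.random.default_rng(3)
        tr = rng.normal(size=(60, 2))
        m = bc.BivariateRWModel(1.3, 0.7, 0.0, 0.1, -0.2)
        C = yule60.mrca_depth_matrix() + 1e-9 * np.eye(60)
        l1 = stats.multivariate_normal(np.full(60, 0.1), 1.3 * C).logpdf(tr[:, 0])
        l2 = stats.multivariate_normal(np.full(60, -0.2), 0.7 * C).logpdf(tr[:, 1])
        assert bc.rw_loglik(C, tr, m) == pytest.approx(l1 + l2, abs=1e-6)

    def test_star_tree_iid(self):
        star = star_tree(25)
        rng = np.random.default_rng(4)
        tr = rng.normal(size=(25, 2))
        m = bc.BivariateRWModel(1.0, 2.0, 0.4, 0.0, 0.0)
        dense = stats.multivariate_normal(np.zeros(2), m.R)
        expect = sum(dense.logpdf(tr[i]) for i in range(25))
        assert bc.rw_loglik(star, tr, m) == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_kronecker_oracle(self, seed):
        n = 5 + seed
        tree = sd.sim_tree(n, seed=seed)
        rng = np.random.default_rng(seed)
        tr = rng.normal(size=(n, 2))
        m = bc.BivariateRWModel(1.3, 0.7, 0.55, 0.1, -0.2)
        C = tree.mrca_depth_matrix() + 1e-9 * np.eye(n)
        dense = np.kron(m.R, C)
        mean = np.concatenate([np.full(n, 0.1), np.full(n, -0.2)])
        expect = stats.multivariate_normal(mean, dense).logpdf(
            np.concatenate([tr[:, 0], tr[:, 1]])
        )
        assert bc.rw_loglik(C, tr, m) == pytest.approx(expect, abs=1e-8)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            bc.BivariateRWModel(1.0, 1.0, 1.0, 0, 0)
        with pytest.raises(ValueError):
            bc.BivariateRWModel(-1.0, 1.0, 0.0, 0, 0)


class TestSteppingStone:
    @staticmethod
    def conjugate_toy(seed=3, n=30, s2=1.0, tau2=4.0):
        rng = np.random.default_rng(seed)
        y = rng.normal(1.0, np.sqrt(s2), size=n)

        def log_lik(th):
            return float(
                -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * np.sum((y - th[0]) ** 2) / s2
            )

        def log_prior(th):
            return float(-0.5 * np.log(2 * np.pi * tau2) - 0.5 * th[0] ** 2 / tau2)

        truth = stats.multivariate_normal(
            np.zeros(n), s2 * np.eye(n) + tau2
        ).logpdf(y)
        return log_lik, log_prior, truth

    def test_ladder_contract(self):
        b = bc.beta_ladder(50)
        assert b[0] == 0.0 and b[-1] == 1.0
        assert np.all(np.diff(b) > 0)
        # Beta(0.4, 1) quantiles crowd near zero
        assert b[1] < 1.0 / 50

    def test_conjugate_evidence_recovered(self):
        ll, lp, truth = self.conjugate_toy()
        errs = [
            bc.stepping_stone(ll, lp, np.array([0.0]), stones=50,
                              iters_per_stone=1000, seed=s).log_marginal - truth
            for s in range(10)
        ]
        assert np.max(np.abs(errs)) < 0.1

    def test_more_iterations_reduce_spread(self):
        ll, lp, truth = self.conjugate_toy()
        def spread(iters, seeds):
            vals = [
                bc.stepping_stone(ll, lp, np.array([0.0]), stones=20,
                                  iters_per_stone=iters, seed=s).log_marginal
                for s in seeds
            ]
            return np.std(vals)
        s_small = spread(150, range(8))
        s_big = spread(1200, range(8, 16))
        assert s_big < s_small

    def test_input_validation(self):
        ll, lp, _ = self.conjugate_toy()
        with pytest.raises(ValueError):
            bc.stepping_stone(ll, lp, np.array([0.0]), stones=1)
        with pytest.raises(ValueError):
            bc.stepping_stone(ll, lp, np.array([0.0]), iters_per_stone=10)


class TestBayesFactor:
    def test_logbf_arithmetic(self):
        r = bc.CorrelationResult(
            ss_corr=-10.0, ss_noncorr=-15.0, diagnostics_ok=True,
            stones=2, iters_per_stone=100,
        )
        assert r.logbf == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "val,cls",
        [(-3.0, "none"), (0.0, "none"), (1.99, "none"), (2.0, "somewhat"),
         (4.99, "somewhat"), (5.0, "strong"), (9.99, "strong"),
         (10.0, "very strong"), (44.0, "very strong")],
    )
    def test_classification_thresholds(self, val, cls):
        assert bc.classify_logbf(val) == cls

    def test_correlated_traits_detected(self):
        tree = sd.sim_tree(100, seed=21)
        C = tree.mrca_depth_matrix() + 1e-12 * np.eye(100)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(900)
        Rl = np.linalg.cholesky(np.array([[1, 0.9], [0.9, 1]]))
        traits = L @ rng.standard_normal((100, 2)) @ Rl.T
        r = bc.test_correlation(tree, traits, stones=8, iters_per_stone=200, seed=0)
        assert r.classification in ("strong", "very strong")

    def test_independent_traits_not_detected(self):
        tree = sd.sim_tree(100, seed=21)
        C = tree.mrca_depth_matrix() + 1e-12 * np.eye(100)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(901)
        traits = L @ rng.standard_normal((100, 2))
        r = bc.test_correlation(tree, traits, stones=8, iters_per_stone=200, seed=1)
        assert r.logbf < 2


class TestGrid:
    def test_mean_grid_pair_count(self):
        plan = bc.plan_grid(["residual", "leaf", "stem"],
                            [f"bio{i}" for i in range(1, 20)], ["mean"])
        assert len(plan) // 2 == 57

    def test_full_grid_run_count(self):
        plan = bc.plan_grid(["residual", "leaf", "stem"],
                            [f"bio{i}" for i in range(1, 20)],
                            ["mean", "q05", "q95"])
        assert len(plan) == 342
        assert len(plan.drop(columns="model").drop_duplicates()) == 171

    def test_single_cell_reduces_to_test_correlation(self):
        tree = sd.sim_tree(40, seed=33)
        rng = np.random.default_rng(33)
        trait = pd.DataFrame(
            {"residual": rng.normal(size=40)}, index=tree.tip_labels
        )
        climate = pd.DataFrame(
            rng.normal(size=(40, 1)),
            index=tree.tip_labels,
            columns=pd.MultiIndex.from_tuples([("bio15", "mean")]),
        )
        grid = bc.correlation_grid(
            tree, trait, climate, stones=4, iters_per_stone=120, seed=7
        )
        assert len(grid) == 1
        row = grid.iloc[0]
        assert row["class"] == bc.classify_logbf(row["logbf"])
        assert row["logbf"] == pytest.approx(
            2 * (row["ss_corr"] - row["ss_noncorr"])
        )

    def test_missing_species_dropped_with_warning(self):
        tree = sd.sim_tree(20, seed=35)
        rng = np.random.default_rng(35)
        trait = pd.DataFrame(
            {"residual": rng.normal(size=20)}, index=tree.tip_labels
        )
        climate = pd.DataFrame(
            rng.normal(size=(15, 1)),
            index=tree.tip_labels[:15],
            columns=pd.MultiIndex.from_tuples([("bio1", "mean")]),
        )
        with pytest.warns(UserWarning, match="dropped"):
            grid = bc.correlation_grid(
                tree, trait, climate, stones=4, iters_per_stone=120, seed=8
            )
        assert grid.iloc[0]["n_species"] == 15
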