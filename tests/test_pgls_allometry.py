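"""Specimen aggregation and PGLS with OU error structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve_triangular

from leafstem import pgls_allometry as pa
from leafstem import phylo_core as pc
from leafstem import synthetic_data as sd
from tests.conftest import star_tree


class TestStemCrossSection:
    def test_unit_radius(self):
        assert pa.stem_cross_section(1.0) == pytest.approx(np.pi)

    def test_radius_two(self):
        assert pa.stem_cross_section(2.0) == pytest.approx(4 * np.pi)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pa.stem_cross_section(0.0)


class TestAggregate:
    def make_records(self, leaf_areas, species="sp1", diameter=2.0):
        return pd.DataFrame(
            {
                "species": species,
                "specimen_id": f"{species}_v1",
                "leaf_area_mm2": leaf_areas,
                "stem_diameter_mm": diameter,
            }
        )

    def test_mean_of_logs(self):
        rec = self.make_records([np.e, np.e**3])
        out = pa.aggregate_species(rec)
        assert out.loc[0, "log_leaf_area"] == pytest.approx(2.0)

    def test_single_specimen_identity(self):
        rec = self.make_records([np.e**2])
        out = pa.aggregate_species(rec)
        assert out.loc[0, "log_leaf_area"] == pytest.approx(2.0)
        # stem: diameter 2 -> radius 1 -> area pi
        assert out.loc[0, "log_stem_area"] == pytest.approx(np.log(np.pi))

    def test_log_base_option(self):
        rec = self.make_records([100.0])
        out = pa.aggregate_species(rec, log_base=10)
        assert out.loc[0, "log_leaf_area"] == pytest.approx(2.0)

    def test_lognormal_recovery_within_2se(self):
        rng = np.random.default_rng(0)
        true_mean = 5.0
        sd_log = 0.3
        vals = np.exp(rng.normal(true_mean, sd_log, size=20))
        out = pa.aggregate_species(self.make_records(vals))
        se = sd_log / np.sqrt(20)
        assert abs(out.loc[0, "log_leaf_area"] - true_mean) < 2 * se * 3

    def test_conflicting_group_labels_rejected(self):
        rec = self.make_records([1.0, 2.0])
        rec["strategy"] = ["generalist", "specialized"]
        with pytest.raises(ValueError, match="conflicting"):
            pa.aggregate_species(rec)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pa.aggregate_species(self.make_records([0.0]))


class TestFitPGLS:
    def test_star_tree_equals_ols(self):
        star = star_tree(30)
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 1.5 * x + 0.3 + rng.normal(size=30)
        tab = pd.DataFrame(
            {"species": star.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        f = pa.fit_pgls(star, tab)
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(f.coef, beta, atol=1e-8)

    def test_perfect_line(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=2)
        tab = pd.DataFrame(
            {
                "species": yule60.tip_labels,
                "log_leaf_area": x,
                "log_stem_area": 2.0 * x - 1.0,
            }
        )
        f = pa.fit_pgls(yule60, tab)
        assert f.slope == pytest.approx(2.0, abs=1e-8)
        assert f.intercept == pytest.approx(-1.0, abs=1e-8)
        assert np.abs(f.residuals).max() < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_cholesky_whitening_oracle(self, seed):
        """GLS estimates equal OLS on the whitened system."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        tree = sd.sim_tree(n, seed=seed)
        x = sd.sim_bm_ou(tree, pc.CovarianceSpec("BM"), seed=seed + 50)
        y = 0.6 * x + rng.normal(size=n)
        tab = pd.DataFrame(
            {"species": tree.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        alpha = float(rng.uniform(0.5, 5.0))
        f = pa.fit_pgls(tree, tab, alpha=alpha)
        V = pc.ou_correlation(tree, alpha)
        L = np.linalg.cholesky(V)
        Xw = solve_triangular(L, np.column_stack([np.ones(n), x]), lower=True)
        yw = solve_triangular(L, y, lower=True)
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        assert np.allclose(f.coef, beta, atol=1e-8)

    def test_residual_order_invariance(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=3)
        y = 0.6 * x + sd.sim_bm_ou(yule60, pc.CovarianceSpec("OU", alpha=2.0), seed=4)
        tab = pd.DataFrame(
            {"species": yule60.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        f1 = pa.fit_pgls(yule60, tab)
        shuffled = tab.sample(frac=1.0, random_state=9)
        f2 = pa.fit_pgls(yule60, shuffled)
        pd.testing.assert_series_equal(f1.residuals, f2.residuals)

    def test_alpha_zero_limit_matches_bm(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=5)
        y = 0.6 * x + sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM", rate=0.3), seed=6)
        tab = pd.DataFrame(
            {"species": yule60.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        f_ou = pa.fit_pgls(yule60, tab, alpha=1e-9)
        f_bm = pa.fit_pgls(yule60, tab, error_model="BM")
        # on an ultrametric tree, alpha -> 0 OU correlation has the same
        # GLS estimates as BM (affine covariance relationship)
        assert np.allclose(f_ou.coef, f_bm.coef, atol=1e-5)

    def test_t_F_relationship_and_df(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=8)
        y = 0.6 * x + sd.sim_bm_ou(yule60, pc.CovarianceSpec("OU", alpha=2.0), seed=9)
        tab = pd.DataFrame(
            {"species": yule60.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        f = pa.fit_pgls(yule60, tab)
        assert np.allclose(f.F, f.t**2)
        assert f.df_resid == 58

    def test_constant_predictor_rejected(self, yule60):
        tab = pd.DataFrame(
            {
                "species": yule60.tip_labels,
                "log_leaf_area": np.ones(60),
                "log_stem_area": np.arange(60.0),
            }
        )
        with pytest.raises(ValueError, match="singular|constant"):
            pa.fit_pgls(yule60, tab)


class TestGroupFits:
    def test_single_group_equals_whole_fit(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=10)
        y = 0.6 * x + sd.sim_bm_ou(yule60, pc.CovarianceSpec("OU", alpha=2.0), seed=11)
        tab = pd.DataFrame(
            {
                "species": yule60.tip_labels,
                "log_leaf_area": x,
                "log_stem_area": y,
                "strategy": "generalist",
            }
        )
        f_all = pa.fit_pgls(yule60, tab)
        fits = pa.fit_pgls_by_group(yule60, tab, "strategy")
        assert np.allclose(fits["generalist"].coef, f_all.coef)

    def test_small_group_skipped_with_warning(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=12)
        tab = pd.DataFrame(
            {
                "species": yule60.tip_labels,
                "log_leaf_area": x,
                "log_stem_area": 0.6 * x,
                "strategy": ["specialized"] * 3 + ["generalist"] * 57,
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            fits = pa.fit_pgls_by_group(yule60, tab, "strategy")
        assert "specialized" not in fits
        assert fits["_skipped"] == ["specialized"]

    def test_group_intercept_rank_recovery(self):
        """Two groups with intercepts of opposite sign: the fitted
        intercept ranking recovers the truth in nearly all replicates."""
        hits = 0
        nrep = 30
        for s in range(nrep):
            tree = sd.sim_tree(40, seed=900 + s)
            x = sd.sim_bm_ou(tree, pc.CovarianceSpec("BM", rate=2.0), seed=950 + s,
                             root_mean=7.0)
            r = sd.sim_bm_ou(tree, pc.CovarianceSpec("OU", rate=0.25, alpha=2.0),
                             seed=990 + s)
            groups = np.where(np.arange(40) < 20, "multi-stemmed", "single-stemmed")
            icept = np.where(groups == "multi-stemmed", -4.12, 0.47)
            y = icept + 0.54 * x + r
            tab = pd.DataFrame(
                {
                    "species": tree.tip_labels,
                    "log_leaf_area": x,
                    "log_stem_area": y,
                    "architecture": groups,
                }
            )
            fits = pa.fit_pgls_by_group(tree, tab, "architecture")
            hits += (
                fits["multi-stemmed"].intercept < fits["single-stemmed"].intercept
            )
        assert hits >= 0.95 * nrep

    def test_table_shape(self, yule60):
        x = sd.sim_bm_ou(yule60, pc.CovarianceSpec("BM"), seed=13)
        tab = pd.DataFrame(
            {
                "species": yule60.tip_labels,
                "log_leaf_area": x,
                "log_stem_area": 0.6 * x - 4.58,
            }
        )
        f = pa.fit_pgls(yule60, tab)
        out = pa.pgls_table({"all": f})
        assert set(out.columns) >= {
            "group", "slope", "slope_se", "slope_t", "slope_p",
            "intercept", "intercept_se", "intercept_t", "intercept_p",
        }
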