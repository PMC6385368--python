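"""Tree I/O, covariance construction and BM ancestral states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from leafstem import phylo_core as pc
from leafstem import synthetic_data as sd


class TestNewick:
    def test_basic_parse(self, three_tip_tree):
        t = three_tip_tree
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert np.allclose(t.tip_depths, 2.0)
        assert t.n_nodes == 5

    def test_single_tip_degenerate(self):
        t = pc.read_newick("(A:1);")
        assert t.tip_labels == ["A"]
        assert t.tip_depths[0] == pytest.approx(1.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(pc.NewickError, match="duplicate"):
            pc.read_newick("((A:1,A:1):1,C:2);")

    def test_malformed_rejected(self):
        with pytest.raises(pc.NewickError):
            pc.read_newick("((A:1,B:1;")

    def test_round_trip(self, yule60):
        text = pc.write_newick(yule60)
        t2 = pc.read_newick(text)
        assert sorted(t2.tip_labels) == sorted(yule60.tip_labels)
        i = t2.tip_index(yule60.tip_labels)
        d1 = yule60.patristic_matrix()
        d2 = t2.patristic_matrix()[np.ix_(i, i)]
        assert np.allclose(d1, d2, atol=1e-9)

    def test_quoted_labels(self):
        t = pc.read_newick("('sp one':1,'sp two':1);")
        assert set(t.tip_labels) == {"sp one", "sp two"}
        t2 = pc.read_newick(pc.write_newick(t))
        assert set(t2.tip_labels) == {"sp one", "sp two"}


class TestPrune:
    def test_path_conservation(self, three_tip_tree):
        pr = pc.prune_to_taxa(three_tip_tree, ["A", "C"])
        assert sorted(pr.tip_labels) == ["A", "C"]
        assert np.allclose(pr.tip_depths, 2.0)
        i, j = pr.tip_index(["A"])[0], pr.tip_index(["C"])[0]
        assert pr.patristic_matrix()[i, j] == pytest.approx(4.0)

    def test_keep_all_is_identity(self, yule60):
        pr = pc.prune_to_taxa(yule60, yule60.tip_labels)
        i = pr.tip_index(yule60.tip_labels)
        assert np.allclose(
            pr.patristic_matrix()[np.ix_(i, i)], yule60.patristic_matrix()
        )

    def test_single_taxon_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            pc.prune_to_taxa(three_tip_tree, ["A"])

    def test_unknown_label_rejected(self, three_tip_tree):
        with pytest.raises(KeyError):
            pc.prune_to_taxa(three_tip_tree, ["A", "Z"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_patristic_submatrix_preserved(self, seed):
        tree = sd.sim_tree(30, seed=seed)
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(tree.tip_labels, size=12, replace=False))
        pr = pc.prune_to_taxa(tree, keep)
        i_full = tree.tip_index(keep)
        i_sub = pr.tip_index(keep)
        assert np.allclose(
            tree.patristic_matrix()[np.ix_(i_full, i_full)],
            pr.patristic_matrix()[np.ix_(i_sub, i_sub)],
            atol=1e-9,
        )


class TestVcv:
    def test_bm_shared_paths(self, three_tip_tree):
        V = pc.vcv(three_tip_tree, pc.CovarianceSpec("BM", rate=1.0))
        order = three_tip_tree.tip_index(["A", "B", "C"])
        expect = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        assert np.allclose(V[np.ix_(order, order)], expect)

    def test_ou_correlation_halving(self):
        tree = pc.read_newick("(A:0.5,B:0.5);")  # d_AB = 1
        corr = pc.ou_correlation(tree, np.log(2.0))
        assert corr[0, 1] == pytest.approx(0.5)

    def test_lambda_zero_diagonal(self, yule60):
        V = pc.vcv(yule60, pc.CovarianceSpec("lambda", lam=0.0))
        assert np.allclose(V, np.diag(yule60.tip_depths))

    def test_bm_diagonal_is_depths(self):
        for seed in range(5):
            tree = sd.sim_tree(25, seed=seed)
            V = pc.vcv(tree, pc.CovarianceSpec("BM", rate=2.5))
            assert np.allclose(np.diag(V), 2.5 * tree.tip_depths)

    @pytest.mark.parametrize(
        "spec",
        [
            pc.CovarianceSpec("BM"),
            pc.CovarianceSpec("OU", alpha=3.0),
            pc.CovarianceSpec("OU", alpha=1.0, stationary=False),
            pc.CovarianceSpec("EB", ebrate=-2.0),
            pc.CovarianceSpec("lambda", lam=0.35),
            pc.CovarianceSpec("kappa", kappa=0.5),
            pc.CovarianceSpec("delta", delta=2.0),
            pc.CovarianceSpec("white"),
        ],
    )
    def test_symmetric_psd_on_random_trees(self, spec):
        for seed in range(12):
            tree = sd.sim_tree(15, seed=seed)
            V = pc.vcv(tree, spec)
            assert np.allclose(V, V.T)
            w = np.linalg.eigvalsh(V)
            assert w.min() >= -1e-10 * max(1.0, w.max())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            pc.CovarianceSpec("lambda", lam=1.5)
        with pytest.raises(ValueError):
            pc.CovarianceSpec("OU", alpha=-1.0)
        with pytest.raises(ValueError):
            pc.CovarianceSpec("BM", rate=0.0)
        with pytest.raises(ValueError):
            pc.CovarianceSpec("nosuch")


class TestAncestralStates:
    def test_two_tip_symmetry(self, two_tip_tree):
        est = pc.anc_state_continuous(two_tip_tree, np.array([0.0, 2.0]))
        assert est[two_tip_tree.root] == pytest.approx(1.0)

    def test_constant_trait(self, yule60):
        est = pc.anc_state_continuous(yule60, np.full(60, 3.25))
        assert np.allclose(est, 3.25)

    def test_weighted_two_tip_formula(self):
        # unequal branches: root estimate is the branch-length-weighted avg
        tree = pc.read_newick("(A:1,B:3);")
        est = pc.anc_state_continuous(tree, np.array([0.0, 4.0]))
        assert est[tree.root] == pytest.approx((0.0 / 1 + 4.0 / 3) / (1 / 1 + 1 / 3),
                                               abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dense_gls_oracle(self, seed):
        """Internal estimates must match the node-augmented GLS solution."""
        tree = sd.sim_tree(6, seed=seed)
        rng = np.random.default_rng(seed)
        y = rng.normal(size=6)
        est = pc.anc_state_continuous(tree, y)
        # dense oracle: covariance over all nodes = shared path lengths
        n_all = tree.n_nodes
        depth = tree.node_depth
        C = np.zeros((n_all, n_all))
        anc = [set() for _ in range(n_all)]
        for node in range(n_all):
            k = node
            while k >= 0:
                anc[node].add(k)
                k = tree.parent[k]
        for a in range(n_all):
            for b in range(n_all):
                common = anc[a] & anc[b]
                C[a, b] = max(depth[k] for k in common)
        tips = np.arange(tree.n_tips)
        others = np.arange(tree.n_tips, n_all)
        Ctt = C[np.ix_(tips, tips)] + 1e-12 * np.eye(len(tips))
        one = np.ones(len(tips))
        Cti = np.linalg.inv(Ctt)
        mu = (one @ Cti @ y) / (one @ Cti @ one)
        cond = mu + C[np.ix_(others, tips)] @ Cti @ (y - mu)
        assert np.allclose(est[others], cond, atol=1e-8)

    def test_missing_values_rejected(self, yule60):
        with pytest.raises(ValueError):
            pc.anc_state_continuous(yule60, np.full(60, np.nan))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 40))
def test_yule_trees_are_valid_and_ultrametric(seed, n):
    tree = sd.sim_tree(n, seed=seed)
    assert tree.n_tips == n
    assert tree.n_nodes == 2 * n - 1
    assert tree.is_ultrametric(rtol=1e-9)
    assert tree.height == pytest.approx(1.0)
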