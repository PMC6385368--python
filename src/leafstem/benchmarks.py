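"""Reproducible end-to-end checks of the package's statistical machinery.

Each function regenerates its own synthetic inputs from a seed, runs the
corresponding analysis exactly as a user would, and returns a measured
quantity: oracle agreement errors, confidence-interval coverage, test
calibration, recovery rates and marginal-likelihood accuracy.  They are
used by the acceptance test-suite and by ``scripts/acceptance.py``.

Problem sizes are desk scale (tens of species, hundreds of replicates)
— large enough for the rates and errors to be meaningful, small enough
to run on one core in minutes; see docs/methods.md.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from . import (
    bayes_correlation as bc,
    discrete_evolution as de,
    pgls_allometry as pa,
    phylo_core as pc,
    shift_inference as si,
    synthetic_data as sd,
)

__all__ = [
    "grid_counts",
    "pgls_whitening_error",
    "pgls_coverage",
    "anova_type1_error",
    "shift_recovery_rate",
    "shift_specificity_rate",
    "mk_enumeration_error",
    "simmap_consistency",
    "stepping_stone_error",
    "bf_arithmetic",
    "pagel_discrimination",
]


def _seed32(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31)


# -- 1. grid bookkeeping ----------------------------------------------------


def grid_counts() -> dict:
    """Pair and model-run counts of the trait x climate grid: 3 traits x
    19 bioclim variables, one or three species summaries."""
    traits = ["residual", "log_leaf_area", "log_stem_area"]
    variables = [f"bio{i}" for i in range(1, 20)]
    mean_plan = bc.plan_grid(traits, variables, ["mean"])
    full_plan = bc.plan_grid(traits, variables, ["mean", "q05", "q95"])
    return {
        "mean_pairs": len(mean_plan) // 2,
        "all_pairs": len(full_plan) // 2,
        "model_runs": len(full_plan),
    }


# -- 2. PGLS whitening oracle ----------------------------------------------


def pgls_whitening_error(seed: int = 0, n_instances: int = 50) -> float:
    """Max |GLS - whitened-OLS| coefficient difference over random
    instances (10-60 tips, random OU alpha)."""
    worst = 0.0
    for i in range(n_instances):
        rng = np.random.default_rng(_seed32(seed, 100 + i))
        n = int(rng.integers(10, 61))
        tree = sd.sim_tree(n, seed=_seed32(seed, 200 + i))
        x = sd.sim_bm_ou(tree, pc.CovarianceSpec("BM"), seed=_seed32(seed, 300 + i))
        y = 0.6 * x + rng.normal(size=n)
        tab = pd.DataFrame(
            {"species": tree.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        alpha = float(rng.uniform(0.3, 8.0))
        fit = pa.fit_pgls(tree, tab, alpha=alpha)
        L = np.linalg.cholesky(pc.ou_correlation(tree, alpha))
        Xw = solve_triangular(L, np.column_stack([np.ones(n), x]), lower=True)
        yw = solve_triangular(L, y, lower=True)
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        worst = max(worst, float(np.abs(fit.coef - beta).max()))
    return worst


# -- 3. PGLS coverage --------------------------------------------------------


def pgls_coverage(seed: int = 0, nrep: int = 500, n: int = 60) -> dict:
    """95% CI coverage of the generating slope 0.60 and intercept -4.58
    under the study conditions (BM predictor, OU residuals)."""
    cs = ci = 0
    for i in range(nrep):
        tree = sd.sim_tree(n, seed=_seed32(seed, 1000 + i))
        x = sd.sim_bm_ou(
            tree, pc.CovarianceSpec("BM", rate=2.0), seed=_seed32(seed, 2000 + i),
            root_mean=7.0,
        )
        r = sd.sim_bm_ou(
            tree, pc.CovarianceSpec("OU", rate=1.0, alpha=2.0),
            seed=_seed32(seed, 3000 + i),
        )
        y = -4.58 + 0.60 * x + r
        tab = pd.DataFrame(
            {"species": tree.tip_labels, "log_leaf_area": x, "log_stem_area": y}
        )
        fit = pa.fit_pgls(tree, tab)
        tq = stats.t.ppf(0.975, fit.df_resid)
        cs += abs(fit.slope - 0.60) <= tq * fit.se[1]
        ci += abs(fit.intercept + 4.58) <= tq * fit.se[0]
    return {"slope_coverage": cs / nrep, "intercept_coverage": ci / nrep}


# -- 4. phylogenetic ANOVA calibration ---------------------------------------


def anova_type1_error(
    seed: int = 0, nrep: int = 500, nsim: int = 500, n: int = 30
) -> float:
    """Rejection rate at nominal 0.05 for BM data with arbitrary labels."""
    rej = 0
    for i in range(nrep):
        tree = sd.sim_tree(n, seed=_seed32(seed, 4000 + i))
        y = pd.Series(
            sd.sim_bm_ou(tree, pc.CovarianceSpec("BM"), seed=_seed32(seed, 5000 + i)),
            index=tree.tip_labels,
        )
        g = pd.Series(np.where(np.arange(n) % 2 == 0, "a", "b"),
                      index=tree.tip_labels)
        res = si.phylo_anova(tree, y, g, nsim=nsim, seed=_seed32(seed, 6000 + i))
        rej += res.p <= 0.05
    return rej / nrep


# -- 5. OU shift recovery / specificity --------------------------------------


def _mid_clade(tree: pc.PhyloTree, lo=6, hi=20) -> int:
    sizes = {
        node: len(tree.tips_below(node))
        for node in range(tree.n_tips, tree.n_nodes)
        if node != tree.root
    }
    ok = [n for n, s in sizes.items() if lo <= s <= hi]
    return max(ok, key=lambda n: sizes[n])


def shift_recovery_rate(
    seed: int = 0, nrep: int = 100, n: int = 60, magnitude: float = 8.0
) -> float:
    """Fraction of replicates where S1 recovers the planted-shift branch
    (or the tip-set-equivalent complementary branch)."""
    hits = 0
    for i in range(nrep):
        tree = sd.sim_tree(n, seed=_seed32(seed, 7000 + i))
        node = _mid_clade(tree)
        y = pd.Series(
            sd.sim_bm_ou(
                tree, pc.CovarianceSpec("OU", rate=1.0, alpha=2.0),
                seed=_seed32(seed, 8000 + i), shifts={node: magnitude},
            ),
            index=tree.tip_labels,
        )
        model = si.detect_ou_shifts(tree, y, nmax=1)
        truth = set(tree.tip_labels[t] for t in tree.tips_below(node))
        comp = set(tree.tip_labels) - truth
        got = set(model.shifts[0][1])
        hits += got in (truth, comp) and model.selected >= 1
    return hits / nrep


def shift_specificity_rate(seed: int = 0, nrep: int = 200, n: int = 60) -> float:
    """Fraction of no-shift OU datasets for which the 0-shift model is
    selected."""
    zero = 0
    for i in range(nrep):
        tree = sd.sim_tree(n, seed=_seed32(seed, 9000 + i))
        y = pd.Series(
            sd.sim_bm_ou(
                tree, pc.CovarianceSpec("OU", rate=1.0, alpha=2.0),
                seed=_seed32(seed, 10_000 + i),
            ),
            index=tree.tip_labels,
        )
        model = si.detect_ou_shifts(tree, y, nmax=1)
        zero += model.selected == 0
    return zero / nrep


# -- 6. Mk enumeration oracle ------------------------------------------------

_FIXTURE_NEWICKS = [
    "(A:1,B:1);",
    "((A:1,B:1):1,C:2);",
    "((A:0.5,B:1.2):0.7,(C:0.3,D:0.9):1.1);",
    "(((A:0.4,B:0.6):0.5,C:0.8):0.3,(D:0.2,E:1.0):0.7);",
    "(((A:0.2,B:0.4):0.3,(C:0.5,D:0.1):0.2):0.6,(E:0.7,F:0.3):0.5);",
]


def _brute_force_mk(tree: pc.PhyloTree, states, model: de.MkModel) -> float:
    P = de._p2(model.q01, model.q10, tree.edge_length)
    internals = [node for node in range(tree.n_nodes) if node >= tree.n_tips]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = dict(zip(internals, assign))
        st = lambda node: states[node] if node < tree.n_tips else amap[node]
        pr = 0.5
        for node in range(tree.n_nodes):
            if node != tree.root:
                pr *= P[node][st(tree.parent[node]), st(node)]
        total += pr
    return float(np.log(total))


def mk_enumeration_error(seed: int = 0) -> float:
    """Max |pruning - enumeration| log-likelihood difference over the
    fixture set of trees with up to 6 tips."""
    worst = 0.0
    rng = np.random.default_rng(_seed32(seed, 11_000))
    for nw in _FIXTURE_NEWICKS:
        tree = pc.read_newick(nw)
        for model in (de.MkModel(0.3, 0.3, "ER"), de.MkModel(0.8, 0.2, "ARD")):
            for _ in range(4):
                states = rng.integers(0, 2, tree.n_tips)
                a = de.mk_loglik(tree, states, model)
                b = _brute_force_mk(tree, states, model)
                worst = max(worst, abs(a - b))
    return worst


# -- 7. stochastic-mapping consistency ---------------------------------------


def simmap_consistency(seed: int = 0, nsim: int = 2000) -> float:
    """Max |simulated root-state frequency - analytic conditional| in
    Monte-Carlo standard errors, over two-tip fixtures."""
    worst_z = 0.0
    cases = [
        ("(A:1,B:1);", [0, 0], de.MkModel(0.4, 0.4)),
        ("(A:0.5,B:2.0);", [0, 1], de.MkModel(0.7, 0.7)),
        ("(A:1.5,B:1.5);", [1, 1], de.MkModel(0.25, 0.25)),
    ]
    for k, (nw, tips, model) in enumerate(cases):
        tree = pc.read_newick(nw)
        hists = de.simmap(tree, tips, model, nsim=nsim, seed=_seed32(seed, 12_000 + k))
        freq = np.mean([h["node_states"][tree.root] == 0 for h in hists])
        p = de.marginal_ancestral_states(tree, tips, model)[tree.root, 0]
        se = max(np.sqrt(p * (1 - p) / nsim), 1e-12)
        worst_z = max(worst_z, abs(freq - p) / se)
    return worst_z


# -- 8. stepping-stone accuracy ----------------------------------------------


def stepping_stone_error(
    seed: int = 0, n_seeds: int = 10, stones: int = 50, iters: int = 1000
) -> float:
    """Max |SS estimate - analytic evidence| over seeds, on the conjugate
    normal-mean toy model."""
    rng = np.random.default_rng(_seed32(seed, 13_000))
    n, s2, tau2 = 30, 1.0, 4.0
    y = rng.normal(1.0, np.sqrt(s2), size=n)

    def log_lik(th):
        return float(
            -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * np.sum((y - th[0]) ** 2) / s2
        )

    def log_prior(th):
        return float(-0.5 * np.log(2 * np.pi * tau2) - 0.5 * th[0] ** 2 / tau2)

    truth = stats.multivariate_normal(np.zeros(n), s2 * np.eye(n) + tau2).logpdf(y)
    errs = [
        bc.stepping_stone(
            log_lik, log_prior, np.array([0.0]), stones=stones,
            iters_per_stone=iters, seed=_seed32(seed, 14_000 + k),
        ).log_marginal
        - truth
        for k in range(n_seeds)
    ]
    return float(np.max(np.abs(errs)))


# -- 9. Bayes-factor arithmetic ----------------------------------------------


def bf_arithmetic() -> dict:
    """logBF identity and threshold classification on fixed fixtures."""
    r = bc.CorrelationResult(
        ss_corr=-10.0, ss_noncorr=-15.0, diagnostics_ok=True,
        stones=2, iters_per_stone=100,
    )
    fixtures = {1.0: "none", 3.0: "somewhat", 7.0: "strong", 12.0: "very strong"}
    return {
        "logbf_identity": r.logbf,
        "classes_correct": float(
            all(bc.classify_logbf(v) == c for v, c in fixtures.items())
        ),
    }


# -- 10. Pagel discrimination ------------------------------------------------


def pagel_discrimination(
    seed: int = 0, n_indep: int = 10, n_tips: int = 200,
    stones: int = 10, iters: int = 300,
) -> dict:
    """logBF behaviour for independently simulated trait pairs (should sit
    below 2) and for a duplicated trait (should exceed 10)."""
    tree = sd.sim_tree(n_tips, seed=_seed32(seed, 15_000))
    below2 = 0
    used = 0
    k = 0
    while used < n_indep and k < 4 * n_indep:
        A, _ = sd.sim_discrete(tree, 1.5, seed=_seed32(seed, 16_000 + k))
        B, _ = sd.sim_discrete(tree, 1.5, seed=_seed32(seed, 17_000 + k))
        k += 1
        if len(np.unique(A)) < 2 or len(np.unique(B)) < 2:
            continue
        r = de.pagel_test(tree, A, B, stones=stones, iters_per_stone=iters,
                          seed=_seed32(seed, 18_000 + k))
        below2 += r.logbf < 2
        used += 1
    A, _ = sd.sim_discrete(tree, 1.5, seed=_seed32(seed, 16_000))
    dup = de.pagel_test(tree, A, A, stones=stones, iters_per_stone=iters,
                        seed=_seed32(seed, 19_000))
    return {
        "independent_below2_rate": below2 / max(used, 1),
        "duplicated_logbf": dup.logbf,
        "n_pairs": used,
    }
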