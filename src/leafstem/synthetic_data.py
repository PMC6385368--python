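"""Seeded generators for every input the pipeline consumes.

The study system is a clade of epiphytic ant-plants: ~70 species on a
dated tree, specimen-level leaf-area and stem-diameter measurements with
group labels (architecture, domatium growth type, mutualistic strategy),
and occurrence tables carrying 19 bioclim values per record.  None of the
original data ships with this package, so each generator produces a
synthetic stand-in with known ground truth: a pure-birth tree, log-scale
allometric trait data with OU-distributed residuals (optionally with
optimum shifts painted on known branches), binary characters evolving
under Mk (independently or with Pagel-style dependence), and per-species
climate values with a tunable correlation to a trait.

Randomness: every generator takes a seed and draws from a dedicated
substream (``numpy`` ``SeedSequence(seed, purpose-id)``), so adding one
generator never perturbs another's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import PhyloTree, CovarianceSpec, vcv

__all__ = [
    "GeneratorConfig",
    "rng_for",
    "sim_tree",
    "sim_bm_ou",
    "sim_allometry_dataset",
    "sim_discrete",
    "sim_occurrences",
    "ARCHITECTURES",
    "DOMATIUM_GROWTH",
    "STRATEGIES",
]

# closed label vocabularies of the study system
ARCHITECTURES = ("multi-stemmed", "single-stemmed")
DOMATIUM_GROWTH = ("diffuse", "apical")
STRATEGIES = ("specialized", "generalist", "non-ant", "no-domatia-outgroup")

# stable substream ids per purpose
_STREAMS = {
    "tree": 1,
    "bm_ou": 2,
    "allometry": 3,
    "discrete": 4,
    "occurrences": 5,
    "anova": 6,
    "misc": 7,
}


def rng_for(purpose: str, seed: int, extra: int = 0) -> np.random.Generator:
    """A reproducible substream keyed by (purpose, seed, extra)."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed) % 2**31, _STREAMS[purpose], int(extra)))
    )


@dataclass
class GeneratorConfig:
    """Ground-truth settings for the synthetic study.

    Defaults mirror the real study's scale: ~70 species; whole-clade
    allometric line log(stem area) = 0.60 * log(leaf area) - 4.58 on the
    natural-log scale; OU residual structure; ~10 leaves measured per stem
    with ~15% lognormal measurement noise.
    """

    seed: int = 0
    n_species: int = 70
    birth_rate: float = 1.0
    # allometry truth (log-log line; slope/intercept from the whole-clade fit)
    slope: float = 0.60
    intercept: float = -4.58
    residual_sd: float = 1.0
    residual_alpha: float = 2.0  # OU attraction of the residual, 1/tree-height units
    group_intercepts: dict = field(default_factory=dict)  # group label -> intercept
    shift_branches: dict = field(default_factory=dict)  # node index -> optimum mu
    # predictor (log leaf area) BM truth
    leaf_log_mean: float = 7.0  # ~1100 mm^2 leaves, centre of the observed range
    leaf_bm_rate: float = 2.0
    # specimen-level noise
    leaves_per_stem: int = 10
    specimen_cv: float = 0.15
    # Mk truth
    mk_rate: float = 0.5
    # climate truth
    climate_rho: float = 0.0
    occurrences_per_species: int = 20


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def sim_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips, rescaled
    to unit height."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = rng_for("tree", seed)
    # lineage-based construction: start with 2 lineages, split a random one
    # at each exponential waiting time
    n_nodes = 2 * n_species - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    birth_time = np.zeros(n_nodes)
    root = n_species  # internals occupy n_species .. n_nodes-1; root first
    next_internal = n_species + 1
    next_tip = 0
    t = 0.0
    # active lineages as (provisional id); ids < n_species are tips-to-be
    # we assign: each split consumes one active lineage, creating two
    active: list[int] = []

    # seed the root's two children as pending lineages
    pending = [(root, 0.0), (root, 0.0)]  # (parent, start time)
    lineages = list(pending)
    internal_ids = iter(range(next_internal, n_nodes))
    while len(lineages) < n_species:
        k = len(lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        par, t0 = lineages[i]
        node = next(internal_ids)
        parent[node] = par
        birth_time[node] = t
        lineages[i] = (node, t)
        lineages.append((node, t))
    # final time: one more waiting interval so the last split is internal
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    edge = np.zeros(n_nodes)
    for tip, (par, t0) in enumerate(lineages):
        parent[tip] = par
        edge[tip] = t_end - t0
    for node in range(n_species + 1, n_nodes):
        edge[node] = birth_time[node] - (
            birth_time[parent[node]] if parent[node] != root else 0.0
        )
    labels = [f"sp{str(i + 1).zfill(3)}" for i in range(n_species)]
    tree = PhyloTree(parent, edge, labels)
    # rescale to unit height
    scale = tree.height
    tree = PhyloTree(parent, edge / scale, labels)
    return tree


# ---------------------------------------------------------------------------
# continuous traits
# ---------------------------------------------------------------------------


def _shift_design(tree: PhyloTree, alpha: float, shift_nodes: list[int]) -> np.ndarray:
    """Hansen-model weight matrix W (n_tips x (1 + n_shifts)).

    Column 0 is the ancestral regime; column r is the regime that starts on
    the branch above ``shift_nodes[r-1]`` and paints that clade until a more
    recent shift overrides it.  Tip expectation is W @ mu.  Weights on each
    row sum to 1 (the ancestral optimum absorbs the stationary start).
    """
    n = tree.n_tips
    k = len(shift_nodes)
    W = np.zeros((n, 1 + k))
    shift_set = {node: r + 1 for r, node in enumerate(shift_nodes)}
    T = tree.tip_depths
    for tip in range(n):
        # walk root -> tip collecting (segment start, end, regime)
        path = []
        node = tip
        while node >= 0:
            path.append(node)
            node = tree.parent[node]
        path.reverse()  # root ... tip
        regime = 0
        t0 = 0.0
        Ttip = T[tip]
        for node in path[1:]:
            t1 = tree.node_depth[node]
            if node in shift_set:
                regime = shift_set[node]
            # the regime applies along the branch ending at `node`
            if alpha == 0:
                W[tip, regime] += 0.0
            else:
                W[tip, regime] += np.exp(-alpha * (Ttip - t1)) - np.exp(
                    -alpha * (Ttip - t0)
                )
            t0 = t1
        # stationary start: weight of everything before the root
        if alpha == 0:
            W[tip, 0] = 1.0
        else:
            W[tip, 0] += np.exp(-alpha * Ttip)
    return W


def sim_bm_ou(
    tree: PhyloTree,
    spec: CovarianceSpec,
    seed: int,
    root_mean: float = 0.0,
    shifts: dict[int, float] | None = None,
) -> np.ndarray:
    """Exact multivariate-normal draw of tip values under ``spec``.

    With ``shifts`` (node index -> new optimum, OU only) tip expectations
    follow the regime optima along each lineage (Hansen model); the
    ancestral optimum is ``root_mean``.
    """
    rng = rng_for("bm_ou", seed)
    V = vcv(tree, spec)
    mean = np.full(tree.n_tips, root_mean, dtype=float)
    if shifts:
        if spec.model != "OU":
            raise ValueError("optimum shifts require the OU model")
        nodes = list(shifts)
        W = _shift_design(tree, spec.alpha, nodes)
        mu = np.concatenate([[root_mean], [shifts[nd] for nd in nodes]])
        mean = W @ mu
    # exact draw via eigendecomposition (V may be singular, e.g. rate -> 0)
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(tree.n_tips)
    return mean + U @ (np.sqrt(w) * z)


# ---------------------------------------------------------------------------
# allometry dataset (specimens + species truth)
# ---------------------------------------------------------------------------


def assign_groups_on_clades(
    tree: PhyloTree, labels: tuple[str, ...], seed: int
) -> pd.Series:
    """Paint group labels on the largest non-nested clades so groups are
    phylogenetically clustered, as mutualistic strategies are in the real
    clade.  The first label is the background state."""
    rng = rng_for("misc", seed)
    k = len(labels)
    sizes = {
        node: len(tree.tips_below(node))
        for node in range(tree.n_tips, tree.n_nodes)
        if node != tree.root
    }
    # candidate clades between 10% and 40% of the tips; order shuffled so
    # different seeds paint different (still sizeable) clades
    lo, hi = max(2, tree.n_tips // 10), max(3, int(0.4 * tree.n_tips))
    cands = sorted(
        (n for n, s in sizes.items() if lo <= s <= hi),
        key=lambda n: -sizes[n],
    )
    head = cands[: max(3, len(cands) // 2)]
    rng.shuffle(head)
    cands = head + cands[len(head):]
    assigned = np.zeros(tree.n_tips, dtype=int)
    taken: set[int] = set()
    next_label = 1
    for node in cands:
        if next_label >= k:
            break
        tips = tree.tips_below(node)
        if any(t in taken for t in tips):
            continue
        assigned[tips] = next_label
        taken.update(tips.tolist())
        next_label += 1
    return pd.Series(
        [labels[g] for g in assigned], index=tree.tip_labels, name="group"
    )


def sim_allometry_dataset(
    tree: PhyloTree, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a specimen table and its species-level ground truth.

    Species log leaf area evolves by BM; species log stem cross-sectional
    area is ``intercept + slope * leaf + OU residual`` (group-specific
    intercepts and residual-optimum shifts optional).  Specimens are then
    back-transformed with lognormal measurement noise: ~``leaves_per_stem``
    leaf areas (mm^2) and one stem diameter (mm) per specimen.

    Returns ``(specimens, truth)``: a long-format specimen table (one row
    per measured leaf, stem diameter repeated) and a per-species truth
    table with the generating values and labels.
    """
    rng = rng_for("allometry", config.seed)
    n = tree.n_tips

    leaf = sim_bm_ou(
        tree,
        CovarianceSpec("BM", rate=config.leaf_bm_rate),
        seed=config.seed,
        root_mean=config.leaf_log_mean,
    )
    resid_spec = CovarianceSpec(
        "OU", rate=config.residual_sd**2, alpha=config.residual_alpha / tree.height
    )
    resid = sim_bm_ou(
        tree,
        resid_spec,
        seed=config.seed + 1,
        root_mean=0.0,
        shifts=config.shift_branches or None,
    )

    strategy = assign_groups_on_clades(tree, STRATEGIES, config.seed)
    architecture = assign_groups_on_clades(tree, ARCHITECTURES, config.seed + 17)
    domatium = assign_groups_on_clades(tree, DOMATIUM_GROWTH, config.seed + 29)

    intercepts = np.full(n, config.intercept)
    if config.group_intercepts:
        for i, sp in enumerate(tree.tip_labels):
            g = strategy.loc[sp]
            if g in config.group_intercepts:
                intercepts[i] = config.group_intercepts[g]
    stem = intercepts + config.slope * leaf + resid

    truth = pd.DataFrame(
        {
            "species": tree.tip_labels,
            "log_leaf_area": leaf,
            "log_stem_area": stem,
            "residual_truth": resid,
            "architecture": architecture.values,
            "domatium_growth": domatium.values,
            "strategy": strategy.values,
        }
    )

    sigma = np.sqrt(np.log1p(config.specimen_cv**2))  # lognormal, mean-preserving
    rows = []
    for i, sp in enumerate(tree.tip_labels):
        stem_area = np.exp(stem[i])
        diameter = 2.0 * np.sqrt(stem_area / np.pi)
        d_obs = diameter * np.exp(rng.normal(-sigma**2 / 2, sigma))
        n_leaves = max(1, int(rng.poisson(config.leaves_per_stem)))
        leaf_obs = np.exp(leaf[i]) * np.exp(
            rng.normal(-sigma**2 / 2, sigma, size=n_leaves)
        )
        for la in leaf_obs:
            rows.append(
                {
                    "species": sp,
                    "specimen_id": f"{sp}_v1",
                    "leaf_area_mm2": la,
                    "stem_diameter_mm": d_obs,
                    "architecture": architecture.loc[sp],
                    "domatium_growth": domatium.loc[sp],
                    "strategy": strategy.loc[sp],
                }
            )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# discrete characters
# ---------------------------------------------------------------------------


def _sim_ctmc_branch(
    state: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> tuple[int, list[tuple[float, int]]]:
    """Exact simulation of a CTMC along one branch; returns the end state and
    the change points [(time-from-branch-start, new state), ...]."""
    changes = []
    pos = 0.0
    while True:
        out = -Q[state, state]
        if out <= 0:
            break
        pos += rng.exponential(1.0 / out)
        if pos >= t:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(len(probs), p=probs))
        changes.append((pos, state))
    return state, changes


def sim_discrete(
    tree: PhyloTree,
    rates,
    seed: int,
    coupling: str = "independent",
    root_state: int | None = None,
):
    """Simulate one or two binary characters down the tree.

    ``coupling='independent'``: ``rates`` is a scalar ER rate or a 2x2 Q
    matrix for a single trait — returns ``(tip_states, history)``.
    ``coupling='dependent'``: ``rates`` is the 4x4 joint rate matrix over
    states {(0,0),(0,1),(1,0),(1,1)} with double transitions zero —
    returns ``(tip_states_A, tip_states_B, history)`` where the history is
    over joint states 0..3.

    ``history`` maps node index -> state at that node, plus a ``'branch'``
    entry mapping node -> change-point list along the branch above it.
    """
    rng = rng_for("discrete", seed)
    if coupling == "independent":
        if np.isscalar(rates):
            q = float(rates)
            Q = np.array([[-q, q], [q, -q]])
        else:
            Q = np.asarray(rates, dtype=float)
        nstate = Q.shape[0]
    elif coupling == "dependent":
        Q = np.asarray(rates, dtype=float)
        if Q.shape != (4, 4):
            raise ValueError("dependent coupling needs a 4x4 rate matrix")
        nstate = 4
    else:
        raise ValueError(coupling)
    if root_state is None:
        root_state = int(rng.integers(nstate))

    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = root_state
    branch_changes: dict[int, list[tuple[float, int]]] = {}
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        s0 = node_state[tree.parent[node]]
        s1, changes = _sim_ctmc_branch(s0, tree.edge_length[node], Q, rng)
        node_state[node] = s1
        branch_changes[node] = changes
    history = {"node_states": node_state.copy(), "branch": branch_changes}
    if coupling == "independent":
        return node_state[: tree.n_tips].copy(), history
    joint = node_state[: tree.n_tips]
    return (joint // 2).copy(), (joint % 2).copy(), history


def pagel_rate_matrix(q: np.ndarray | list[float]) -> np.ndarray:
    """Dependent-model 4x4 generator from the eight rates
    (q12, q13, q21, q24, q31, q34, q42, q43) over joint states
    1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1); double transitions are zero."""
    q12, q13, q21, q24, q31, q34, q42, q43 = [float(x) for x in q]
    Q = np.array(
        [
            [0.0, q12, q13, 0.0],
            [q21, 0.0, 0.0, q24],
            [q31, 0.0, 0.0, q34],
            [0.0, q42, q43, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def independent_rate_matrix(a1: float, a2: float, b1: float, b2: float) -> np.ndarray:
    """Independent-model 4x4 generator from per-trait rates: trait A gains
    at a1 and is lost at a2; trait B gains at b1 and is lost at b2 —
    regardless of the other trait's state."""
    # joint states (A,B): 1=(0,0) 2=(0,1) 3=(1,0) 4=(1,1)
    return pagel_rate_matrix([b1, a1, b2, a1, a2, b1, a2, b2])


# ---------------------------------------------------------------------------
# occurrences / climate
# ---------------------------------------------------------------------------

BIOCLIM_COLUMNS = [f"bio{i}" for i in range(1, 20)]

# loosely CHELSA-like scales: temperatures in 0.1 degC, precipitation in mm,
# seasonality dimensionless
_BIO_MEANS = np.array(
    [250, 80, 60, 500, 320, 180, 140, 260, 240, 270, 230, 2500, 350, 60, 45, 80, 40, 700, 400],
    dtype=float,
)
_BIO_SDS = np.array(
    [30, 15, 10, 120, 35, 30, 30, 30, 30, 30, 30, 800, 120, 30, 20, 25, 15, 250, 200],
    dtype=float,
)


def sim_occurrences(
    species: list[str],
    seed: int,
    n_per_species: int = 20,
    correlate_with: np.ndarray | None = None,
    rho: float = 0.0,
    correlated_variable: str = "bio15",
    n_duplicates: int = 0,
    n_zero_coords: int = 0,
) -> pd.DataFrame:
    """Occurrence table with per-species bioclim means plus within-species
    scatter.  ``correlate_with`` (one value per species) induces a
    correlation of ``rho`` between the species mean of
    ``correlated_variable`` and that trait.  Optionally plants exact
    duplicates and (0, 0) coordinate rows for testing the cleaner."""
    rng = rng_for("occurrences", seed)
    n_sp = len(species)
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    species_centers = rng.normal(_BIO_MEANS, _BIO_SDS, size=(n_sp, 19))
    if correlate_with is not None and rho != 0.0:
        z = np.asarray(correlate_with, dtype=float)
        z = (z - z.mean()) / z.std()
        j = BIOCLIM_COLUMNS.index(correlated_variable)
        noise = rng.standard_normal(n_sp)
        species_centers[:, j] = _BIO_MEANS[j] + _BIO_SDS[j] * (
            rho * z + np.sqrt(1 - rho**2) * noise
        )
    rows = []
    for i, sp in enumerate(species):
        lon0 = rng.uniform(130, 170)  # Malesia / SW Pacific
        lat0 = rng.uniform(-20, 5)
        for _ in range(n_per_species):
            row = {
                "species": sp,
                "longitude": np.clip(lon0 + rng.normal(0, 1.5), -180, 180),
                "latitude": np.clip(lat0 + rng.normal(0, 1.5), -90, 90),
            }
            vals = species_centers[i] + rng.normal(0, 0.15 * _BIO_SDS, size=19)
            row.update(dict(zip(BIOCLIM_COLUMNS, vals)))
            rows.append(row)
    df = pd.DataFrame(rows)
    if n_duplicates:
        dup = df.sample(n=n_duplicates, random_state=int(seed) % 2**31)
        df = pd.concat([df, dup], ignore_index=True)
    if n_zero_coords:
        bad = df.sample(n=n_zero_coords, random_state=(int(seed) + 1) % 2**31).copy()
        bad["longitude"] = 0.0
        bad["latitude"] = 0.0
        df = pd.concat([df, bad], ignore_index=True)
    return df.reset_index(drop=True)
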