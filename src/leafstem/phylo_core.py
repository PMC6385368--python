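"""Rooted, dated phylogenies and phylogenetic covariance construction.

The tree is the covariance scaffold for every comparative model in this
package: generalized least squares, the nine continuous-trait models,
Mk discrete-character models and the bivariate random walk all reduce to
multivariate-normal (or Markov-chain) computations whose structure is read
off the tree.  :class:`PhyloTree` stores the tree in flat arrays (parent
pointers, branch lengths, a postorder) so that likelihood code can work
with plain numpy.

Newick parsing is delegated to dendropy; everything downstream of the
parse lives here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CovarianceSpec",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "vcv",
    "anc_state_continuous",
    "NewickError",
]

#: models accepted by :class:`CovarianceSpec`
CONTINUOUS_MODELS = (
    "BM",
    "OU",
    "EB",
    "trend",
    "lambda",
    "kappa",
    "delta",
    "drift",
    "white",
)

ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Malformed Newick input or violated tree invariants."""


class PhyloTree:
    """A rooted tree with branch lengths, held in flat arrays.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``,
    in the order ``tip_labels`` lists them) followed by internal nodes; the
    root is the last index.  ``parent[root] == -1`` and
    ``edge_length[root] == 0``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        tip_labels: Sequence[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        self._validate()
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0:
                self.children[p].append(node)
        self.postorder = self._postorder()
        # depth = time from root
        self.node_depth = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            p = self.parent[node]
            if p >= 0:
                self.node_depth[node] = self.node_depth[p] + self.edge_length[node]
        self._mrca_depth_cache: np.ndarray | None = None

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        if len(self.edge_length) != self.n_nodes:
            raise NewickError("parent and edge_length lengths differ")
        if len(set(self.tip_labels)) != self.n_tips:
            dupes = sorted(
                {x for x in self.tip_labels if self.tip_labels.count(x) > 1}
            )
            raise NewickError(f"duplicate tip labels: {dupes}")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.edge_length < 0):
            raise NewickError("negative branch length")

    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()  # children before parents
        if len(order) != self.n_nodes:
            raise NewickError("tree is not connected")
        return np.asarray(order, dtype=np.int64)

    # -- basic queries --------------------------------------------------

    @property
    def tip_depths(self) -> np.ndarray:
        return self.node_depth[: self.n_tips]

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance (tree height, in the tree's time units)."""
        return float(self.tip_depths.max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths
        h = d.max()
        return bool(h == 0 or np.all(np.abs(d - h) <= rtol * h))

    def tips_below(self, node: int) -> np.ndarray:
        """Indices of tips in the clade subtended by ``node``."""
        out = []
        stack = [node]
        while stack:
            k = stack.pop()
            if k < self.n_tips:
                out.append(k)
            stack.extend(self.children[k])
        return np.asarray(sorted(out), dtype=np.int64)

    def clade_tipsets(self) -> dict[int, frozenset[str]]:
        """Map node index -> frozenset of subtended tip labels (node identity
        across trees with shared taxa)."""
        sets: dict[int, frozenset[str]] = {}
        tmp: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder:
            if node < self.n_tips:
                tmp[node] = {self.tip_labels[node]}
            else:
                for c in self.children[node]:
                    tmp[node] |= tmp[c]
            sets[node] = frozenset(tmp[node])
        return sets

    def mrca_depth_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of the depth (time from root) of each pair's
        MRCA — the shared root-to-MRCA path length, i.e. the BM covariance
        at unit rate."""
        if self._mrca_depth_cache is None:
            self._mrca_depth_cache = self._depth_functional(self.node_depth)
            self._mrca_depth_cache.setflags(write=False)
        return self._mrca_depth_cache

    def _depth_functional(self, depth: np.ndarray) -> np.ndarray:
        """Shared-path matrix for arbitrary per-node 'depths' (used by the
        kappa transform, which recomputes depths from transformed branch
        lengths while keeping the MRCA structure)."""
        n = self.n_tips
        out = np.zeros((n, n))
        for node in self.postorder:
            if node < n:
                out[node, node] = depth[node]
                continue
            groups = [self.tips_below(c) for c in self.children[node]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    out[np.ix_(groups[a], groups[b])] = depth[node]
                    out[np.ix_(groups[b], groups[a])] = depth[node]
        return out

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path lengths between tips."""
        t = self.mrca_depth_matrix()
        d = self.tip_depths
        return d[:, None] + d[None, :] - 2.0 * t

    def tip_index(self, labels: Sequence[str]) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.tip_labels)}
        missing = [x for x in labels if x not in lookup]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        return np.asarray([lookup[x] for x in labels], dtype=np.int64)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else (lf.label or "") for lf in leaves]
    if any(not lab for lab in labels):
        raise NewickError("unlabelled tip")
    internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    index = {id(nd): i for i, nd in enumerate(leaves)}
    for j, nd in enumerate(internals):
        index[id(nd)] = len(leaves) + j
    n_nodes = len(leaves) + len(internals)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    edge = np.zeros(n_nodes)
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above node {i}")
            edge[i] = float(nd.edge.length)
    return PhyloTree(parent, edge, labels)


def read_newick(text: str) -> PhyloTree:
    """Parse one Newick tree (branch lengths mandatory except at the root;
    internal labels are ignored; quoted labels supported)."""
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"could not parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: PhyloTree, include_root_length: bool = False) -> str:
    """Serialize to Newick (labels quoted only when needed)."""

    def quote(lab: str) -> str:
        if any(c in lab for c in "(),:;[] \t'"):
            return "'" + lab.replace("'", "''") + "'"
        return lab

    def rec(node: int) -> str:
        if node < tree.n_tips:
            core = quote(tree.tip_labels[node])
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[node]) + ")"
        if node == tree.root and not include_root_length:
            return core
        return f"{core}:{tree.edge_length[node]:.12g}"

    return rec(tree.root) + ";"


def prune_to_taxa(tree: PhyloTree, keep: Sequence[str]) -> PhyloTree:
    """Restrict the tree to ``keep``, collapsing degree-2 nodes so that all
    pairwise path lengths among retained tips are preserved."""
    keep = list(dict.fromkeys(keep))
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    tree.tip_index(keep)  # raises on unknown labels
    keep_set = set(keep)

    # number of retained tips below each node
    count = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.postorder:
        if node < tree.n_tips:
            count[node] = 1 if tree.tip_labels[node] in keep_set else 0
        else:
            count[node] = sum(count[c] for c in tree.children[node])

    # new root = MRCA of kept tips: deepest node with all kept tips below
    new_root = tree.root
    total = count[tree.root]
    while True:
        heirs = [c for c in tree.children[new_root] if count[c] == total]
        if heirs and count[heirs[0]] == total and len(heirs) == 1:
            new_root = heirs[0]
        else:
            break

    new_parent: list[int] = []
    new_edge: list[float] = []
    new_labels: list[str] = []
    node_map: dict[int, int] = {}

    def build(node: int, acc_len: float, parent_new: int) -> None:
        kids = [c for c in tree.children[node] if count[c] > 0]
        is_tip = node < tree.n_tips
        if not is_tip and len(kids) == 1 and node != new_root:
            # degree-2 internal: splice out, summing branch lengths
            build(kids[0], acc_len + tree.edge_length[kids[0]], parent_new)
            return
        idx = len(new_parent)
        node_map[node] = idx
        new_parent.append(parent_new)
        new_edge.append(acc_len)
        new_labels.append(tree.tip_labels[node] if is_tip else "")
        for c in kids:
            build(c, tree.edge_length[c], idx)

    build(new_root, 0.0, -1)

    # renumber: tips first (in original tip order), internals after, root last
    order = sorted(
        range(len(new_parent)),
        key=lambda i: (new_labels[i] == "", -1 if new_parent[i] != -1 else 1),
    )
    tips = [i for i in range(len(new_parent)) if new_labels[i]]
    internals = [i for i in range(len(new_parent)) if not new_labels[i]]
    internals.sort(key=lambda i: new_parent[i] != -1, reverse=True)  # root last
    order = tips + internals
    remap = {old: new for new, old in enumerate(order)}
    parent2 = [remap[new_parent[i]] if new_parent[i] >= 0 else -1 for i in order]
    edge2 = [new_edge[i] for i in order]
    labels2 = [new_labels[i] for i in order if new_labels[i]]
    return PhyloTree(parent2, edge2, labels2)


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------


@dataclass
class CovarianceSpec:
    """A continuous-trait covariance model on the tree.

    Parameters
    ----------
    model:
        One of BM, OU, EB, trend, lambda, kappa, delta, drift, white.
    rate:
        Diffusion rate sigma^2 (BM-family) or stationary variance (OU, white).
    alpha:
        OU attraction rate toward the optimum (>= 0).
    ebrate:
        Early-burst exponential rate-change parameter (typically < 0).
    lam, kappa, delta:
        The branch-length / node-depth transforms of Pagel's lambda,
        kappa and delta.
    slope:
        Linear time trend: for ``trend`` the diffusion rate changes as
        sigma^2 (1 + slope * t); for ``drift`` the mean changes as
        mu + slope * t (handled by the mean model, not the covariance).
    stationary:
        OU only.  ``True`` gives the stationary covariance
        rate * exp(-alpha * d_ij) (unit rate = the Martins-Hansen
        correlation used as the PGLS error structure); ``False`` gives the
        fixed-root form rate * exp(-alpha*d_ij) * (1 - exp(-2*alpha*t_ij))
        / (2*alpha), which tends to BM as alpha -> 0 and is the form used
        for the nine-model likelihood comparison.
    """

    model: str
    rate: float = 1.0
    alpha: float = 1.0
    ebrate: float = -1.0
    lam: float = 1.0
    kappa: float = 1.0
    delta: float = 1.0
    slope: float = 0.0
    stationary: bool = True

    def __post_init__(self) -> None:
        if self.model not in CONTINUOUS_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.rate <= 0:
            raise ValueError("diffusion rate must be > 0")
        if self.alpha < 0:
            raise ValueError("OU attraction rate must be >= 0")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def _check_psd(V: np.ndarray, tol: float = 1e-10) -> None:
    w = np.linalg.eigvalsh((V + V.T) / 2.0)
    if w.min() < -tol * max(1.0, w.max()):
        raise np.linalg.LinAlgError(
            f"covariance not positive semi-definite (min eigenvalue {w.min():.3g})"
        )


def ou_correlation(tree: PhyloTree, alpha: float) -> np.ndarray:
    """Martins–Hansen OU correlation matrix exp(-alpha * d_ij) with unit
    variance — the standard OU error structure for GLS on ultrametric trees."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return np.exp(-alpha * tree.patristic_matrix())


def vcv(tree: PhyloTree, spec: CovarianceSpec) -> np.ndarray:
    """Tip covariance matrix implied by ``spec`` on ``tree``.

    BM entry (i, j) is the shared root-to-MRCA path length times the rate;
    OU uses the stationary form rate * exp(-alpha * d_ij); lambda scales BM
    off-diagonals; kappa/delta/EB transform branch lengths or node depths;
    white is diagonal.  The result is checked for positive semi-definiteness.
    """
    t = tree.mrca_depth_matrix()
    m = spec.model
    if m == "BM" or m == "drift":
        V = spec.rate * t
    elif m == "OU":
        d = tree.patristic_matrix()
        if spec.stationary:
            V = spec.rate * np.exp(-spec.alpha * d)
        elif spec.alpha < 1e-10:
            V = spec.rate * t
        else:
            a = spec.alpha
            V = spec.rate * np.exp(-a * d) * (-np.expm1(-2.0 * a * t)) / (2.0 * a)
    elif m == "EB":
        r = spec.ebrate
        if abs(r) < 1e-12:
            V = spec.rate * t
        else:
            V = spec.rate * (np.expm1(r * t) / r)
    elif m == "trend":
        h = tree.height
        s = spec.slope
        if h > 0 and s < -1.0 / h:
            raise ValueError("trend slope makes the rate negative inside the tree")
        V = spec.rate * (t + 0.5 * s * t**2)
    elif m == "lambda":
        V = spec.rate * t.copy()
        off = ~np.eye(tree.n_tips, dtype=bool)
        V[off] *= spec.lam
    elif m == "kappa":
        depth_k = np.zeros(tree.n_nodes)
        for node in tree.postorder[::-1]:
            p = tree.parent[node]
            if p >= 0:
                depth_k[node] = depth_k[p] + tree.edge_length[node] ** spec.kappa
        V = spec.rate * tree._depth_functional(depth_k)
    elif m == "delta":
        V = spec.rate * t**spec.delta
    elif m == "white":
        V = spec.rate * np.eye(tree.n_tips)
    else:  # pragma: no cover
        raise ValueError(m)
    _check_psd(V)
    return V


def vcv_to_csv(tree: PhyloTree, V: np.ndarray, path) -> None:
    import pandas as pd

    pd.DataFrame(V, index=tree.tip_labels, columns=tree.tip_labels).to_csv(path)


def warn_if_unidentifiable(tree: PhyloTree, model: str) -> None:
    if model in ("trend", "drift") and tree.is_ultrametric():
        warnings.warn(
            f"model {model!r} is not identifiable from BM on an ultrametric tree",
            UserWarning,
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# Continuous ancestral states (BM / GLS)
# ---------------------------------------------------------------------------


def anc_state_continuous(
    tree: PhyloTree, trait: np.ndarray | dict[str, float]
) -> np.ndarray:
    """Maximum-likelihood (GLS) ancestral-state estimates under Brownian
    motion, for every node.

    Returns a length-``n_nodes`` array: observed values at tips, GLS
    estimates at internal nodes; the root entry equals the GLS mean.
    Uses the two-pass message-passing algorithm (upward conditional means,
    downward combination), equivalent to solving the node-augmented GLS
    system.
    """
    if isinstance(trait, dict):
        y = np.asarray([trait[lab] for lab in tree.tip_labels], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValueError("need exactly one trait value per tip")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")

    n = tree.n_nodes
    # upward pass: x_up[k], v_up[k] = conditional mean and variance of node k
    # given the tips below it (variance in branch-length units)
    x_up = np.zeros(n)
    v_up = np.zeros(n)
    extra = np.zeros(n)  # effective extra branch length after collapsing below
    for node in tree.postorder:
        if node < tree.n_tips:
            x_up[node] = y[node]
            v_up[node] = 0.0
        else:
            ws, xs = [], []
            for c in tree.children[node]:
                bl = tree.edge_length[c] + v_up[c]
                ws.append(1.0 / bl if bl > 0 else np.inf)
                xs.append(x_up[c])
            ws = np.asarray(ws)
            xs = np.asarray(xs)
            if np.any(np.isinf(ws)):
                # zero-length branch to a known value: node pinned
                pin = xs[np.isinf(ws)]
                x_up[node] = pin[0]
                v_up[node] = 0.0
            else:
                W = ws.sum()
                x_up[node] = float(ws @ xs) / W
                v_up[node] = 1.0 / W

    # downward pass: combine the upward message with the message from the
    # rest of the tree through the parent
    x_dn = np.zeros(n)  # mean from "above" (complement of the subtree)
    v_dn = np.full(n, np.inf)
    est = np.zeros(n)
    for node in tree.postorder[::-1]:
        if node == tree.root:
            est[node] = x_up[node]
            continue
        p = tree.parent[node]
        # parent's info excluding this child's upward message
        ws, xs = [], []
        for c in tree.children[p]:
            if c == node:
                continue
            bl = tree.edge_length[c] + v_up[c]
            ws.append(1.0 / bl)
            xs.append(x_up[c])
        if np.isfinite(v_dn[p]):
            ws.append(1.0 / v_dn[p])
            xs.append(x_dn[p])
        ws = np.asarray(ws)
        xs = np.asarray(xs)
        W = ws.sum()
        x_above = float(ws @ xs) / W
        v_above = 1.0 / W + tree.edge_length[node]
        x_dn[node] = x_above
        v_dn[node] = v_above
        if node < tree.n_tips:
            est[node] = y[node]
        else:
            wa, wb = 1.0 / v_above, (1.0 / v_up[node] if v_up[node] > 0 else np.inf)
            if np.isinf(wb):
                est[node] = x_up[node]
            else:
                est[node] = (wa * x_above + wb * x_up[node]) / (wa + wb)
    return est
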