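"""Phylogenetic comparative methods on rooted branch-length trees.

Ancestral reconstruction uses squared-change parsimony weighted by branch
lengths: internal states minimize the sum over edges of (state change)^2 /
branch length.  The minimizer is the solution of a sparse Laplacian system and
is point-identical to the generalized-least-squares (Brownian motion) ancestral
state estimates, which is why a single solver serves both the parsimony and the
model-based framing.  Uncertainty for a univariate trait comes from the
conditional Gaussian distribution of internal nodes given the tips: precision
matrix = the internal-internal block of the branch-length-weighted graph
Laplacian, scaled by the Brownian rate sigma^2 (REML by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

logger = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """Rooted tree stored as parent pointers in preorder.

    ``parent[i]`` is the index of node ``i``'s parent (-1 for the root, node 0);
    ``lengths[i]`` the branch above node ``i`` (NaN at the root); ``labels[i]``
    the taxon name for tips (None for unlabeled internal nodes).
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list[Optional[str]]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.sum(self.parent < 0) != 1 or self.parent[0] != -1:
            raise ValueError("exactly one root expected, stored at index 0")
        if np.any(self.parent[1:] >= np.arange(1, self.n_nodes)):
            raise ValueError("nodes must be in preorder (parent before child)")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("branch lengths must be nonnegative")
        tips = self.tip_indices()
        names = [self.labels[i] for i in tips]
        if any(n is None for n in names):
            bad = [i for i in tips if self.labels[i] is None]
            raise ValueError(f"unlabeled tips at node indices {bad}")
        if len(set(names)) != len(names):
            raise ValueError("tip labels are not unique")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def tip_indices(self) -> list[int]:
        has_child = np.zeros(self.n_nodes, bool)
        has_child[self.parent[self.parent >= 0]] = True
        return [i for i in range(self.n_nodes) if not has_child[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    def height(self) -> float:
        return float(np.max(self.depths()))

    def to_newick(self) -> str:
        ch = self.children()

        def fmt(i: int) -> str:
            if ch[i]:
                inner = ",".join(fmt(c) for c in ch[i])
                lab = self.labels[i] or ""
                s = f"({inner}){lab}"
            else:
                s = self.labels[i] or ""
            if i != 0:
                s += f":{float(self.lengths[i])!r}"
            return s

        return fmt(0) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        missing = []
        for i, node in enumerate(nodes):
            parent.append(-1 if node.parent_node is None else index[id(node.parent_node)])
            if node.parent_node is None:
                lengths.append(np.nan)
            else:
                if node.edge.length is None:
                    name = node.taxon.label if node.taxon else f"node{i}"
                    missing.append(name)
                    lengths.append(np.nan)
                else:
                    lengths.append(float(node.edge.length))
            labels.append(node.taxon.label if node.taxon else None)
        if missing:
            raise ValueError(f"branch lengths missing for nodes: {missing}")
        return cls(np.array(parent), np.array(lengths), labels)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels))


@dataclass
class AncestralReconstruction:
    """Ancestral states plus Brownian-rate-based uncertainty.

    ``node_states`` covers every node (tips hold their observed values);
    ``internal_indices`` lists which rows are reconstructed.  ``node_variances``
    are unit-rate conditional variances (multiply by ``sigma2`` per trait);
    ``ci95`` is states +/- 1.96 * sqrt(sigma2 * variance) where available.
    """

    node_states: np.ndarray  # n_nodes x n_traits
    internal_indices: list[int]
    sigma2: Optional[np.ndarray] = None  # per trait
    node_variances: Optional[np.ndarray] = None  # n_nodes, unit-rate scale
    ci95: Optional[np.ndarray] = None  # n_nodes x n_traits x 2
    tip_order: list[str] = field(default_factory=list)


def _effective_lengths(tree: Phylogeny) -> np.ndarray:
    """Branch lengths with zeros replaced by a small fraction of tree height."""
    lengths = tree.lengths.copy()
    zero = np.where(lengths[1:] == 0)[0] + 1
    if zero.size:
        eps = 1e-8 * max(tree.height(), 1.0)
        lengths[zero] = eps
        logger.info("replaced %d zero-length branches by %.3g", zero.size, eps)
    return lengths


def _laplacian(tree: Phylogeny) -> scipy.sparse.csr_matrix:
    lengths = _effective_lengths(tree)
    n = tree.n_nodes
    rows, cols, vals = [], [], []
    for i in range(1, n):
        w = 1.0 / lengths[i]
        p = tree.parent[i]
        rows += [i, p, i, p]
        cols += [i, p, p, i]
        vals += [w, w, -w, -w]
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def prune_to_taxa(tree: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    """Induced subtree on ``keep``; unifurcations are collapsed additively.

    Root-to-tip path lengths of kept tips are preserved (a unary root keeps its
    stem branch rather than being collapsed away).
    """
    tip_idx = {tree.labels[i]: i for i in tree.tip_indices()}
    unknown = [t for t in keep if t not in tip_idx]
    if unknown:
        raise ValueError(f"taxa not in tree: {unknown}")
    keep_set = set(keep)

    ch = tree.children()
    # retained[i]: subtree below i contains a kept tip
    retained = np.zeros(tree.n_nodes, bool)
    for i in range(tree.n_nodes - 1, -1, -1):
        if not ch[i]:
            retained[i] = tree.labels[i] in keep_set
        else:
            retained[i] = any(retained[c] for c in ch[i])

    new_parent: list[int] = []
    new_lengths: list[float] = []
    new_labels: list[Optional[str]] = []

    def build(i: int, parent_new: int, carried: float) -> None:
        kept_children = [c for c in ch[i] if retained[c]] if ch[i] else []
        is_tip = not ch[i]
        length = carried + (0.0 if i == 0 else tree.lengths[i])
        if not is_tip and len(kept_children) == 1 and parent_new != -1:
            # unifurcation below the root: merge lengths additively
            build(kept_children[0], parent_new, length)
            return
        idx = len(new_parent)
        new_parent.append(parent_new)
        new_lengths.append(np.nan if parent_new == -1 else length)
        new_labels.append(tree.labels[i])
        for c in kept_children:
            build(c, idx, 0.0)

    build(0, -1, 0.0)
    return Phylogeny(np.array(new_parent), np.array(new_lengths), new_labels)


def _align_tip_values(
    tree: Phylogeny, tip_values, trait_names=None
) -> tuple[np.ndarray, list[str]]:
    """Return (n_tips x n_traits array in tree tip order, tip order)."""
    import pandas as pd

    order = tree.tip_labels
    if isinstance(tip_values, pd.DataFrame):
        missing = [t for t in order if t not in tip_values.index]
        if missing:
            raise ValueError(f"tip values missing for taxa: {missing}")
        arr = tip_values.loc[order].to_numpy(dtype=float)
    elif isinstance(tip_values, dict):
        missing = [t for t in order if t not in tip_values]
        if missing:
            raise ValueError(f"tip values missing for taxa: {missing}")
        arr = np.array([np.atleast_1d(tip_values[t]) for t in order], dtype=float)
    else:
        arr = np.asarray(tip_values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != len(order):
            raise ValueError(
                f"{arr.shape[0]} trait rows for {len(order)} tips; "
                "pass a DataFrame/dict keyed by taxon to disambiguate"
            )
    return arr, order


def squared_change_parsimony(tree: Phylogeny, tip_values) -> AncestralReconstruction:
    """Branch-length-weighted squared-change parsimony ancestral states.

    Minimizes sum_edges (x_child - x_parent)^2 / length independently per
    trait; equivalently the Brownian-motion GLS point estimates.
    """
    values, order = _align_tip_values(tree, tip_values)
    tips = tree.tip_indices()
    internal = [i for i in range(tree.n_nodes) if i not in set(tips)]
    states = np.zeros((tree.n_nodes, values.shape[1]))
    states[tips, :] = values
    if internal:
        Q = _laplacian(tree).tocsc()
        Qii = Q[np.ix_(internal, internal)]
        Qit = Q[np.ix_(internal, tips)]
        rhs = -Qit @ values
        sol = scipy.sparse.linalg.spsolve(Qii.tocsc(), rhs)
        states[internal, :] = np.atleast_2d(sol).reshape(len(internal), -1)
    return AncestralReconstruction(
        node_states=states, internal_indices=internal, tip_order=order
    )


def scp_objective(tree: Phylogeny, states: np.ndarray) -> float:
    """The weighted squared-change criterion at a full node-state assignment."""
    lengths = _effective_lengths(tree)
    total = 0.0
    for i in range(1, tree.n_nodes):
        diff = states[i] - states[tree.parent[i]]
        total += float(np.sum(diff**2)) / lengths[i]
    return total


def _tip_covariance(tree: Phylogeny) -> np.ndarray:
    """Shared root-to-tip path lengths (unit-rate BM tip covariance)."""
    tips = tree.tip_indices()
    lengths = _effective_lengths(tree)
    n = len(tips)
    # ancestor chains with cumulative depths
    depths = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        depths[i] = depths[tree.parent[i]] + lengths[i]
    chains = []
    for t in tips:
        chain = []
        j = t
        while j != -1:
            chain.append(j)
            j = tree.parent[j]
        chains.append(set(chain))
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            shared = chains[a] & chains[b]
            # deepest shared ancestor
            mrca = max(shared, key=lambda j: depths[j])
            C[a, b] = C[b, a] = depths[mrca]
    for a in range(n):
        C[a, a] = depths[tips[a]]
    return C


def brownian_rate(tree: Phylogeny, tip_values, method: str = "reml") -> np.ndarray:
    """Estimate the Brownian rate sigma^2 per trait by REML (default) or ML."""
    if tree.n_tips <= 2:
        raise ValueError("sigma^2 not estimable with 2 or fewer tips")
    values, _ = _align_tip_values(tree, tip_values)
    C = _tip_covariance(tree)
    Cinv = np.linalg.inv(C)
    one = np.ones(C.shape[0])
    denom = one @ Cinv @ one
    n = C.shape[0]
    out = []
    for j in range(values.shape[1]):
        y = values[:, j]
        mu = (one @ Cinv @ y) / denom
        r = y - mu
        q = r @ Cinv @ r
        out.append(q / (n - 1) if method == "reml" else q / n)
    return np.array(out)


def phenogram95(
    tree: Phylogeny, tip_values, method: str = "reml"
) -> AncestralReconstruction:
    """Ancestral states for one trait with 95% conditional intervals.

    sigma^2 is estimated under Brownian motion (REML by default); conditional
    variances of internal nodes given the tips come from inverting the
    internal block of the weighted graph Laplacian.  Tips get zero-width
    intervals.  Plotting node states against node depth with these intervals
    gives the classic 95% phenogram.
    """
    values, order = _align_tip_values(tree, tip_values)
    if values.shape[1] != 1:
        raise ValueError("phenogram95 is univariate; pass a single trait")
    rec = squared_change_parsimony(tree, values)
    sigma2 = brownian_rate(tree, values, method=method)
    tips = set(tree.tip_indices())
    internal = rec.internal_indices
    variances = np.zeros(tree.n_nodes)
    if internal:
        Q = _laplacian(tree).tocsc()
        Qii = Q[np.ix_(internal, internal)].toarray()
        variances[internal] = np.diag(np.linalg.inv(Qii))
    half = 1.96 * np.sqrt(sigma2[None, :] * variances[:, None])
    ci = np.stack([rec.node_states - half, rec.node_states + half], axis=-1)
    rec.sigma2 = sigma2
    rec.node_variances = variances
    rec.ci95 = ci
    rec.tip_order = order
    return rec


def phylomorphospace(tree: Phylogeny, tip_scores) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Place internal nodes in a 2-D ordination by squared-change parsimony.

    Returns (node_coordinates: n_nodes x 2, edges as (parent, child) index
    pairs) ready for plotting a phylogeny over a morphospace.
    """
    values, _ = _align_tip_values(tree, tip_scores)
    if values.shape[1] != 2:
        raise ValueError("phylomorphospace requires exactly 2 score dimensions")
    rec = squared_change_parsimony(tree, values)
    edges = [(int(tree.parent[i]), i) for i in range(1, tree.n_nodes)]
    return rec.node_states, edges
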