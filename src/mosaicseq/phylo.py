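"""Kimura two-parameter distances, neighbor-joining and bootstrap supports.

The distance/NJ/bootstrap chain is implemented here directly (it is the
inferential core of the package); dendropy supplies only the tree container
and Newick serialization.  Ambiguous columns are removed pairwise: each
sequence pair keeps exactly the columns where both sequences carry an
unambiguous A/C/G/T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

PURINES = frozenset(b"AG")
PYRIMIDINES = frozenset(b"CT")


class SaturationError(ValueError):
    """Distance undefined: observed divergence at or beyond model saturation."""


@dataclass(frozen=True)
class SubstitutionCounts:
    P: float  # transition proportion
    Q: float  # transversion proportion
    n: int    # compared sites after pairwise deletion

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("no comparable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("invalid substitution proportions")


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("nonzero diagonal")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and nonnegative")


def count_substitutions(a: str, b: str) -> SubstitutionCounts:
    """Transition/transversion proportions with pairwise deletion.

    Columns where either sequence has a gap or a non-ACGT symbol are
    excluded before counting.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    x = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(x, acgt) & np.isin(y, acgt)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no unambiguous columns shared by the pair")
    x, y = x[valid], y[valid]
    diff = x != y
    purine = np.isin(x, np.frombuffer(b"AG", dtype=np.uint8))
    purine_y = np.isin(y, np.frombuffer(b"AG", dtype=np.uint8))
    transitions = int((diff & (purine == purine_y)).sum())
    transversions = int((diff & (purine != purine_y)).sum())
    return SubstitutionCounts(P=transitions / n, Q=transversions / n, n=n)


def k2p_distance(c: SubstitutionCounts) -> float:
    """Kimura (1980) two-parameter distance in substitutions per site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
    """
    arg1 = 1.0 - 2.0 * c.P - c.Q
    arg2 = 1.0 - 2.0 * c.Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"saturated pair (P={c.P:.4f}, Q={c.Q:.4f}): log argument <= 0"
        )
    return -0.5 * np.log(arg1) - 0.25 * np.log(arg2)


def k2p_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances over an aligned sequence set."""
    labels = list(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = count_substitutions(sequences[labels[i]], sequences[labels[j]])
            d[i, j] = d[j, i] = k2p_distance(c)
    return DistanceMatrix(labels, d)


def nj_build(D: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining (Saitou & Nei) with deterministic ties.

    Q-criterion join selection; the joined pair's branch lengths follow the
    usual rate-corrected formulas, negative lengths are clamped to zero with
    the deficit moved to the sister edge; ties in Q are broken by the lowest
    (i, j) index pair.  Returns an unrooted tree (trifurcating seed node).
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lbl)) for lbl in D.labels]
    d = D.d.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        nonlocal d, active, nodes
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        i, j = active[i_pos], active[j_pos]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        nodes.append(parent)
        new_row = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        active.remove(i)
        active.remove(j)
        active.append(k)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i_pos in range(m):
            for j_pos in range(i_pos + 1, m):
                val = q[i_pos, j_pos]
                if best is None or val < best[0] - 1e-12:
                    best = (val, i_pos, j_pos)
        _, i_pos, j_pos = best
        dij = sub[i_pos, j_pos]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        join(i_pos, j_pos, li, dij - li)

    # final three nodes joined at a trifurcation: three-point formulas
    i, j, k = active
    root = dendropy.Node()
    lx = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    ly = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lz = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, length in ((nodes[i], lx), (nodes[j], ly), (nodes[k], lz)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_total_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths."""
    return float(sum(e.length for e in tree.edges() if e.length is not None))


def _bipartitions(tree: dendropy.Tree, all_labels: frozenset) -> set:
    """Internal bipartitions as frozensets of labels (side without the
    lexicographically first label, making the encoding orientation-free)."""
    ref = min(all_labels)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_labels) - 2:
            continue
        if ref in side:
            side = all_labels - side
        bips.add(side)
    return bips


def bootstrap_support(
    alignment: Mapping[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree on K2P distances with bootstrap supports on internal edges.

    Columns are resampled with replacement; each original internal
    bipartition's support is the percentage of replicate trees containing
    it, stored as the integer label of the child node of that edge.  With
    fewer than four taxa there are no internal edges and supports are left
    unset.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = list(alignment)
    tree = nj_build(k2p_matrix(alignment))
    if len(labels) < 4:
        return tree
    all_labels = frozenset(labels)
    ref = min(all_labels)
    counts: Dict[frozenset, int] = {}
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must share one length")
    ncol = lengths.pop()
    arrays = {
        l: np.frombuffer(alignment[l].upper().encode(), dtype="S1")
        for l in labels
    }
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(ncol, size=ncol)
        resampled = {l: arrays[l][cols].tobytes().decode() for l in labels}
        try:
            rep_tree = nj_build(k2p_matrix(resampled))
        except (SaturationError, ValueError):
            continue  # replicate uninformative; counts toward the denominator
        for bip in _bipartitions(rep_tree, all_labels):
            counts[bip] = counts.get(bip, 0) + 1
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_labels) - 2:
            continue
        key = all_labels - side if ref in side else side
        support = 100.0 * counts.get(key, 0) / n_replicates
        node.label = str(int(round(support)))
    return tree
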