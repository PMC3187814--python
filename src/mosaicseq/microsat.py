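"""Microsatellite chord distances and midpoint-rooted clustering.

Strains are described by per-locus allele multisets (12 loci by default).
Aneuploid loci are first reduced to two alleles by uniform random discard
("diploidization"), within-strain allele frequencies are then 1.0 for a
homozygote and 0.5/0.5 for a heterozygote, and the Cavalli-Sforza & Edwards
chord distance is averaged over the loci scored in both strains, which
keeps strains with different locus coverage comparable.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .phylo import DistanceMatrix, nj_build

Profile = Mapping[str, Tuple[int, ...]]

SQRT2 = float(np.sqrt(2.0))


def diploidize(profile: Profile, seed: int = 0) -> Dict[str, Tuple[int, ...]]:
    """Reduce every locus with more than two alleles to exactly two.

    The surviving pair is chosen uniformly at random among the observed
    alleles; loci already carrying one or two alleles pass unchanged.
    Idempotent: a diploid profile is returned as-is.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, Tuple[int, ...]] = {}
    for locus in sorted(profile):
        alleles = tuple(profile[locus])
        if not alleles:
            raise ValueError(f"locus {locus} has no alleles")
        if len(alleles) > 2:
            keep = sorted(rng.choice(len(alleles), size=2, replace=False))
            alleles = tuple(alleles[k] for k in keep)
        out[locus] = alleles
    return out


def _frequencies(alleles: Sequence[int]) -> Dict[int, float]:
    freqs: Dict[int, float] = {}
    for a in alleles:
        freqs[a] = freqs.get(a, 0.0) + 1.0 / len(alleles)
    return freqs


def chord_distance(x: Profile, y: Profile) -> float:
    """Cavalli-Sforza & Edwards chord distance averaged over shared loci.

    Per shared locus l:  d_l^2 = 2 (1 - sum_a sqrt(x_la * y_la));
    D = sqrt(mean_l d_l^2).  Loci missing in either strain are excluded.
    Bounded by sqrt(2), attained when the strains share no allele at any
    shared locus.
    """
    shared = sorted(set(x) & set(y))
    if not shared:
        raise ValueError("no locus scored in both strains")
    total = 0.0
    for locus in shared:
        fx = _frequencies(x[locus])
        fy = _frequencies(y[locus])
        s = sum(np.sqrt(fx[a] * fy[a]) for a in set(fx) & set(fy))
        total += 2.0 * max(1.0 - s, 0.0)
    return float(np.sqrt(total / len(shared)))


def chord_distance_matrix(
    profiles: Mapping[str, Profile], seed: int = 0
) -> DistanceMatrix:
    """Diploidize all strains (seeded) and compute all pairwise distances."""
    strains = sorted(profiles)
    rng = np.random.default_rng(seed)
    dip = {
        s: diploidize(profiles[s], seed=int(rng.integers(2**31)))
        for s in strains
    }
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = chord_distance(dip[strains[i]], dip[strains[j]])
    return DistanceMatrix(strains, d)


def _leaf_by_label(tree: dendropy.Tree) -> Dict[str, dendropy.Node]:
    return {l.taxon.label: l for l in tree.leaf_node_iter()}


def _path(leaf_a: dendropy.Node, leaf_b: dendropy.Node):
    """Ordered list of (edge, toward_parent) steps from leaf_a to leaf_b."""
    ancestors_a = []
    node = leaf_a
    while node is not None:
        ancestors_a.append(node)
        node = node.parent_node
    index_a = {id(n): k for k, n in enumerate(ancestors_a)}
    up_b = []
    node = leaf_b
    while id(node) not in index_a:
        up_b.append(node)
        node = node.parent_node
    mrca_pos = index_a[id(node)]
    steps = [(n.edge, True) for n in ancestors_a[:mrca_pos]]
    steps += [(n.edge, False) for n in reversed(up_b)]
    return steps


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographic order
    of the (sorted) leaf-label pair.  A tree whose branch lengths are all
    zero is rooted at the first internal node, with a warning.
    """
    tree = tree.clone(depth=1)
    leaves = _leaf_by_label(tree)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    labels = sorted(leaves)
    # pairwise path lengths by leaf-to-leaf walks
    best: Optional[Tuple[float, Tuple[str, str]]] = None
    path_cache = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            steps = _path(leaves[la], leaves[lb])
            length = sum((e.length or 0.0) for e, _ in steps)
            path_cache[(la, lb)] = steps
            if best is None or length > best[0] + 1e-12:
                best = (length, (la, lb))
    diameter, (la, lb) = best
    if diameter <= 0:
        warnings.warn("all branch lengths zero; rooting at first internal node",
                      stacklevel=2)
        internal = next(n for n in tree.preorder_node_iter() if not n.is_leaf())
        tree.reroot_at_node(internal)
        tree.is_rooted = True
        return tree
    half = diameter / 2.0
    cum = 0.0
    for edge, toward_parent in path_cache[(la, lb)]:
        elen = edge.length or 0.0
        if cum + elen >= half - 1e-12:
            rem = half - cum  # distance from the end of the edge nearer leaf A
            # edge.head_node is the child; walking up traverses head -> tail
            if toward_parent:
                head_len = rem            # from new root to head (child) side
            else:
                head_len = elen - rem
            tail_len = elen - head_len
            tree.reroot_at_edge(edge, length1=tail_len, length2=head_len)
            tree.is_rooted = True
            return tree
        cum += elen
    raise AssertionError("midpoint not located on diameter path")


def cluster_tree(profiles: Mapping[str, Profile], seed: int = 0) -> dendropy.Tree:
    """Chord-distance NJ tree, midpoint-rooted — the strain clustering view."""
    D = chord_distance_matrix(profiles, seed=seed)
    return midpoint_root(nj_build(D))


def nearest_neighbor_purity(
    tree: dendropy.Tree, population: Mapping[str, str]
) -> float:
    """Fraction of leaves whose nearest leaf (patristic) shares their label."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    good = 0
    for t in taxa:
        dists = [
            (pdm.patristic_distance(t, u), u.label)
            for u in taxa
            if u is not t
        ]
        _, nearest = min(dists)
        if population[nearest] == population[t.label]:
            good += 1
    return good / len(taxa)
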