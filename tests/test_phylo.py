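"""K2P distances, NJ reconstruction, bootstrap supports, Newick round trips."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicseq.phylo import (
    DistanceMatrix,
    SaturationError,
    SubstitutionCounts,
    bootstrap_support,
    count_substitutions,
    k2p_distance,
    k2p_matrix,
    nj_build,
    tree_total_length,
)


class TestCountSubstitutions:
    def test_identical(self):
        c = count_substitutions("ACGTACGT", "ACGTACGT")
        assert (c.P, c.Q, c.n) == (0.0, 0.0, 8)

    def test_hand_count(self):
        # one A<->G transition, one A<->T transversion in 10 sites
        a = "AACCGGTTAA"
        b = "GACCGGTTTA"
        c = count_substitutions(a, b)
        assert c.P == pytest.approx(0.1)
        assert c.Q == pytest.approx(0.1)
        assert c.n == 10

    def test_pairwise_deletion(self):
        c = count_substitutions("ACGTACGTAN", "ACGTACGTAA")
        assert c.n == 9
        c2 = count_substitutions("ACGT-CGTAA", "ACGTACGTAA")
        assert c2.n == 9

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError, match="unambiguous"):
            count_substitutions("NNNN", "ACGT")


class TestK2PDistance:
    def test_zero(self):
        assert k2p_distance(SubstitutionCounts(0.0, 0.0, 100)) == 0.0

    @pytest.mark.parametrize(
        "P,Q,expected",
        [(0.1, 0.05, 0.17018), (0.0, 0.1, 0.10847)],
    )
    def test_closed_form(self, P, Q, expected):
        assert k2p_distance(SubstitutionCounts(P, Q, 100)) == pytest.approx(
            expected, abs=5e-6
        )

    def test_saturation_is_explicit_error(self):
        with pytest.raises(SaturationError):
            k2p_distance(SubstitutionCounts(0.5, 0.0, 100))
        with pytest.raises(SaturationError):
            k2p_distance(SubstitutionCounts(0.0, 0.5, 100))

    @given(
        P=st.floats(0.0, 0.4),
        Q=st.floats(0.0, 0.4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_k2p_dominates_p_distance(self, P, Q):
        """Jensen-type inequality: the corrected distance is never below the
        raw proportion of differing sites."""
        if 1 - 2 * P - Q <= 0.01 or 1 - 2 * Q <= 0.01:
            return
        d = k2p_distance(SubstitutionCounts(P, Q, 1000))
        assert d >= P + Q - 1e-12


from mosaicseq.validation import random_additive_tree


def bipartition_set(tree: dendropy.Tree) -> set:
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(labels)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        bips.add(labels - side if ref in side else side)
    return bips


class TestNJBuild:
    def test_three_taxa_three_point(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_build(DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            n.taxon.label: n.edge.length for n in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.4)

    def test_additive_five_taxon_recovery(self):
        rng = np.random.default_rng(0)
        D = random_additive_tree(rng, 5)
        tree = nj_build(D)
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for i, a in enumerate(D.labels):
            for j, b in enumerate(D.labels):
                if i < j:
                    got = pdm.patristic_distance(
                        tns.get_taxon(a), tns.get_taxon(b)
                    )
                    assert got == pytest.approx(D.d[i, j], abs=1e-9)
        assert tree_total_length(tree) == pytest.approx(
            _total_length_from_additive(D), abs=1e-9
        )

    def test_matches_dendropy_nj_on_random_matrices(self):
        """Independent oracle: dendropy's own NJ yields the same topology."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            pts = rng.random((n, 4))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = nj_build(DistanceMatrix(labels, d))
            csv = "," + ",".join(labels) + "\n" + "\n".join(
                labels[i] + "," + ",".join(str(x) for x in d[i]) for i in range(n)
            )
            import io

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(labels)
            )
            ref = pdm.nj_tree()
            assert bipartition_set(mine) == bipartition_set(ref)

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        labels = list("ABCD")
        t1 = nj_build(DistanceMatrix(labels, d.copy()))
        t2 = nj_build(DistanceMatrix(labels, d.copy()))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_rejects_asymmetric(self):
        d = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_build(DistanceMatrix(list("ABC"), d))


def _total_length_from_additive(D: DistanceMatrix) -> float:
    tree = nj_build(D)
    return tree_total_length(tree)


class TestTreeLength:
    def test_cherry(self):
        t = dendropy.Tree.get(data="(A:0.2,B:0.3);", schema="newick")
        assert tree_total_length(t) == pytest.approx(0.5)


class TestNewickRoundTrip:
    def test_lossless(self):
        rng = np.random.default_rng(2)
        D = random_additive_tree(rng, 7)
        tree = nj_build(D)
        s = tree.as_string(schema="newick")
        back = dendropy.Tree.get(data=s, schema="newick")
        assert bipartition_set(back) == bipartition_set(tree)
        assert tree_total_length(back) == pytest.approx(
            tree_total_length(tree), abs=1e-10
        )


TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def clade_alignment(rng, n_per_clade=2, n_cols=300, between=0.12):
    """Two clean clades; each taxon gets its own disjoint private mutations
    (distinct counts) so all pairwise distances are distinct and NJ is
    tie-free."""
    base = "".join(rng.choice(list("ACGT"), n_cols))
    other = list(base)
    for s in rng.choice(n_cols // 2, int(between * n_cols), replace=False):
        other[s] = TS[other[s]]
    other = "".join(other)
    aln = {}
    site = n_cols // 2  # private mutations live in the second half
    for k, root in enumerate((base, other)):
        for i in range(n_per_clade):
            seq = list(root)
            for _ in range(2 + 2 * i + k):
                seq[site] = TS[seq[site]]
                site += 1
            aln[f"c{k}_{i}"] = "".join(seq)
    return aln


def star_alignment(rng, n_taxa=4, n_cols=120, divergence=0.1):
    """Taxa derived independently from one ancestor: no internal signal."""
    base = "".join(rng.choice(list("ACGT"), n_cols))
    aln = {}
    for i in range(n_taxa):
        seq = list(base)
        for s in rng.choice(n_cols, int(divergence * n_cols), replace=False):
            seq[s] = TS[seq[s]]
        aln[f"t{i}"] = "".join(seq)
    return aln


class TestBootstrap:
    def test_saturated_signal_gives_full_support(self):
        rng = np.random.default_rng(3)
        aln = clade_alignment(rng)
        tree = bootstrap_support(aln, n_replicates=50, seed=4)
        supports = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert supports and all(s >= 95 for s in supports)

    def test_random_alignment_low_support(self):
        """i.i.d. columns carry no tree signal; mean support stays low."""
        supports = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            aln = star_alignment(rng)
            tree = bootstrap_support(aln, n_replicates=30, seed=seed)
            supports.extend(
                int(n.label)
                for n in tree.preorder_node_iter()
                if n.label and not n.is_leaf()
            )
        assert np.mean(supports) < 80

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        aln = clade_alignment(rng)
        t1 = bootstrap_support(aln, 25, seed=9).as_string(schema="newick")
        t2 = bootstrap_support(aln, 25, seed=9).as_string(schema="newick")
        assert t1 == t2

    def test_taxon_order_invariant_supports(self):
        rng = np.random.default_rng(6)
        aln = clade_alignment(rng, n_per_clade=3)
        fwd = bootstrap_support(dict(aln), 25, seed=1)
        rev = bootstrap_support(dict(reversed(list(aln.items()))), 25, seed=1)

        def support_map(tree):
            out = {}
            for n in tree.preorder_node_iter():
                if n.label and not n.is_leaf():
                    side = frozenset(l.taxon.label for l in n.leaf_iter())
                    out[side] = int(n.label)
            return out

        labels = frozenset(aln)
        ref = min(labels)
        fwd_map = {
            (labels - k if ref in k else k): v for k, v in support_map(fwd).items()
        }
        rev_map = {
            (labels - k if ref in k else k): v for k, v in support_map(rev).items()
        }
        assert set(fwd_map) == set(rev_map)

    def test_three_taxa_no_supports(self):
        rng = np.random.default_rng(7)
        aln = star_alignment(rng, n_taxa=3)
        tree = bootstrap_support(aln, 10, seed=0)
        assert all(
            not n.label for n in tree.preorder_node_iter() if not n.is_leaf()
        )
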