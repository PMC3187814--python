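"""Identity classification, chimera breakpoints, neutral SNPs, truncations."""

import numpy as np
import pytest

from mosaicseq import ancestry
from mosaicseq.ancestry import ClassificationThresholds

from conftest import diverge, random_seq


class TestPercentIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 1_000)
        pct, n = ancestry.percent_identity(s, s)
        assert pct == 100.0
        assert n == 1_000

    def test_seven_mismatches_in_100(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 100)
        b = diverge(a, [3, 17, 30, 44, 61, 78, 92])
        pct, n = ancestry.percent_identity(a, b)
        assert pct == pytest.approx(93.0)
        assert n == 100

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 300)
        b = diverge(a, range(0, 300, 9))
        assert ancestry.percent_identity(a, b) == ancestry.percent_identity(b, a)

    def test_gap_columns_count_against_identity(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + a[13:]  # 3-nt deletion
        pct, n = ancestry.percent_identity(a, b)
        assert n == 20
        assert pct == pytest.approx(100.0 * 17 / 20)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            ancestry.percent_identity("", "ACGT")


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(3)
    uv = random_seq(rng, 1_000)
    ce = diverge(uv, rng.choice(1_000, 200, replace=False))  # ~80% to uvarum
    return ce, uv


@pytest.fixture(scope="module")
def chimera():
    """Chimera joined at 500 between ~7%-diverged parents, with diagnostic
    sites flanking the junction so the oracle is sharp."""
    rng = np.random.default_rng(6)
    refA = random_seq(rng, 1_000)
    sites = set(rng.choice(1_000, 70, replace=False)) | {499, 500}
    refB = diverge(refA, sorted(sites))
    return refA[:500] + refB[500:], refA, refB


class TestClassifyMarker:
    def test_exact_uvarum(self, refs):
        ce, uv = refs
        call = ancestry.classify_marker("PMA1", uv, ce, uv)
        assert call.lineage == "uvarum"
        assert call.identity_to_uvarum == 100.0

    def test_exact_cerevisiae(self, refs):
        ce, uv = refs
        call = ancestry.classify_marker("MAL32", ce, ce, uv)
        assert call.lineage == "cerevisiae"

    def test_lager_band(self, refs):
        """~93% identity to uvarum, far from cerevisiae: a lager-type allele."""
        ce, uv = refs
        rng = np.random.default_rng(4)
        lager = diverge(uv, rng.choice(1_000, 70, replace=False))
        call = ancestry.classify_marker("HO", lager, ce, uv)
        assert call.lineage == "lager"
        assert 92.0 <= call.identity_to_uvarum <= 94.0

    def test_absent_marker(self, refs):
        ce, uv = refs
        assert ancestry.classify_marker("MEL1", "", ce, uv).lineage == "absent"

    def test_chimeric_query(self, refs):
        ce, uv = refs
        q = uv[:500] + ce[500:]
        call = ancestry.classify_marker("MAL33", q, ce, uv)
        assert call.lineage == "chimeric"
        assert call.chimera is not None

    def test_threshold_monotonicity(self, refs):
        """Raising identity to uvarum never demotes a uvarum call to lager."""
        ce, uv = refs
        rng = np.random.default_rng(5)
        sites = rng.choice(1_000, 60, replace=False)
        previous = None
        for n_sub in (60, 40, 25, 15, 5, 0):
            q = diverge(uv, sites[:n_sub])
            call = ancestry.classify_marker("m", q, ce, uv)
            if previous == "uvarum":
                assert call.lineage == "uvarum"
            previous = call.lineage


class TestDetectBreakpoint:
    def test_breakpoint_near_construction(self, chimera):
        q, refA, refB = chimera
        call = ancestry.detect_breakpoint(q, refA, refB)
        assert 495 <= call.breakpoint <= 505
        assert call.seg5_ref == "refA"
        assert call.seg3_ref == "refB"
        assert call.seg5_identity > 99.0
        assert call.seg3_identity > 99.0

    def test_segment_lengths_partition_query(self, chimera):
        q, refA, refB = chimera
        call = ancestry.detect_breakpoint(q, refA, refB)
        assert call.seg5_length + call.seg3_length == len(q)
        assert call.breakpoint == call.seg5_length

    def test_pure_parent_degenerate(self, chimera):
        _, refA, refB = chimera
        call = ancestry.detect_breakpoint(refA, refA, refB)
        assert call.breakpoint == len(refA)
        assert call.seg3_length == 0

    def test_orderings_symmetric(self, chimera):
        q, refA, refB = chimera
        fwd = ancestry.detect_breakpoint(q, refA, refB)
        rev = ancestry.detect_breakpoint(q, refB, refA)
        assert fwd.breakpoint == rev.breakpoint

    def test_short_query_rejected(self):
        with pytest.raises(ValueError, match="50"):
            ancestry.detect_breakpoint("ATG" * 10, "ATG" * 10, "ATG" * 10)

    def test_mal33_like_geometry(self):
        """Synthetic stand-in with the published chimera geometry: a 1407-nt
        gene whose first 397 nt are ~91% identical to one parent and whose
        last 1010 nt match the other exactly."""
        rng = np.random.default_rng(7)
        uvarum_mal33 = random_seq(rng, 1_407)
        sites = set(rng.choice(1_407, 310, replace=False)) | {396, 397}
        cerevisiae_mal33 = diverge(uvarum_mal33, sorted(sites))  # ~78% apart
        seg5 = diverge(uvarum_mal33[:397], rng.choice(396, 36, replace=False))
        query = seg5 + cerevisiae_mal33[397:]
        call = ancestry.detect_breakpoint(
            query, cerevisiae_mal33, uvarum_mal33, "cerevisiae", "uvarum"
        )
        assert call.seg5_ref == "uvarum"
        assert call.seg3_ref == "cerevisiae"
        assert abs(call.seg5_length - 397) <= 5
        assert abs(call.seg3_length - 1_010) <= 5
        assert call.seg5_identity == pytest.approx(91.0, abs=1.5)
        assert call.seg3_identity == pytest.approx(100.0, abs=0.5)


class TestNeutralFraction:
    def test_hand_built_three_quarters(self):
        # GCT->GCC (syn), CTG->CTA (syn), CGT->CGC (syn), ATG->AAG (nonsyn)
        a = "GCT" + "CTG" + "CGT" + "ATG"
        b = "GCC" + "CTA" + "CGC" + "AAG"
        assert ancestry.neutral_fraction(a, b) == pytest.approx(0.75)

    def test_identical_is_undefined(self):
        assert ancestry.neutral_fraction("ATGGCT", "ATGGCT") is None

    def test_simulated_lager_proteins_near_identical(self, parents):
        """Translation oracle: at 7% nucleotide divergence with 95% of coding
        substitutions synonymous, expected protein identity is
        1 - 0.07*0.05*3 ~ 98.9% and BLOSUM62 similarity exceeds 99%."""
        from Bio.Align import substitution_matrices
        from Bio.Seq import Seq

        blosum = substitution_matrices.load("BLOSUM62")
        total = same = similar = 0
        for gene in parents.genes[:30]:
            uv = parents.uvarum_genome[gene.chrom][gene.start - 1:gene.end]
            lg = parents.lager_genome[gene.chrom][gene.start - 1:gene.end]
            frac = ancestry.neutral_fraction(uv, lg)
            assert frac is None or frac > 0.8
            pu, pl = str(Seq(uv).translate()), str(Seq(lg).translate())
            total += len(pu)
            for x, y in zip(pu, pl):
                if x == y:
                    same += 1
                    similar += 1
                elif blosum[x][y] > 0:
                    similar += 1
        assert 100.0 * same / total > 98.5
        assert 100.0 * similar / total > 99.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ancestry.neutral_fraction("ATG", "ATGGCT")
        with pytest.raises(ValueError):
            ancestry.neutral_fraction("ATGC", "ATGA")


def agt1_like_orf(rng=None):
    """Synthetic 616-residue ORF emulating the maltose-transporter geometry:
    inserting a T at nt 1183 shifts the frame and stops translation at
    codon 395."""
    rng = rng or np.random.default_rng(8)
    codons = []
    aa_codons = ["GCT", "GAA", "TTC", "GGT", "CAT", "ATC", "AAA", "CTG"]
    for _ in range(615):
        codons.append(aa_codons[rng.integers(len(aa_codons))])
    orf = "ATG" + "".join(codons) + "TAA"
    # nt 1183 starts codon 395; make the insertion create TAA there
    orf = orf[:1182] + "AA" + orf[1184:]
    assert len(orf) == 3 * 617
    return orf


class TestPredictTruncation:
    def test_full_length_616(self):
        tc = ancestry.predict_truncation(agt1_like_orf())
        assert tc.protein_length_aa == 616
        assert not tc.premature

    def test_t_insertion_at_1183_truncates_to_394(self):
        orf = agt1_like_orf()
        mutated = orf[:1182] + "T" + orf[1182:]
        tc = ancestry.predict_truncation(mutated)
        assert tc.protein_length_aa == 394
        assert tc.premature

    def test_immediate_stop(self):
        tc = ancestry.predict_truncation("ATGTAAGCT")
        assert tc.protein_length_aa == 1
        assert tc.premature

    def test_no_stop_flagged(self):
        tc = ancestry.predict_truncation("ATGGCTGCT")
        assert not tc.stop_found
        assert tc.protein_length_aa == 3

    def test_insertion_stop_bound(self):
        """An insertion creating an immediate in-frame stop at position k can
        never yield a protein longer than floor((k+2)/3)."""
        orf = agt1_like_orf()
        k = 1183
        mutated = orf[:k - 1] + "T" + orf[k - 1:]
        tc = ancestry.predict_truncation(mutated)
        assert tc.protein_length_aa <= (k + 2) // 3

    def test_requires_atg(self):
        with pytest.raises(ValueError):
            ancestry.predict_truncation("TTGGCTTAA")
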