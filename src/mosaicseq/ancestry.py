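"""Lineage assignment of sequenced markers in mosaic hybrid genomes.

A marker amplified from a hybrid strain is assigned to one of three
parental lineages by pairwise nucleotide identity against reference
alleles: a *cerevisiae*-type donor (>=99% identity to the cerevisiae
reference), the *uvarum* recipient (>=98% identity to the uvarum
reference), or the lager-type sister lineage (2-6% divergence from
uvarum).  Markers fitting none of these are tested for a chimeric
structure (a single breakpoint joining two parental segments, the
signature of an introgression junction falling inside a gene) and
otherwise called ambiguous.  The module also quantifies the synonymous
fraction of coding substitutions (near-neutral divergence is the evidence
that lager-type alleles share a recent common origin with uvarum) and
predicts frameshift truncations from single-base insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from Bio import Align
from Bio.Seq import Seq

LINEAGES = ("cerevisiae", "uvarum", "lager", "chimeric", "ambiguous", "absent")


@dataclass(frozen=True)
class ClassificationThresholds:
    cerevisiae_min: float = 99.0
    uvarum_min: float = 98.0
    # Identity to uvarum, [low, high).  Lager-type alleles sit at roughly
    # 91-95% identity to their uvarum counterparts ("93 Lg"-class entries),
    # so the band reaches down to 91.
    lager_band: Tuple[float, float] = (91.0, 98.0)
    chimera_margin: float = 2.0  # identity points a breakpoint must gain

    def __post_init__(self):
        if not (0 < self.cerevisiae_min <= 100 and 0 < self.uvarum_min <= 100):
            raise ValueError("thresholds must lie in (0, 100]")
        if self.lager_band[1] > self.uvarum_min:
            raise ValueError("lager band must end at or below the uvarum threshold")


@dataclass(frozen=True)
class MarkerCall:
    marker: str
    lineage: str
    identity_to_cerevisiae: Optional[float]
    identity_to_uvarum: Optional[float]
    aligned_length: int
    chimera: Optional["ChimeraCall"] = None


@dataclass(frozen=True)
class ChimeraCall:
    """A single breakpoint partitioning a query into two parental segments."""

    breakpoint: int          # 1-based position in query; last base of 5' segment
    seg5_length: int
    seg3_length: int
    seg5_ref: str            # reference the 5' segment matches best
    seg3_ref: str
    seg5_identity: float     # identity of the 5' segment to seg5_ref
    seg3_identity: float
    seg5_identity_other: float
    seg3_identity_other: float


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aln) -> Tuple[int, int]:
    """(matches, aligned columns) of a Biopython alignment."""
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches, len(a)


def percent_identity(a: str, b: str) -> Tuple[float, int]:
    """Global-alignment nucleotide identity.

    Identity is matches over aligned columns; gap columns count as
    non-matches (a conservative denominator).  Returns (percent, columns).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    aln = _aligner().align(a, b)[0]
    matches, columns = _alignment_stats(aln)
    return 100.0 * matches / columns, columns


def _query_match_profile(query: str, ref: str) -> list:
    """Per-query-position match indicator against ref, via global alignment."""
    aln = _aligner().align(query, ref)[0]
    qa, ra = aln[0], aln[1]
    profile = []
    for x, y in zip(qa, ra):
        if x == "-":
            continue
        profile.append(1 if x == y else 0)
    assert len(profile) == len(query)
    return profile


def detect_breakpoint(query: str, refA: str, refB: str,
                      nameA: str = "refA", nameB: str = "refB") -> ChimeraCall:
    """Locate the breakpoint best splitting the query between two references.

    Both references are globally aligned to the query; match indicators are
    projected onto query coordinates and the breakpoint p maximising
    matches(query[1..p], one reference) + matches(query[p+1..n], the other)
    is chosen over both orderings.
    """
    query = query.upper()
    if len(query) < 50:
        raise ValueError("query shorter than 50 nt: insufficient signal")
    import numpy as np

    profA = np.array(_query_match_profile(query, refA.upper()))
    profB = np.array(_query_match_profile(query, refB.upper()))
    n = len(query)
    cumA = np.concatenate([[0], np.cumsum(profA)])
    cumB = np.concatenate([[0], np.cumsum(profB)])
    # ordering 1: refA 5', refB 3'; ordering 2: refB 5', refA 3'
    score_ab = cumA + (cumB[n] - cumB)
    score_ba = cumB + (cumA[n] - cumA)
    # ties resolved toward the largest p, so a query identical to the 5'
    # reference yields the degenerate breakpoint p = n (empty 3' segment)
    p_ab = int(len(score_ab) - 1 - np.argmax(score_ab[::-1]))
    p_ba = int(len(score_ba) - 1 - np.argmax(score_ba[::-1]))
    if score_ab[p_ab] >= score_ba[p_ba]:
        p, c5, c3, n5, n3 = p_ab, cumA, cumB, nameA, nameB
        o5, o3 = cumB, cumA
    else:
        p, c5, c3, n5, n3 = p_ba, cumB, cumA, nameB, nameA
        o5, o3 = cumA, cumB

    def seg_identity(cum, lo, hi):
        length = hi - lo
        return 100.0 * (cum[hi] - cum[lo]) / length if length else 100.0

    return ChimeraCall(
        breakpoint=p,
        seg5_length=p,
        seg3_length=n - p,
        seg5_ref=n5,
        seg3_ref=n3,
        seg5_identity=seg_identity(c5, 0, p),
        seg3_identity=seg_identity(c3, p, n),
        seg5_identity_other=seg_identity(o5, 0, p),
        seg3_identity_other=seg_identity(o3, p, n),
    )


def classify_marker(
    marker: str,
    query: Optional[str],
    cerevisiae_ref: str,
    uvarum_ref: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> MarkerCall:
    """Assign a marker to a parental lineage by pairwise identity."""
    if not cerevisiae_ref or not uvarum_ref:
        raise ValueError("references must be non-empty")
    if not query:
        return MarkerCall(marker, "absent", None, None, 0)
    id_ce, len_ce = percent_identity(query, cerevisiae_ref)
    id_uv, len_uv = percent_identity(query, uvarum_ref)
    aligned = max(len_ce, len_uv)
    if id_ce >= thresholds.cerevisiae_min:
        lineage = "cerevisiae"
    elif id_uv >= thresholds.uvarum_min:
        lineage = "uvarum"
    elif thresholds.lager_band[0] <= id_uv < thresholds.lager_band[1]:
        lineage = "lager"
    else:
        lineage = "ambiguous"
        if len(query) >= 50:
            chim = detect_breakpoint(query, cerevisiae_ref, uvarum_ref,
                                     "cerevisiae", "uvarum")
            best_single = max(id_ce, id_uv)
            split_identity = (
                chim.seg5_identity * chim.seg5_length
                + chim.seg3_identity * chim.seg3_length
            ) / len(query)
            if (
                chim.seg5_length > 0
                and chim.seg3_length > 0
                and split_identity >= best_single + thresholds.chimera_margin
            ):
                return MarkerCall(marker, "chimeric", id_ce, id_uv, aligned, chim)
    return MarkerCall(marker, lineage, id_ce, id_uv, aligned)


def neutral_fraction(coding_a: str, coding_b: str) -> Optional[float]:
    """Fraction of differing sites whose substitution is synonymous.

    Both sequences must be in-frame, equal-length and gap-free.  A
    differing site counts as synonymous iff its two codons encode the same
    amino acid under the standard code.  Returns None when the sequences
    are identical (the fraction is undefined, not 0 or 1).
    """
    a, b = coding_a.upper(), coding_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    if "-" in a or "-" in b:
        raise ValueError("gapped input not supported")
    diff = syn = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca == cb:
            continue
        same_aa = str(Seq(ca).translate()) == str(Seq(cb).translate())
        for j in range(3):
            if ca[j] != cb[j]:
                diff += 1
                if same_aa:
                    syn += 1
    if diff == 0:
        return None
    return syn / diff


@dataclass(frozen=True)
class TruncationCall:
    protein_length_aa: int
    premature: bool
    stop_found: bool


def predict_truncation(orf: str) -> TruncationCall:
    """Translate frame 1 to the first stop and flag premature termination.

    A single-base insertion that shifts the frame typically brings a stop
    codon into frame well before the natural end of the protein; the
    resulting truncated length is the diagnostic readout.
    """
    orf = orf.upper()
    if not orf.startswith("ATG"):
        raise ValueError("ORF must start with ATG")
    if len(orf) < 6:
        raise ValueError("ORF too short")
    n_codons = len(orf) // 3
    protein = str(Seq(orf[:n_codons * 3]).translate())
    stop = protein.find("*")
    if stop == -1:
        return TruncationCall(n_codons, premature=False, stop_found=False)
    return TruncationCall(stop, premature=stop < n_codons - 1, stop_found=True)
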