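"""Synthetic three-parent mosaic genomes and downstream datasets.

The simulator emulates the experimental situation this package analyses:
a *S. uvarum*-like recipient genome, a "lager"-type sister lineage derived
from it at low (~7%) divergence with mostly synonymous substitutions, and a
distant *S. cerevisiae*-like donor (~20% divergence) whose subtelomeric
blocks are introgressed into the recipient.  Every generator records its
ground truth so detection and classification stages can be scored exactly.

All coordinates are 1-based inclusive.  All randomness is driven by an
explicit integer seed; identical seeds give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# transition partner, then the two transversion partners, for each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_CODON_TABLE = {}


def _codon_table() -> Dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE


@dataclass
class GeneModel:
    """A toy in-frame gene used only to decide where synonymous sites are."""

    chrom: str
    start: int  # 1-based, first base of the first codon
    end: int    # inclusive, last base of the last codon


@dataclass
class ParentSet:
    """The three simulated parental genomes on a shared coordinate system."""

    cerevisiae_genome: Dict[str, str]
    uvarum_genome: Dict[str, str]
    lager_genome: Dict[str, str]
    divergence_uv_lg: float
    divergence_ce: float
    neutral_target: float
    seed: int
    genes: List[GeneModel] = field(default_factory=list)
    realized_neutral_fraction: Optional[float] = None


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every simulated dataset."""

    introgressions: List[Tuple[str, int, int, str]] = field(default_factory=list)
    marker_lineage: Dict[str, str] = field(default_factory=dict)
    tetrad_genotypes: Dict[str, Dict[str, set]] = field(default_factory=dict)
    seed: int = 0
    notes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "introgressions": [list(t) for t in self.introgressions],
            "marker_lineage": dict(self.marker_lineage),
            "tetrad_genotypes": {
                t: {s: sorted(m) for s, m in spores.items()}
                for t, spores in self.tetrad_genotypes.items()
            },
            "seed": self.seed,
            "notes": list(self.notes),
        }


def _random_genome(rng: np.random.Generator, chrom_lengths: Sequence[int]) -> Dict[str, str]:
    genome = {}
    for i, length in enumerate(chrom_lengths):
        seq = rng.choice(BASES, size=length)
        genome[f"chr{i + 1:02d}"] = seq.tobytes().decode()
    return genome


def _toy_genes(chrom: str, length: int, gene_len: int = 999, spacer: int = 201) -> List[GeneModel]:
    """Tile a chromosome with in-frame genes separated by short intergenes."""
    genes = []
    pos = spacer + 1
    while pos + gene_len - 1 <= length - spacer:
        genes.append(GeneModel(chrom, pos, pos + gene_len - 1))
        pos += gene_len + spacer
    return genes


def _substituted_base(rng: np.random.Generator, base: str) -> str:
    """Random substitution with a 2:1 transition:transversion bias."""
    if rng.random() < 0.5:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def _synonymous_change(codon: str, pos_in_codon: int, rng: np.random.Generator) -> Optional[str]:
    """Return a base change at pos_in_codon keeping the amino acid, or None."""
    table = _codon_table()
    aa = table[codon]
    base = codon[pos_in_codon]
    candidates = [_TRANSITION[base]] + list(_TRANSVERSIONS[base])
    for new in candidates:  # transition tried first: keeps the 2:1 bias high
        alt = codon[:pos_in_codon] + new + codon[pos_in_codon + 1:]
        if table[alt] == aa:
            return new
    return None


def _apply_codon_change(arr: list, codon_start0: int, rng: np.random.Generator,
                        synonymous: bool) -> bool:
    """Substitute one base of the codon at ``codon_start0``.

    For a synonymous change the third position is tried first (where one
    almost always exists), then the others; ATG and TGG have none and the
    call returns False.  For a nonsynonymous change the first position is
    tried first and stop codons are avoided.
    """
    table = _codon_table()
    codon = "".join(arr[codon_start0:codon_start0 + 3])
    aa = table[codon]
    positions = (2, 0, 1) if synonymous else (0, 1, 2)
    for pos in positions:
        base = codon[pos]
        for new in [_TRANSITION[base]] + list(_TRANSVERSIONS[base]):
            alt = codon[:pos] + new + codon[pos + 1:]
            ok = (table[alt] == aa) if synonymous else (
                table[alt] != aa and table[alt] != "*"
            )
            if ok:
                arr[codon_start0 + pos] = new
                return True
    return False


def _derive(
    genome: Dict[str, str],
    genes: List[GeneModel],
    divergence: float,
    neutral_target: Optional[float],
    rng: np.random.Generator,
) -> Tuple[Dict[str, str], int, int]:
    """Derive a diverged genome; returns (genome, n_coding_subs, n_synonymous).

    Each substitution lands in a distinct position (intergenic sites) or a
    distinct codon (coding sites), so the realized divergence equals the
    requested rate up to rounding and the synonymous fraction of coding
    substitutions tracks ``neutral_target``.
    """
    derived = {}
    n_coding_total = 0
    n_syn_total = 0
    gene_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, seq in genome.items():
        arr = list(seq)
        n_sub = int(round(divergence * len(seq)))
        sites = rng.choice(len(seq), size=n_sub, replace=False)
        chrom_genes = gene_by_chrom.get(chrom, [])
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        coding = 0
        for site in sites:
            pos1 = int(site) + 1  # 1-based
            in_gene = False
            if starts.size:
                hit = np.searchsorted(starts, pos1, side="right") - 1
                in_gene = hit >= 0 and pos1 <= ends[hit]
            if in_gene and neutral_target is not None:
                coding += 1  # placed codon-wise below
            else:
                arr[site] = _substituted_base(rng, arr[site])
        if coding and neutral_target is not None:
            codon_starts0 = np.concatenate([
                np.arange(g.start - 1, g.end, 3) for g in chrom_genes
            ])
            rng.shuffle(codon_starts0)
            if coding > len(codon_starts0):
                coding = len(codon_starts0)
            n_syn_want = int(round(neutral_target * coding))
            placed_syn = placed_nonsyn = 0
            for cs in codon_starts0:
                if placed_syn < n_syn_want:
                    if _apply_codon_change(arr, int(cs), rng, synonymous=True):
                        placed_syn += 1
                elif placed_syn + placed_nonsyn < coding:
                    if _apply_codon_change(arr, int(cs), rng, synonymous=False):
                        placed_nonsyn += 1
                else:
                    break
            n_coding_total += placed_syn + placed_nonsyn
            n_syn_total += placed_syn
        derived[chrom] = "".join(arr)
    return derived, n_coding_total, n_syn_total


def simulate_parents(
    seed: int,
    chrom_lengths: Sequence[int] = (120_000, 120_000, 120_000),
    divergence_uv_lg: float = 0.07,
    divergence_ce: float = 0.20,
    neutral_target: float = 0.95,
) -> ParentSet:
    """Simulate the three parental genomes.

    The *uvarum* genome is drawn uniformly at random; the lager genome is
    derived from it by ``divergence_uv_lg`` substitutions placed mostly at
    synonymous sites (``neutral_target`` of the coding hits), reproducing the
    ~93%-identity, nearly-neutral regime of lager-type alleles; the
    cerevisiae genome is derived independently at ``divergence_ce``.
    """
    if not 0 <= divergence_uv_lg <= 0.25 or not 0 <= divergence_ce <= 0.25:
        raise ValueError("divergences must lie in [0, 0.25]")
    if any(l < 1000 for l in chrom_lengths):
        raise ValueError("chromosomes must be at least 1 kb")
    rng = np.random.default_rng(seed)
    uvarum = _random_genome(rng, chrom_lengths)
    genes: List[GeneModel] = []
    for chrom, seq in uvarum.items():
        genes.extend(_toy_genes(chrom, len(seq)))
    lager, n_coding, n_syn = _derive(uvarum, genes, divergence_uv_lg, neutral_target, rng)
    realized = n_syn / n_coding if n_coding else None
    if realized is not None and realized < neutral_target - 0.05:
        warnings.warn(
            f"neutral target {neutral_target} unattainable; realized {realized:.3f}",
            stacklevel=2,
        )
    cerevisiae, _, _ = _derive(uvarum, [], divergence_ce, None, rng)
    return ParentSet(
        cerevisiae_genome=cerevisiae,
        uvarum_genome=uvarum,
        lager_genome=lager,
        divergence_uv_lg=divergence_uv_lg,
        divergence_ce=divergence_ce,
        neutral_target=neutral_target,
        seed=seed,
        genes=genes,
        realized_neutral_fraction=realized,
    )


def implant_introgressions(
    recipient: Mapping[str, str],
    donor: Mapping[str, str],
    intervals: Sequence[Tuple[str, int, int]],
    donor_lineage: str = "cerevisiae",
    seed: int = 0,
) -> Tuple[Dict[str, str], TruthRecord]:
    """Replace recipient sequence by donor sequence on each 1-based interval."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if chrom not in recipient:
            raise ValueError(f"interval on unknown chromosome: {(chrom, start, end)}")
        if not (1 <= start <= end <= len(recipient[chrom])):
            raise ValueError(f"interval out of bounds: {(chrom, start, end)}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping intervals on {chrom}: ({s1},{e1}) and ({s2},{e2})"
                )
    mosaic = dict(recipient)
    for chrom, ivals in by_chrom.items():
        seq = mosaic[chrom]
        for start, end in ivals:
            seq = seq[:start - 1] + donor[chrom][start - 1:end] + seq[end:]
        mosaic[chrom] = seq
        assert len(seq) == len(recipient[chrom])
    truth = TruthRecord(
        introgressions=[(c, s, e, donor_lineage) for c, s, e in sorted(intervals)],
        seed=seed,
    )
    return mosaic, truth


#: Subtelomeric block lengths for the three-contig preset.  The middle block
#: reproduces the 30,803-bp contig; the flanking two are sized so that the
#: three together total ~70 kb.
CABC_BLOCKS = (20_000, 30_803, 19_000)


def cabc_intervals(chrom_lengths: Mapping[str, int], margin: int = 2_000) -> List[Tuple[str, int, int]]:
    """Three subtelomeric introgression intervals, one per chromosome."""
    chroms = sorted(chrom_lengths)
    if len(chroms) < 3:
        raise ValueError("cABC preset needs at least three chromosomes")
    intervals = []
    for chrom, block in zip(chroms[:3], CABC_BLOCKS):
        end = chrom_lengths[chrom] - margin
        intervals.append((chrom, end - block + 1, end))
    return intervals


def make_probe_design(
    genome: Mapping[str, str], probe_length: int = 50, spacing: int = 250
) -> pd.DataFrame:
    """Tile probes along a genome; one probe every ``spacing`` bp.

    50-mer footprints keep the chance of a fully conserved probe inside
    20%-diverged background negligible (0.8^50), so background and
    introgressed probes separate cleanly.
    """
    rows = []
    i = 0
    for chrom in sorted(genome):
        length = len(genome[chrom])
        pos = 1
        while pos + probe_length - 1 <= length:
            rows.append((f"p{i:06d}", chrom, pos, pos + probe_length - 1))
            i += 1
            pos += spacing
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])


def _probe_identity(probe_seq: str, sample_seq: str) -> float:
    a = np.frombuffer(probe_seq.encode(), dtype="S1")
    b = np.frombuffer(sample_seq.encode(), dtype="S1")
    return float((a == b).mean()) * 100.0


# Three-plateau response of probe intensity to probe/sample identity.  The
# plateaus emulate the qualitative classes seen on a comparative array:
# near-identical DNA hybridises strongly, ~93%-diverged DNA gives reduced but
# clear signal, and 20%-diverged DNA is indistinguishable from background.
# The exact plateau heights are calibration knobs, not measured values.
SIGNAL_BACKGROUND = 100.0
SIGNAL_MID = 1_500.0
SIGNAL_HIGH = 10_000.0


def _signal_model(identity_pct: np.ndarray) -> np.ndarray:
    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    p = np.asarray(identity_pct, dtype=float)
    low_to_mid = sigmoid((p - 86.0) / 1.5)
    mid_to_high = sigmoid((p - 96.5) / 0.7)
    return (
        SIGNAL_BACKGROUND
        + (SIGNAL_MID - SIGNAL_BACKGROUND) * low_to_mid
        + (SIGNAL_HIGH - SIGNAL_MID) * mid_to_high
    )


def simulate_array(
    probe_design: pd.DataFrame,
    genome: Mapping[str, str],
    reference_genome: Mapping[str, str],
    noise_sd: float = 0.1,
    n_replicates: int = 2,
    seed: int = 0,
) -> List[pd.DataFrame]:
    """Simulate replicate probe-intensity tables for one sample genome.

    ``reference_genome`` is the genome the probes were designed against; a
    probe's noiseless intensity follows the three-plateau response to the
    identity between the probe footprint in the design genome and the same
    footprint in the sample ``genome``.  Noise is multiplicative log-normal.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    identities = np.empty(len(probe_design))
    for k, row in enumerate(probe_design.itertuples(index=False)):
        if row.chrom not in genome or row.end > len(genome[row.chrom]):
            raise ValueError(f"probe {row.probe_id} outside genome")
        probe_seq = reference_genome[row.chrom][row.start - 1:row.end]
        sample_seq = genome[row.chrom][row.start - 1:row.end]
        identities[k] = _probe_identity(probe_seq, sample_seq)
    clean = _signal_model(identities)
    replicates = []
    for _ in range(n_replicates):
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(clean))) if noise_sd > 0 else 1.0
        df = probe_design.copy()
        df["intensity"] = clean * noise
        replicates.append(df)
    return replicates


def simulate_meiosis(
    parent_marker_sets: Tuple[Mapping[str, bool], Mapping[str, bool]],
    n_tetrads: int,
    linkage: Optional[Mapping[Tuple[str, str], object]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Simulate four-spore tetrads from a cross of two marker-typed parents.

    Markers heterozygous between the parents segregate 2:2 in every tetrad.
    Marker pairs listed in ``linkage`` with a map distance (cM) co-segregate
    through a four-chromatid crossover model; all other heterozygous pairs
    assort independently (uniform over the six 2:2 spore patterns), giving
    the expected 1:1:4 PD:NPD:TT ratio.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    p1, p2 = parent_marker_sets
    markers = sorted(set(p1) | set(p2))
    rng = np.random.default_rng(seed)
    linkage = dict(linkage or {})
    # partition heterozygous markers into linkage groups
    het = [m for m in markers if bool(p1.get(m, False)) != bool(p2.get(m, False))]
    groups: List[List[Tuple[str, float]]] = []
    in_group = {}
    for (a, b), dist in linkage.items():
        if dist == "unlinked":
            continue
        if a not in het or b not in het:
            continue
        if a in in_group:
            groups[in_group[a]].append((b, float(dist)))
            in_group[b] = in_group[a]
        elif b in in_group:
            groups[in_group[b]].append((a, float(dist)))
            in_group[a] = in_group[b]
        else:
            groups.append([(a, 0.0), (b, float(dist))])
            in_group[a] = in_group[b] = len(groups) - 1
    for m in het:
        if m not in in_group:
            groups.append([(m, 0.0)])
            in_group[m] = len(groups) - 1

    spore_names = ["a", "b", "c", "d"]
    columns = []
    data = {m: [] for m in markers}
    truth = TruthRecord(seed=seed)
    patterns_2_2 = [np.array(p) for p in
                    [(1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1),
                     (0, 1, 1, 0), (0, 1, 0, 1), (0, 0, 1, 1)]]
    for t in range(n_tetrads):
        tname = f"T{t + 1:04d}"
        spore_presence = {m: None for m in markers}
        for group in groups:
            # markers in the group are ordered by their map offset from the
            # first marker; alleles tracked on four chromatids
            ordered = sorted(group, key=lambda md: md[1])
            first = True
            prev_d = 0.0
            perm = rng.permutation(4)  # random spore packaging
            base_pattern = patterns_2_2[rng.integers(6)]
            # realize the first marker's 2:2 pattern uniformly
            alleles = {}
            current = base_pattern.copy()
            for name, d in ordered:
                if not first:
                    # crossovers between previous marker and this one
                    n_co = rng.poisson(max(d - prev_d, 0.0) / 50.0)
                    for _ in range(n_co):
                        i = rng.integers(2)           # chromatid carrying allele 1
                        j = 2 + rng.integers(2)       # chromatid carrying allele 0
                        ones = np.flatnonzero(current == 1)
                        zeros = np.flatnonzero(current == 0)
                        ci, cj = ones[i], zeros[j - 2]
                        current = current.copy()
                        current[ci], current[cj] = current[cj], current[ci]
                alleles[name] = current.copy()
                first = False
                prev_d = d
            for name, d in ordered:
                pat = alleles[name]
                carrier_is_p1 = bool(p1.get(name, False))
                presence = pat if carrier_is_p1 else 1 - pat
                spore_presence[name] = presence[perm]
        for m in markers:
            if spore_presence[m] is None:  # homozygous marker
                val = 1 if p1.get(m, False) and p2.get(m, False) else 0
                spore_presence[m] = np.full(4, val)
        spores = {}
        for si, sn in enumerate(spore_names):
            col = f"{tname}{sn}"
            columns.append(col)
            spores[sn] = {m for m in markers if spore_presence[m][si]}
            for m in markers:
                data[m].append("+" if spore_presence[m][si] else "-")
        truth.tetrad_genotypes[tname] = spores
    table = pd.DataFrame(data, index=columns).T
    table.index.name = "marker"
    return table, truth


def simulate_microsat_profiles(
    n_populations: int = 3,
    n_strains_per_pop: int = 20,
    n_loci: int = 12,
    allele_pool_overlap: float = 0.0,
    within_pop_diversity: float = 0.5,
    aneuploidy_rate: float = 0.1,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> Tuple[Dict[str, Dict[str, Tuple[int, ...]]], TruthRecord]:
    """Simulate population-structured multilocus microsatellite profiles.

    Each population draws alleles from a per-locus pool; ``allele_pool_overlap``
    is the fraction of the pool shared between populations.  Strains carry 1-4
    alleles per locus (aneuploids allowed) and loci may be missing.  With
    ``within_pop_diversity`` 0 every strain is homozygous for its population's
    first allele.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    pool_size = 4
    n_shared = int(round(allele_pool_overlap * pool_size))
    profiles: Dict[str, Dict[str, Tuple[int, ...]]] = {}
    truth = TruthRecord(seed=seed)
    for p in range(n_populations):
        pop_pools = []
        for l in range(n_loci):
            shared = [100 * l + k for k in range(n_shared)]
            private = [100 * l + 10 + 10 * p + k for k in range(pool_size - n_shared)]
            # private alleles first: the modal allele stays population-specific
            pop_pools.append(private + shared)
        for s in range(n_strains_per_pop):
            strain = f"pop{p + 1}_s{s + 1:02d}"
            truth.marker_lineage[strain] = f"pop{p + 1}"
            prof: Dict[str, Tuple[int, ...]] = {}
            for l in range(n_loci):
                if rng.random() < missing_rate:
                    continue
                pool = pop_pools[l]
                if within_pop_diversity <= 0:
                    alleles = (pool[0], pool[0])
                else:
                    weights = np.ones(len(pool))
                    weights[0] = max(1.0, len(pool) * (1 - within_pop_diversity) / within_pop_diversity)
                    weights /= weights.sum()
                    n_alleles = 2
                    if rng.random() < aneuploidy_rate:
                        n_alleles = int(rng.integers(3, 5))
                    alleles = tuple(int(a) for a in rng.choice(pool, size=n_alleles, p=weights))
                prof[f"L{l + 1:02d}"] = alleles
            profiles[strain] = prof
    return profiles, truth


def truth_probe_partition(
    probe_design: pd.DataFrame, truth: TruthRecord
) -> np.ndarray:
    """Boolean mask over probes: True where a probe lies inside an implant."""
    inside = np.zeros(len(probe_design), dtype=bool)
    for chrom, start, end, _ in truth.introgressions:
        sel = (
            (probe_design["chrom"] == chrom)
            & (probe_design["start"] >= start)
            & (probe_design["end"] <= end)
        )
        inside |= sel.to_numpy()
    return inside
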