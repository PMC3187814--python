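"""Tetrad segregation and assortment analysis of marker matrices.

Works on Table-shaped TSV matrices: one row per marker, one column per
strain or spore, four spore columns (a-d) per complete tetrad.  Provides
spore-viability arithmetic, per-marker per-tetrad segregation ratios
(a marker heterozygous between the two parents of a cross segregates 2:2),
parental-ditype / nonparental-ditype / tetratype classification of marker
pairs, and an exact binomial test of independent assortment (unlinked
markers give PD = NPD in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import binomtest

PRESENT, ABSENT, MISSING, ALLELE = "present", "absent", "missing", "allele"

#: How raw table cells map onto presence calls.  Contig labels and the cE
#: marker letter are positives; "ND" is missing; lineage-diagnostic allele
#: labels are kept as alleles (their segregation is allele vs allele).
DEFAULT_VOCAB: Dict[str, str] = {
    "+": PRESENT,
    "-": ABSENT,
    "−": ABSENT,
    "ND": MISSING,
    "delay": PRESENT,
    "cA": PRESENT,
    "cB": PRESENT,
    "cC": PRESENT,
    "E": PRESENT,
    "UVA": ALLELE,
    "LG": ALLELE,
    "UVAR": ALLELE,
    "CARB": ALLELE,
    "MAL31": ALLELE,
    "MTY1": ALLELE,
    "MAL31/MTY1": ALLELE,
}

RATIO_CLASSES = ("4:0", "3:1", "2:2", "1:3", "0:4", "incomplete")


def viability(n_asci: int, n_germinated: int, spores_per_ascus: int = 4) -> int:
    """Percent of viable spore clones, rounded half-up to an integer."""
    if n_asci <= 0:
        raise ValueError("n_asci must be positive")
    total = n_asci * spores_per_ascus
    if not 0 <= n_germinated <= total:
        raise ValueError("n_germinated out of range")
    pct = Decimal(100 * n_germinated) / Decimal(total)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def normalize_cell(value: str, vocab: Mapping[str, str] = DEFAULT_VOCAB) -> str:
    value = str(value).strip()
    kind = vocab.get(value)
    if kind == ALLELE:
        return value  # allele labels pass through unchanged
    if kind is None:
        raise ValueError(f"unknown table cell {value!r}")
    return kind


def segregation_ratio(marker_values: Sequence[str]) -> str:
    """Ratio class from four presence calls; any missing value → incomplete."""
    vals = list(marker_values)
    if len(vals) != 4:
        raise ValueError("a tetrad has exactly four spores")
    if all(v == MISSING for v in vals):
        raise ValueError("all spores missing")
    if any(v == MISSING for v in vals):
        return "incomplete"
    if not all(v in (PRESENT, ABSENT) for v in vals):
        raise ValueError(f"non-presence values: {vals}")
    n_present = sum(v == PRESENT for v in vals)
    return f"{n_present}:{4 - n_present}"


def allele_segregation(marker_values: Sequence[str]) -> str:
    """Ratio class for a two-allele marker (e.g. lineage-diagnostic RFLP)."""
    vals = [str(v) for v in marker_values]
    if len(vals) != 4:
        raise ValueError("a tetrad has exactly four spores")
    if any(v == MISSING for v in vals):
        return "incomplete"
    alleles = sorted(set(vals))
    if len(alleles) == 1:
        return "4:0"
    if len(alleles) != 2:
        raise ValueError(f"more than two alleles in one tetrad: {alleles}")
    n = sum(v == alleles[0] for v in vals)
    n = max(n, 4 - n)
    return f"{n}:{4 - n}"


@dataclass(frozen=True)
class DitypeClass:
    marker_x: str
    marker_y: str
    tetrad: str
    klass: str  # PD | NPD | TT | unscorable


def classify_ditype(x: Sequence[str], y: Sequence[str]) -> str:
    """PD/NPD/TT for two markers that both segregate 2:2 in one tetrad."""
    try:
        if segregation_ratio(x) != "2:2" or segregation_ratio(y) != "2:2":
            return "unscorable"
    except ValueError:
        return "unscorable"
    same = [a == b for a, b in zip(x, y)]
    if all(same):
        return "PD"
    if not any(same):
        return "NPD"
    return "TT"


@dataclass
class AssortmentResult:
    pd_count: int
    npd_count: int
    tt_count: int
    p_value: Optional[float]  # exact binomial, PD = NPD among ditypes


def assortment_test(classes: Sequence[str]) -> AssortmentResult:
    """Exact binomial test of PD = NPD over scorable tetrads."""
    n_pd = sum(c == "PD" for c in classes)
    n_npd = sum(c == "NPD" for c in classes)
    n_tt = sum(c == "TT" for c in classes)
    if n_pd + n_npd == 0:
        return AssortmentResult(n_pd, n_npd, n_tt, None)
    p = binomtest(n_pd, n_pd + n_npd, 0.5).pvalue
    return AssortmentResult(n_pd, n_npd, n_tt, float(p))


@dataclass
class TetradTable:
    """Marker matrix with named tetrads of four ordered spore columns."""

    df: pd.DataFrame  # index: marker; columns: strains/spores (raw cells)
    tetrads: Dict[str, List[str]] = field(default_factory=dict)
    methodology: Optional[pd.Series] = None

    def spores(self, tetrad: str) -> List[str]:
        return self.tetrads[tetrad]

    def marker_values(self, marker: str, tetrad: str) -> List[str]:
        return [self.df.loc[marker, c] for c in self.spores(tetrad)]

    def presence(self, marker: str, tetrad: str,
                 vocab: Mapping[str, str] = DEFAULT_VOCAB) -> List[str]:
        return [normalize_cell(v, vocab) for v in self.marker_values(marker, tetrad)]


def _infer_tetrads(columns: Sequence[str]) -> Dict[str, List[str]]:
    groups: Dict[str, Dict[str, str]] = {}
    for col in columns:
        if len(col) > 1 and col[-1] in "abcd":
            groups.setdefault(col[:-1], {})[col[-1]] = col
    return {
        prefix.rstrip("-_"): [cols[l] for l in "abcd"]
        for prefix, cols in groups.items()
        if len(cols) == 4
    }


def parse_marker_table(path_or_buffer, tetrads: Optional[Dict[str, List[str]]] = None) -> TetradTable:
    """Parse a marker TSV (marker, methodology, then strain/spore columns)."""
    try:
        df = pd.read_csv(path_or_buffer, sep="\t", dtype=str,
                         index_col=False, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed marker table: {exc}") from exc
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0]) + 2  # header + 1-based
        raise ValueError(f"ragged or empty cells at line {row}")
    if df.iloc[:, 0].duplicated().any():
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise ValueError(f"duplicate marker name: {dup}")
    df = df.set_index(df.columns[0])
    methodology = df.iloc[:, 0]
    body = df.iloc[:, 1:]
    if tetrads is None:
        tetrads = _infer_tetrads(body.columns)
    return TetradTable(df=body, tetrads=tetrads, methodology=methodology)


def load_example_table() -> TetradTable:
    """The bundled marker matrix for the NBRC1948 x CBS7001 cross.

    Encodes the published four-tetrad marker table.  Note one internal
    discrepancy carried over from the source data: the cE row marks the
    CBS380T reference column positive although the accompanying text states
    that strain did not inherit cE; the tetrad columns themselves are
    unaffected.
    """
    ref = resources.files("mosaicseq.data") / "nbcb_cross_markers.tsv"
    with ref.open("r") as fh:
        return parse_marker_table(fh)


def segregation_table(
    table: TetradTable, vocab: Mapping[str, str] = DEFAULT_VOCAB
) -> pd.DataFrame:
    """Per-marker, per-tetrad ratio classes (presence or allele markers)."""
    rows = []
    for marker in table.df.index:
        for tetrad in table.tetrads:
            raw = table.marker_values(marker, tetrad)
            norm = [normalize_cell(v, vocab) for v in raw]
            if any(v not in (PRESENT, ABSENT, MISSING) for v in norm):
                klass = allele_segregation(
                    [MISSING if n == MISSING else r for r, n in zip(raw, norm)]
                )
            else:
                klass = segregation_ratio(norm)
            rows.append((marker, tetrad, klass))
    return pd.DataFrame(rows, columns=["marker", "tetrad", "ratio"])


def ditype_table(
    table: TetradTable,
    markers: Sequence[str],
    vocab: Mapping[str, str] = DEFAULT_VOCAB,
) -> List[DitypeClass]:
    """All pairwise PD/NPD/TT classes among the given presence markers."""
    out = []
    for i, mx in enumerate(markers):
        for my in markers[i + 1:]:
            for tetrad in table.tetrads:
                klass = classify_ditype(
                    table.presence(mx, tetrad, vocab),
                    table.presence(my, tetrad, vocab),
                )
                out.append(DitypeClass(mx, my, tetrad, klass))
    return out


@dataclass
class ContigContent:
    contigs: set
    conflicts: Dict[str, List[str]] = field(default_factory=dict)


def infer_contig_content(
    table: TetradTable,
    contig_map: Mapping[str, Sequence[str]],
    vocab: Mapping[str, str] = DEFAULT_VOCAB,
) -> Dict[str, ContigContent]:
    """Per-spore contig sets: a contig is present iff all its marker rows are.

    ``contig_map`` maps contig name → marker rows diagnostic for it.  Rows
    disagreeing within one spore are recorded as conflicts, not resolved.
    """
    out: Dict[str, ContigContent] = {}
    spore_cols = [c for cols in table.tetrads.values() for c in cols]
    for col in spore_cols:
        content = ContigContent(contigs=set())
        for contig, rows in contig_map.items():
            calls = [normalize_cell(table.df.loc[r, col], vocab) for r in rows]
            if all(c == PRESENT for c in calls):
                content.contigs.add(contig)
            elif any(c == PRESENT for c in calls):
                content.conflicts[contig] = [
                    r for r, c in zip(rows, calls) if c != PRESENT
                ]
        out[col] = content
    return out


#: Default mapping of the three large donor contigs to their diagnostic rows.
DEFAULT_CONTIG_MAP: Dict[str, Tuple[str, ...]] = {
    "cA": ("Contig cA",),
    "cB": ("Contig cB",),
    "cC": ("Contig cC",),
}
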