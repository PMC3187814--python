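import numpy as np
import pytest

from mosaicseq import synthio


@pytest.fixture(scope="session")
def parents():
    """One shared parent set at the default divergence regime."""
    return synthio.simulate_parents(
        seed=42, chrom_lengths=(120_000, 120_000, 120_000)
    )


@pytest.fixture(scope="session")
def mosaic_with_truth(parents):
    lengths = {c: len(s) for c, s in parents.uvarum_genome.items()}
    intervals = synthio.cabc_intervals(lengths)
    return synthio.implant_introgressions(
        parents.uvarum_genome, parents.cerevisiae_genome, intervals, seed=42
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def diverge(seq: str, sites, kind: str = "transition") -> str:
    """Substitute the given 0-based sites (transitions by default)."""
    swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
    table = swap if kind == "transition" else tv
    out = list(seq)
    for s in sites:
        out[s] = table[out[s]]
    return "".join(out)
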