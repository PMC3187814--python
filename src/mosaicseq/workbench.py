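"""Shared I/O, run configuration and the end-to-end pipeline.

Internal coordinates are 1-based inclusive everywhere; the single place
they are converted is BED export (0-based half-open).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import acgh, ancestry, microsat, phylo, synthio, tetrads

logger = logging.getLogger("mosaicseq")


# ---------------------------------------------------------------- file formats

def read_fasta(path) -> Dict[str, str]:
    """FASTA → ordered {id: sequence}; duplicate ids are an error."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_probe_tsv(path) -> pd.DataFrame:
    """Probe table: probe_id, chrom, start, end[, intensity][, telo_group]."""
    df = pd.read_csv(path, sep="\t")
    required = ["probe_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe TSV missing columns: {missing}")
    bad = df.index[(df["start"] < 1) | (df["end"] < df["start"])]
    if len(bad):
        raise ValueError(f"invalid probe coordinates at row {int(bad[0]) + 2}")
    if "intensity" in df.columns:
        neg = df.index[df["intensity"] < 0]
        if len(neg):
            raise ValueError(f"negative intensity at row {int(neg[0]) + 2}")
    return df


def write_probe_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(regions: Sequence[acgh.IntrogressionRegion], path) -> None:
    """Regions (1-based inclusive) → BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i + 1}\t"
                f"{r.mean_log_ratio:.4f}\n"
            )


def write_newick(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------- run config

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "chrom_lengths", "divergence_uv_lg",
    "divergence_ce", "neutral_target", "noise_sd", "n_replicates",
    "probe_spacing", "window_probes", "gap_merge_bp", "min_region_bp",
    "threshold_k", "n_tetrads", "bootstrap_replicates", "n_populations",
    "n_strains_per_pop", "n_loci", "allele_pool_overlap",
}

ALL_STAGES = ("simulate", "acgh-scan", "classify", "tetrad", "phylo", "microsat")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "mosaicseq_run"
    stages: Tuple[str, ...] = ALL_STAGES
    chrom_lengths: Tuple[int, ...] = (120_000, 120_000, 120_000)
    divergence_uv_lg: float = 0.07
    divergence_ce: float = 0.20
    neutral_target: float = 0.95
    noise_sd: float = 0.1
    n_replicates: int = 2
    probe_spacing: int = 250
    window_probes: int = 11
    gap_merge_bp: int = 1000
    min_region_bp: int = 1000
    threshold_k: float = 3.0
    n_tetrads: int = 100
    bootstrap_replicates: int = 100
    n_populations: int = 3
    n_strains_per_pop: int = 8
    n_loci: int = 12
    allele_pool_overlap: float = 0.25

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in mapping.items()})
        for stage in cfg.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage: {stage}")
        return cfg

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_mapping(tomllib.load(fh))

    def resolved(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["chrom_lengths"] = list(self.chrom_lengths)
        return d


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order on fully synthetic data.

    Every output under ``config.out_dir`` is reproducible from the config
    and seed alone; the resolved configuration is logged and embedded in
    the summary report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(config.resolved(), sort_keys=True))
    report: dict = {"config": config.resolved(), "stages": {}}
    seed = config.seed

    parents = synthio.simulate_parents(
        seed=seed,
        chrom_lengths=config.chrom_lengths,
        divergence_uv_lg=config.divergence_uv_lg,
        divergence_ce=config.divergence_ce,
        neutral_target=config.neutral_target,
    )
    chrom_lengths = {c: len(s) for c, s in parents.uvarum_genome.items()}
    intervals = synthio.cabc_intervals(chrom_lengths)
    mosaic, truth = synthio.implant_introgressions(
        parents.uvarum_genome, parents.cerevisiae_genome, intervals, seed=seed
    )

    if "simulate" in config.stages:
        write_fasta(mosaic, out / "mosaic_genome.fasta")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        report["stages"]["simulate"] = {
            "chromosomes": len(mosaic),
            "implanted_blocks": len(truth.introgressions),
            "implanted_bp": sum(e - s + 1 for _, s, e, _ in truth.introgressions),
        }

    if "acgh-scan" in config.stages:
        design = synthio.make_probe_design(
            parents.cerevisiae_genome, spacing=config.probe_spacing
        )
        test_reps = synthio.simulate_array(
            design, mosaic, parents.cerevisiae_genome,
            noise_sd=config.noise_sd, n_replicates=config.n_replicates,
            seed=seed + 1,
        )
        ref_reps = synthio.simulate_array(
            design, parents.uvarum_genome, parents.cerevisiae_genome,
            noise_sd=config.noise_sd, n_replicates=config.n_replicates,
            seed=seed + 2,
        )
        scan_cfg = acgh.ScanConfig(
            window_probes=config.window_probes,
            gap_merge_bp=config.gap_merge_bp,
            min_region_bp=config.min_region_bp,
            threshold_k=config.threshold_k,
        )
        smoothed, regions = acgh.scan_pipeline(test_reps, ref_reps, scan_cfg)
        count, total_kb = acgh.summarize_regions(regions, config.min_region_bp)
        write_bed(regions, out / "regions.bed")
        write_probe_tsv(
            smoothed.df.rename(columns={"value": "log_ratio"}),
            out / "log_ratios.tsv",
        )
        report["stages"]["acgh-scan"] = {
            "regions": len(regions),
            "regions_gt_min": count,
            "total_kb_gt_min": total_kb,
        }

    if "classify" in config.stages:
        calls = []
        step = max(1, len(parents.genes) // 20)
        for gene in parents.genes[::step][:20]:
            s, e = gene.start - 1, gene.end
            query = mosaic[gene.chrom][s:e]
            call = ancestry.classify_marker(
                f"{gene.chrom}:{gene.start}-{gene.end}",
                query,
                parents.cerevisiae_genome[gene.chrom][s:e],
                parents.uvarum_genome[gene.chrom][s:e],
            )
            calls.append(call)
        pd.DataFrame(
            [
                (c.marker, c.lineage, c.identity_to_cerevisiae, c.identity_to_uvarum)
                for c in calls
            ],
            columns=["marker", "lineage", "id_cerevisiae", "id_uvarum"],
        ).to_csv(out / "marker_calls.tsv", sep="\t", index=False)
        report["stages"]["classify"] = {
            "markers": len(calls),
            "lineage_counts": {
                k: int(v)
                for k, v in pd.Series([c.lineage for c in calls])
                .value_counts()
                .sort_index()
                .items()
            },
        }

    if "tetrad" in config.stages:
        p1 = {"cA": True, "cB": True, "cC": True}
        p2 = {"cA": False, "cB": False, "cC": False}
        table, _ = synthio.simulate_meiosis((p1, p2), config.n_tetrads, seed=seed + 3)
        table.to_csv(out / "tetrads.tsv", sep="\t")
        ttable = tetrads.TetradTable(
            df=table,
            tetrads={
                t: [f"{t}{s}" for s in "abcd"]
                for t in sorted({c[:-1] for c in table.columns})
            },
        )
        classes = [
            d.klass
            for d in tetrads.ditype_table(ttable, ["cA", "cB", "cC"])
            if d.klass != "unscorable"
        ]
        res = tetrads.assortment_test(classes)
        report["stages"]["tetrad"] = {
            "tetrads": config.n_tetrads,
            "PD": res.pd_count,
            "NPD": res.npd_count,
            "TT": res.tt_count,
            "p_value": res.p_value,
        }

    if "phylo" in config.stages:
        gene = parents.genes[0]
        s, e = gene.start - 1, gene.end
        aln = {
            "uvarum": parents.uvarum_genome[gene.chrom][s:e],
            "lager": parents.lager_genome[gene.chrom][s:e],
            "hybrid": mosaic[gene.chrom][s:e],
            "cerevisiae": parents.cerevisiae_genome[gene.chrom][s:e],
        }
        tree = phylo.bootstrap_support(
            aln, n_replicates=config.bootstrap_replicates, seed=seed + 4
        )
        write_newick(tree, out / "marker_tree.nwk")
        report["stages"]["phylo"] = {
            "taxa": len(aln),
            "tree_length": round(phylo.tree_total_length(tree), 6),
        }

    if "microsat" in config.stages:
        profiles, ms_truth = synthio.simulate_microsat_profiles(
            n_populations=config.n_populations,
            n_strains_per_pop=config.n_strains_per_pop,
            n_loci=config.n_loci,
            allele_pool_overlap=config.allele_pool_overlap,
            seed=seed + 5,
        )
        tree = microsat.cluster_tree(profiles, seed=seed + 6)
        write_newick(tree, out / "microsat_tree.nwk")
        purity = microsat.nearest_neighbor_purity(tree, ms_truth.marker_lineage)
        report["stages"]["microsat"] = {
            "strains": len(profiles),
            "nearest_neighbor_purity": round(purity, 4),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
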