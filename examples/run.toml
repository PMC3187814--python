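# Demo configuration for the end-to-end synthetic analysis:
#   mosaicseq run --config examples/run.toml
seed = 11
out_dir = "demo"
chrom_lengths = [120000, 120000, 120000]
divergence_uv_lg = 0.07
divergence_ce = 0.20
neutral_target = 0.95
noise_sd = 0.1
n_replicates = 2
n_tetrads = 100
bootstrap_replicates = 100
n_populations = 3
n_strains_per_pop = 8
n_loci = 12
allele_pool_overlap = 0.25
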