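# Methods

`mosaicseq` implements the computational chain used to characterise yeast
strains whose genomes are mosaics of three parental lineages: a
*Saccharomyces uvarum*-like recipient background, a closely related
"lager-type" sister lineage at roughly 93% nucleotide identity to
*S. uvarum*, and subtelomeric blocks introgressed from a distant
*S. cerevisiae*-like donor (~80% identity). The package couples a
ground-truthed simulator of this situation to the five analysis stages a
study of such strains needs: comparative-hybridization scanning,
identity-based lineage classification, tetrad genetics, distance-based
phylogenetics, and microsatellite clustering.

## Synthetic data model (`synthio`)

**Parent genomes.** The recipient (uvarum-like) genome is i.i.d. uniform
ACGT per chromosome (default three chromosomes of 120 kb). The lager-like
genome is derived from it by substitutions at rate `divergence_uv_lg`
(default 0.07, i.e. ~93% identity, the observed lager-type regime); the
cerevisiae-like donor is derived independently at `divergence_ce` (default
0.20). Substitutions carry a 2:1 transition:transversion bias, consistent
with the two-parameter substitution model used downstream.

**Neutral placement.** Each chromosome carries a toy annotation of in-frame
999-bp genes separated by 201-bp intergenes (chosen only so that codon
structure exists; it does not mimic real gene models). Coding substitutions
between uvarum and lager are placed in distinct codons, a fraction
`neutral_target` (default 0.95) of them synonymous — third codon position
first, the two other positions as fallback; ATG/TGG codons, which admit no
synonymous change, are skipped. Placing each substitution in its own codon
makes the realized nucleotide divergence equal the request up to rounding
(the ±0.5-point invariant) and the synonymous fraction track its target. At
these defaults the deduced proteins are ~98.9% identical and >99% similar
under BLOSUM62 — the "almost all neutral SNPs, near-identical proteins"
signature of a recently diverged sister lineage.

**Introgressions.** `implant_introgressions` splices donor sequence over
1-based inclusive intervals of the recipient (coordinates are 1-based
inclusive throughout the package; the only conversion is BED export).
The `cABC` preset implants three subtelomeric blocks, one per chromosome,
ending 2 kb before the chromosome end. Only one of the three published
contig lengths is known exactly (30,803 bp); the other two are set to
20,000 and 19,000 bp so the trio totals ~70 kb as reported for the shared
donor content.

**Array signal.** Probes tile the donor-design genome (50-mer footprints
every 250 bp by default). A probe's noiseless intensity is a three-plateau
double-logistic in the percent identity between the probe footprint in the
design genome and the same footprint in the sample: background 100 units
below ~80% identity, an intermediate plateau ~1,500 around 93%, and a high
plateau 10,000 above ~99%. The plateau heights and logistic midpoints are
calibration knobs — the source experiments report only the qualitative
classes (strong, weak-but-visible for ~20%-diverged probes, background).
Noise is multiplicative log-normal with sd `noise_sd` (default 0.1) per
replicate. 50-mer footprints are used instead of 25-mers because the chance
of a fully conserved 25-mer inside 20%-diverged background is 0.8^25 ≈ 0.4%
per probe — enough to sprinkle full-intensity singletons through the
background — while 0.8^50 is negligible; the shorter real oligos are partly
why the real platform cannot distinguish 90%-identical paralogs.

**Meioses.** Tetrads are simulated marker-wise. Every marker heterozygous
between the parents segregates 2:2 by construction. Unlinked markers draw
their spore pattern uniformly from the six 2:2 patterns, giving the
classical 1:1:4 PD:NPD:TT expectation; linked pairs run a four-chromatid
model in which the number of crossovers between loci is Poisson with mean
(map distance in cM)/50 and each crossover exchanges the distal alleles of
one chromatid from each parental pair. k = 0 crossovers gives PD, one gives
TT, and two or more mix PD/NPD/TT in the standard no-interference ratios.

**Microsatellites.** Each population draws from per-locus allele pools of
size 4 with `allele_pool_overlap` of the pool shared across populations
(private alleles listed first so the modal allele is population-specific);
strains are diploid with occasional 3-4-allele aneuploid loci
(`aneuploidy_rate` 0.1) and missing loci (`missing_rate` 0.05). These rates
emulate the reported 5-11 amplifiable loci of 12 in partially cerevisiae
hybrids. What the generator does *not* model: stepwise mutation, linkage
between loci, admixed individuals — so passing tests show the distance and
clustering machinery is correct, not that real strain histories are
recoverable.

## Comparative-hybridization scan (`acgh`)

The chain is background subtraction → replicate normalization → log2
ratios → (display smoothing) → segmentation → gap merge → summary.

- **Background**: probes are split in genome order into 16 zones; each
  zone's background is the mean of its lowest 2% of intensities, probes
  subtract a value interpolated between zone centres, and results are
  floored at 1% of the track median (a *relative* floor keeps the whole
  chain invariant to rescaling both channels). Zone estimates that are
  outliers against the other zones (beyond median + 3·1.4826·MAD of the 16
  estimates) are clamped to that bound: a zone lying wholly inside an
  introgressed block would otherwise report the signal itself as
  background. Smooth background trends pass the clamp untouched. This is a
  deliberately simple stand-in for the commercial zoned-background
  algorithm it replaces, specified so it is fully testable.
- **Normalization**: the second replicate is divided by the least-squares
  through-origin slope of its regression on the first, then replicates are
  averaged. (Whether the original analysis included an intercept is
  unknown; through-origin is the simplest defensible choice.)
- **Ratios**: log base 2 (the array convention; the source says only "log
  ratio").
- **Smoothing**: an 11-probe centered moving average per chromosome
  (window truncated at ends) is computed for plotting and summaries, but
  segmentation runs on the raw per-probe ratios: the 11-probe window is a
  display device, and detecting on raw ratios keeps boundaries at probe
  resolution.
- **Segmentation**: background level = track median; spread = MAD scaled
  by 1.4826, with an absolute lower bound of 0.05 log2 units so the
  elevation threshold stays meaningful on noiseless tracks where the MAD
  degenerates to zero (0.05·3 ≈ a minimum detectable fold change of 1.11).
  A probe is elevated above median + k·spread (k default 3 — an exposed
  parameter, not a published value); maximal runs of ≥2 elevated probes
  become regions spanning first-probe start to last-probe end.
- **Gap merge**: regions on one chromosome separated by <1 kb of genomic
  gap are merged, treating sub-kilobase gaps as false-negative probes
  inside one contiguous introgression. At 250-bp probe spacing this also
  absorbs single-probe dips caused by cross-hybridizing (locally conserved)
  probes inside real blocks. Merging is idempotent.
- **Telomeric dedup**: probes sharing a `telo_group` label (repeats present
  at many chromosome ends) are counted once per region.

Performance, measured by `validation.scan_recovery_experiment` (one random
3-8-kb block per seed in an 80-kb chromosome, two replicate arrays per
condition as in the two-chips-per-strain protocol, noise sd 0.1): ≥95% of
blocks recovered with boundary error ≤ one probe spacing over 100 seeds,
and zero false >1-kb regions in noiseless runs. With a single replicate per
condition, recovery drops to ~91-94% because noise-amplified background
probes adjacent to a block occasionally extend its boundary.

## Lineage classification (`ancestry`)

Percent identity uses Biopython's global aligner (match +1, mismatch −1,
gap open −5, extend −1); identity = matches / aligned columns with gap
columns counted against identity (a conservative, reproducible convention —
the original alignment parameters are unstated, so reproductions may differ
by ~±1 point). Decision order: cerevisiae if ≥99% to the cerevisiae
reference; else uvarum if ≥98% to the uvarum reference; else lager-type if
identity to uvarum falls in [91, 98); else a chimera test, and failing
that, ambiguous. The lager band's lower edge is 91 because published
lager-type alleles range from 91% to 95% identity to uvarum, even though a
figure caption summarises them as "2 to 6%" divergence; the band's upper
edge defers to the 98% uvarum rule.

Breakpoint detection aligns the query to both references, projects match
indicators onto query coordinates, and picks the split p maximising
matches(5′ segment vs one reference) + matches(3′ segment vs the other)
over both orderings. Within the inevitable tie plateau (positions where
both references agree) the largest p is chosen, so a pure-parent query
returns the degenerate p = length. A chimera call requires the split to
improve the length-weighted identity by ≥2 points over the best single
assignment (exposed as `chimera_margin`), which suppresses spurious
breakpoints between near-identical references.

`neutral_fraction` counts differing sites whose codons translate
identically (standard code; nuclear genes only); zero differing sites
returns None, not 0 or 1. `predict_truncation` translates frame 1 to the
first stop; "premature" means the stop precedes the final codon, and a
missing stop is flagged rather than silently treated as full length.

## Tetrad genetics (`tetrads`)

Viability is 100·germinated/(asci·4) rounded half-up (36/52 → 69%).
Segregation ratio classes come from present:absent counts over the four
spores, with any missing spore yielding "incomplete"; two-allele markers
(e.g. lineage-diagnostic RFLP patterns) are classed by allele counts. Cell
vocabulary mapping (+, −, contig labels, allele labels, ND→missing,
delay→present) is a declared dictionary, not ad hoc parsing. PD/NPD/TT is
defined only where both markers segregate 2:2: PD when the spore
partitions coincide, NPD when they are exactly complementary, TT otherwise.
Independence is tested with the exact binomial PD = NPD among ditype
tetrads — the published claim rests on four tetrads, far too few for
power, so the package formalises the test and validates it at scale on
simulated crosses (at 1,000 tetrads, unlinked markers stay above p = 0.01
in ≥95% of runs; 1-cM linkage drives PD ≫ NPD and p < 0.01). Map-distance
estimation is deliberately out of scope.

The bundled marker table reproduces the published cross matrix (two fully
genotyped tetrads plus parents and two reference strains). One discrepancy
is carried over from the source and flagged rather than resolved: the cE
row marks one reference strain positive while the accompanying text states
it did not inherit that contig; the tetrad columns are unaffected.

## Phylogenetics (`phylo`)

K2P, NJ and bootstrap are implemented directly (they are the computation
under test); dendropy provides the tree container and Newick codec, and
serves as the independent oracle in the test suite (its NJ and midpoint
rooting must agree with ours).

- `count_substitutions` removes, per pair, every column where either
  sequence carries a gap or non-ACGT symbol (pairwise deletion — chosen
  over complete deletion because ambiguous positions are removed "for each
  sequence pair").
- `k2p_distance` is −½ln(1−2P−Q) − ¼ln(1−2Q); a non-positive log argument
  raises an explicit saturation error instead of returning infinity.
- `nj_build` is canonical neighbor-joining with Q-criterion selection,
  rate-corrected branch lengths, lowest-index tie-breaking (determinism),
  and negative branch lengths clamped to zero with the deficit moved to
  the sister edge so path lengths are preserved. On additive matrices the
  generating tree is reproduced exactly (validated on 200/200 random 4-12
  taxon trees).
- `bootstrap_support` resamples alignment columns with replacement
  (default 100 replicates), rebuilds the K2P/NJ tree, and reports for each
  internal bipartition of the original tree the percentage of replicates
  containing it. Saturated replicates are skipped but stay in the
  denominator (they are evidence of instability, not missing data).

## Microsatellite clustering (`microsat`)

Aneuploid loci (3-4 alleles) are first reduced to two by uniform random
discard (seeded; validated unbiased by chi-square over 3,000 seeds).
Within-strain frequencies are 1.0 for a homozygote, 0.5/0.5 for a
heterozygote. The Cavalli-Sforza–Edwards chord distance is used with
per-locus averaging over the loci scored in both strains:
d_l² = 2(1 − Σ_a √(x_la·y_la)), D = √(mean_l d_l²). Averaging (rather than
summing) over shared loci keeps strains with different locus coverage
comparable, which is the point of the missing-data handling; whether the
original analysis averaged or summed is unstated, so the averaged form is
documented as the package's choice. D is bounded by √2, attained at
disjoint allele sets. Trees are NJ on the chord matrix, midpoint rooted:
the root bisects the longest leaf-to-leaf path, ties broken by
lexicographic leaf-pair order, and an all-zero-length tree roots at the
first internal node with a warning.

## Workbench

Coordinates are 1-based inclusive internally; BED export converts to
0-based half-open in one tested place. FASTA I/O goes through Biopython
(duplicate ids rejected), probe tables are TSV with validated coordinates
and non-negative intensities, trees are Newick via dendropy. `RunConfig`
reads TOML, rejects unknown keys before execution, and the full resolved
config is logged and embedded in the summary report, so every output is
reproducible from config + seed. The end-to-end `run` command executes
simulate → scan → classify → tetrad → phylo → microsat on synthetic data
in a few seconds on one CPU.

## Problem sizes and tolerances

Default validation sizes — three 120-kb chromosomes, 250-bp probe spacing,
100-seed scan experiments, 100×1,000-tetrad crosses, 200 NJ property
cases, 3,000-seed discard audits — were chosen so the full suite and the
acceptance script each complete in well under a minute while keeping every
statistical check far from its decision boundary. Numerical tolerances:
K2P versus closed form at 1e-10; Newick round trips at 1e-10 on lengths;
alignment-dependent identity checks at ±1-1.5 points; stochastic
recovery/balance checks at the rates stated above.

## Known limitations

- The array signal model is qualitative; absolute intensities and the
  identity-response midpoints are not fitted to any measured
  cross-hybridization curve.
- Classification thresholds act on global-alignment identity; genes with
  large indels or paralogy would need curated references.
- One breakpoint per gene; multi-junction chimeras are out of scope.
- The meiosis model has no chromatid interference and no gene conversion.
- Real-data reproduction of the published region counts and tree lengths
  requires the original array data and deposited sequences (external
  downloads) and inherits their alignment-tool dependence; the package
  validates the machinery on synthetic truth instead.
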