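# Methods

`rrbskit` implements a reduced-representation bisulfite sequencing (RRBS)
plus RNA-seq methylome analysis as a reusable pipeline, together with a
synthetic-data generator that plants the biological structure the
analysis is meant to recover. This note records the models, the
parameters that matter, the numerical choices, and what a passing test
does and does not establish.

## The analysis pipeline

**Reduced genome.** MspI cuts C^CGG; the digestion fragments within a
length window (20–180 bp for the alignment index, mirroring the
BS-seeker2-style build) form the reduced genome. Each fragment is indexed
twice in three-letter space: C→T converted forward, and C→T of its
reverse complement (equivalent to a G→A reverse index). Size selection is
inclusive at both bounds. Fragments containing N are kept, but cytosines
whose context involves an N are excluded from calling.

**Alignment.** Reads are C→T collapsed and matched by exact seed k-mer
lookup (seed length 20); if the exact seed misses, all single-substitution
neighbours are probed (1 seed mismatch). Candidates are scored by total
mismatches in converted space, with at most 2 per read; a tie for the
best placement is ambiguous and the read is discarded. This is a
deliberate simplification of a seeded short-read aligner: no gaps, no
quality weighting, sufficient for error-free simulated reads and exact to
test.

**Calling.** For each reference cytosine covered by a uniquely aligned
read, a strand-appropriate C (or G on the minus strand, in fragment
orientation) counts as methylated, T (A) as converted, anything else is
non-informative. Context (CpG/CHG/CHH) comes from the reference, never
from reads. CpG counts from the two strands are summed into one record
keyed at the plus-strand C position. Counts are kept as integers; the
level is their exact ratio, so "unmethylated (0 %)" is an exact equality.

**Site filters.** A site is high-confidence if covered by ≥ 10 reads in
at least one sample and shared if covered by ≥ 10 in every sample;
comparative analyses use shared sites after SNP exclusion.

**Conversion rate.** Estimated as converted/(converted + unconverted)
over non-CpG cytosine read-bases. This assumes true non-CpG methylation
is ≈ 0; with the generator's default non-CpG means the estimate is biased
low by roughly the mean non-CpG methylation (~0.004). The estimator is
validated on a world simulated with zero non-CpG methylation, where it
recovers the planted 94.27 % rate within ±0.005.

**SNP exclusion.** A simple maximum-likelihood diploid genotyper
(per-base error rate ε = 0.01, ties toward hom-ref) stands in for the
external caller. Variants pass with depth inside
[max(4, ⌊mean/3⌋), round-half-up(1.75·mean)] and mean MAPQ ≥ 20; the
mean coverage is taken over covered positions only. A combined CpG site
is *tested* in a dataset if either dinucleotide position meets that
dataset's window, carries a SNP if a passing variant overlaps either
position, and the exclusion set is the union over datasets. Non-CpG
cytosines are excluded when their own position carries a SNP or the
3′-adjacent position carries a CpG-creating variant (alt G downstream of
a plus-strand C, mirrored on the minus strand). Report percentages are
formatted at two decimals, round-half-up.

**Regions and statistics.** TSS windows are 300 bp upstream to 200 bp
downstream of the TSS (orientation-aware); gene bodies exclude the 5′ 5 %
of the span; shores (CGS) are 2 kb flanks truncated at neighbouring CGIs
and chromosome ends (2 kb is the community convention; the width is
exposed). Dinucleotide densities count plus-strand start positions per
100 bp. Group comparisons dispatch on normality (Shapiro–Wilk for
n ≤ 5000, else Kolmogorov–Smirnov), use an F-test to choose pooled vs
Welch t-tests, and otherwise fall back to Wilcoxon tests. The
X-vs-autosome comparison is one-sided (elevation). Spearman correlation
uses average ranks and the large-sample t approximation for p.

**ASE.** Sites need RNA depth ≥ 10, no second SNP within 20 bp (both
removed), no indel within 15 bp, and heterozygote balance
min/max ≥ 0.3 — applied to DNA counts by default, since applying it to
RNA would delete true allelic imbalance (an RNA-level reading is an
option). The exact two-sided binomial test (minimum-likelihood
definition) and Benjamini–Hochberg correction give per-SNP q-values; a
gene is ASE only if *all* its retained SNPs have q < 0.05, and
mono-allelic if additionally every SNP has zero reads on one consistent
allele side (majority side when unphased — stricter than requiring any
zero side, and flagged as such).

**Clustering and validation.** Tissues are clustered on shared-site
levels with Ward.D2 (scipy's `ward` on Euclidean distances, identical to
R's `ward.D2`). Bootstrap support resamples sites with replacement;
support is the percentage of replicates containing each original
cluster. Only ordinary bootstrap probabilities are computed; the
multiscale "approximately unbiased" p-value is a possible future
extension. Resampling is implemented through multinomial row weights in
the Gram matrix — algebraically identical to materialising each
replicate, and fast enough for 10⁴ replicates on large site matrices.
Top changes between two tissues are the 10 largest increases and 10
largest decreases **of the level itself**; each record carries
log2(b/a) with ±6 substituted when one side is zero (both-zero sites are
excluded), and the capped log2 changes are what the cross-dataset
validation counts signs on and correlates. Ranking by the capped log2
change instead would degenerate: at depth ~20, thousands of sites tie at
exactly ±6 through sampling noise alone.

## The synthetic world

The generator's defaults are a fixed stated world; they were chosen to
emulate the study design at desk scale and are not adjusted per run.

* **Genome**: 2 autosomes + X with tapered lengths (850, 680, 544 kb;
  ~2 Mb total). Background sequence is uniform-random with 35 % of
  background CpGs broken (C→T), emulating vertebrate CpG depletion —
  this is what gives RRBS genuine enrichment (retained fragments carry a
  several-fold larger share of CpGs than of genome length) and starves
  WGS of depth specifically at CpG-rich sites.
* **Genes**: 340, lengths 1.5–2.6 kb, 2–4 exons, placed on a jittered
  grid with ≥ 2.8 kb clearance so neighbouring promoters stay out of
  each other's ±2 kb metagene windows.
* **CGIs**: 290, lengths 0.4–1.2 kb, ~25 CpG/100 bp (≥ 4× background);
  85 % are centred on a TSS (~73 % of genes get a CGI promoter,
  comparable to mammalian genomes and necessary for ≥ 200 genes to enter
  promoter-methylation correlations). CGI placement, TSS anchoring and
  promoter-replacement picks are stratified per chromosome: a full-size
  genome has essentially deterministic per-chromosome composition, and
  an unstratified miniature injects spurious chromosome effects that
  confound the X-vs-autosome null.
* **Methylome**: CpG probabilities are a two-component mixture — low
  (Beta, mean ≈ 0.045) in CGIs, high (Beta(20, 5), mean 0.8) elsewhere,
  with gene bodies at 0.68–0.82 rising weakly with expression. Promoters
  follow a convex edge ramp anchored at the TSS (uniformly low across
  the promoter, rising steeply near the island edge, plus a small linear
  term that pins the profile minimum to the anchor bin); the promoter
  floor rises from 0.05 toward 0.65 as expression falls, which plants
  the TSS methylation–expression anticorrelation. CpG probabilities are
  strand-symmetric. Non-CpG cytosines: Beta with means 0.0055 (CHG) and
  0.003 (CHH). A female methylome shifts X CpG probabilities halfway to
  0.85 (inactivation mixture); a male one does not. 5 % of CpG sites are
  tissue-variable in a switch-like way (independently low ≈ 0.03 or high
  ≈ 0.8 per tissue), emulating tissue-specific differentially methylated
  sites — the signal the cross-individual top-change validation relies
  on. All truth-level draws derive from `truth_seed`, so two individuals
  with different `seed` share one biology.
* **Expression and promoter erosion**: FPKM is log-normal with 27.57 %
  exact zeros. In 70 % of low-expression (FPKM < 1) genes, each TSS-window
  CpG is rewritten to TpG with probability 0.5 or ApG with probability
  0.1 — the fixed sequence trace of 5-methylcytosine deamination. This
  mechanism alone produces the positive CpG-density and negative
  TpG-density correlations with expression (ApG weaker), and their
  absence when the replacement fraction is zero.
* **Variants**: heterozygous SNPs at 0.5 % of CpG sites (C→T or G→A,
  CpG-destroying), ~150 CpG-creating variants (alt G after a C),
  scattered non-CpG SNPs, and 2 exonic het SNPs for each gene entering
  the allelic analysis. Reads are drawn from a random haplotype, so SNP
  alleles bias methylation calls exactly as they would in real data.
* **Sequencing**: each RRBS read spans one strand of one size-selected
  (30–160 bp) fragment; cytosines read C with probability
  p + (1−p)(1−0.9427). Reads are otherwise error-free (sequencing error
  is a knob, default 0; trimming is out of scope). RRBS depth target is
  20 reads/fragment — with 8 samples and the ≥ 10 rule this loses a few
  per cent of sites, as intended. Control pileups are Poisson(12.7) over
  retained fragments; WGS pileups are Poisson(25 · exp(−0.1 · w)) where
  w is the CpG count of the surrounding 100 bp (any monotone GC-bias
  penalty suffices; this one reproduces the tested-fraction contrast
  between control and WGS). Allelic RNA counts are binomial at allele
  probability 0.5 / 0.8 (fixed direction per gene) / 1.0 for
  none / ASE / mono-allelic genes at Poisson(50) depth; the observed
  FPKM table adds log-normal noise (σ = 0.2).

## What a green test establishes — and does not

The simulator plants precisely the structure the pipeline is asked to
recover, with binomial read noise, incomplete conversion, SNP
contamination and GC-bias as the only corruptions. A passing recovery
test therefore establishes that the implementation is faithful to its
own model, not that the model captures real tissue; in particular there
are no PCR duplicates, no adapter or quality artefacts, no mapping bias
(fragments are unique by construction), and expression is consumed as a
given table rather than estimated from reads.

Scale caveats, all consequences of a ~2 Mb genome: the X is ~27 % of the
genome (vs ~5 % real), so pooled level histograms over-weight the
X-inactivation mid-mass and bimodality is judged on autosomes; with
~100 genes per chromosome, chromosome-level composition noise is visible
to site-level tests (hence the stratified allocation and the one-sided
elevation test); and absolute site counts are ~20× smaller than the
study's.

## Numerical choices

Coordinates are 0-based half-open everywhere internally; 1-based only in
VCF-like and CGmap-style output, BED output 0-based half-open. Depth
windows use floor for the lower bound (with a floor of 4 reads) and
round-half-up for the upper; the published control upper bound (20) is
not reproducible from 1.75 × 12.7 under any standard rounding and the
formula is kept as stated. Report percentages are two-decimal
round-half-up. Genotype ties break toward hom-ref, then het. Bootstrap
supports, all simulations and the generator are deterministic under
their seeds; per-operation RNG streams are derived as
`default_rng([stream_id, seed])`, so adding an operation never shifts
another's draws.
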