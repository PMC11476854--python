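# Methods

## Scope

`autozyg` implements the post-variant-calling stages of a case–control
genome comparison for a single proband: SNV retention, runs-of-homozygosity
(ROH) detection, genomic and pedigree inbreeding, ROH–gene overlap and
keyword triage of enrichment tables. Alignment, duplicate marking, variant
calling, functional annotation and genome-build liftover are upstream of the
package: it consumes a merged, genotyped multi-sample VCF.

## Variant retention

The chain mirrors a GATK SelectVariants/VariantFiltration workflow.

- **SNP-only selection** keeps records whose ref and every alt are single
  nucleotides; a record with any non-SNV allele is dropped whole (record-level
  semantics, as in `--select-type-to-include SNP`).
- **Hard filters** use strict inequalities exactly as written in the filter
  expression (QD < 2.0, FS > 60.0, MQ < 56.0, SOR > 3.0, MQRankSum < −12.5,
  ReadPosRankSum < −8.0). A value sitting on a threshold passes. A record
  lacking an annotation passes that filter, matching VariantFiltration's
  treatment of missing annotations.
- **Depth rule.** Site-level INFO DP is compared against the nearest-rank
  75th percentile of the DP values of the table being filtered (the value at
  1-based sorted position ⌈q·n⌉ — unambiguous and always an observed value).
  The default discards records with DP *below* that percentile, i.e. keeps
  only the deepest quartile of sites. This is an unusually aggressive
  direction for a depth filter, and is therefore switchable
  (`dp_direction="above"`), but the aggressive variant is the default because
  it is the workflow this package reproduces. The threshold is computed
  before any downstream subsetting, so later stages cannot shift it.
- **Known-variant exclusion** removes records whose (chrom, pos, ref, alt)
  match a known set (a dbSNP export); a multi-allelic record is removed only
  when every alt is known, so novel alleles at known sites survive.
  Position-only matching is available as an option. The known set must
  already be in the analysis genome's coordinates.
- **Proband-unique selection** keeps records where every sample is called,
  the proband carries an alt allele, and at least one proband alt is absent
  from every control in any dose. Haploid (MT) calls follow the same rule
  with single-allele genotypes.

## ROH detection

The scanner reconstructs the behaviour of `plink --homozyg`. Only the two
segment-level constraints (≥100 SNPs, >1000 kb) were study-specific; the
window machinery uses PLINK 1.9's published defaults, and every knob is a
field of `RohParams`:

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 50 | SNPs per scanning window |
| `window_het_max` | 1 | hets allowed in a "homozygous" window |
| `window_missing_max` | 5 | missing calls allowed per window |
| `window_hit_fraction` | 0.05 | min. fraction of covering windows that are homozygous for a SNP to be a run candidate |
| `max_gap_kb` | 1000 | split runs at larger inter-SNP gaps |
| `min_snps` | 100 | min. SNPs per reported segment |
| `min_kb` | 1000 | min. length (strict) per reported segment, kb |
| `min_density_kb_per_snp` | 50 | max. average spacing within a segment |

Candidate runs are trimmed so both endpoints are homozygous non-missing
SNPs; segment length is end − start + 1 bp (1-based inclusive). When a
chromosome carries fewer SNPs than `window_snps`, a single window spanning
all its SNPs is used. X and MT are never scanned — F_ROH is an autosomal
quantity.

PLINK's own trimming and density bookkeeping have undocumented corners; this
package's semantics are *defined* by the in-repository brute-force oracle
that materializes every window and candidate run, and the vectorized scanner
is tested for exact agreement with it on hundreds of random genotype
vectors. Numerical identity with PLINK on real data is not claimed. One
visible consequence of the window-fraction rule: a homozygous block embedded
in dense heterozygous flanks loses one SNP at each edge (too few homozygous
windows cover the outermost SNPs), so a 120-SNP block is reported with 118
SNPs; the same block occupying a whole chromosome keeps all 120.

## Inbreeding

F_ROH = total autosomal ROH length / autosomal genome length (default
2,212,284 kb, the CanFam6 autosome total; configurable per build). The
pedigree expectation uses the standard kinship recursion, descending on the
individual farther from the founders, with memoization; founders are
mutually unrelated and may carry a per-founder inbreeding coefficient
(`founder_f`). The sib-mating expectation at breed baseline b has the closed
form ¼·(1 + b); the package exposes both the closed form and the recursion
with inbred founders and asserts their equality. Reported coefficients are
rounded half-up (0.284 → 0.28, 0.286 → 0.29); raw values are retained.
The baseline itself is the arithmetic mean of the control F_ROH values
(computed with `math.fsum`, so it is permutation-invariant).

## Gene overlap and triage

A gene is assigned to a segment on ≥1 bp of intersection after converting
BED half-open coordinates to the package's 1-based inclusive convention;
full containment is available as an option. Keyword triage retains
enrichment rows whose *term* contains any keyword case-insensitively as a
substring (gene names are not searched); the default keywords are
"Development", "Sex" and the stem "hermaphrodit" (covering both
"hermaphroditism" and "hermaphroditic"). An optional pattern list
(`MIR*`, `OR*` by default) models portal-side loss of miRNA and
olfactory-receptor symbols; the `OR*` default is deliberately broad.

## Synthetic data

The simulator generates what the pipeline consumes, with full truth:

- **Marker backdrop.** Default desk-scale genome: 4 autosomes × 120 Mb with
  40,000 markers each (~1 marker/3 kb), ~1 cM/Mb, plus an X of the same size
  and a 16.7 kb haploid MT with 60 markers. Alt-allele frequencies are drawn
  uniformly in [0.1, 0.5].
- **Founders.** Haplotypes are drawn per chromosome from a finite pool;
  founders sample the pool with replacement. A pool of K haplotypes gives a
  per-locus coalescence probability of ~1/K between any two draws, so the
  pool size is the baseline-autozygosity dial: the default K = 8 puts
  founder-level autozygosity near 0.125, on the order of the control dogs'
  F_ROH (~0.13–0.14). `founder_pool_size=None` gives every founder unique
  haplotypes ("clean" founders, baseline 0) for calibration tests. Pool
  indices ride along as ancestry labels, so identity of labels is identity
  by descent and each individual's true autozygous fraction and segments are
  known exactly.
- **Meiosis.** Crossovers are a Poisson process at the chromosome's cM/Mb
  (Haldane model, no interference), with a random start phase; the MT genome
  is copied maternally without recombination. The X is gene-dropped as an
  ordinary diploid chromosome — adequate here because the case animal is XX,
  but male hemizygosity and X-specific recombination are not modelled.
- **Pedigree.** The default quartet mirrors the study family: proband =
  offspring of two full sibs (shared founder grandparents), with the sire and
  two controls (each bred from its own founder pair) as the comparison
  genomes. Controls are one generation below their founders so their
  baseline ROH is broken up by one round of recombination rather than being
  whole-chromosome blocks.
- **Proband-only variants.** 43 de-novo SNVs are injected at off-marker
  positions, split 20/9/14 across autosomes/X/MT, with 8 of the X variants
  packed into one 800 bp span; the proband is het (haploid-alt on MT), all
  controls reference.
- **Quality annotations.** Each record receives DP plus the six filterable
  annotations drawn inside the passing region; a configurable fraction
  instead violates exactly one named threshold, with the truth label
  retained, so filter verdicts can be checked against truth at 100%.

What the simulator does *not* emulate: linkage disequilibrium within founder
haplotypes beyond pool sharing, allele-frequency spectra of real dog
populations, sequencing-error or genotype-likelihood models, indels, and
male X hemizygosity. Passing tests therefore demonstrate algorithmic
correctness (segment calling, filtering logic, pedigree arithmetic,
truth recovery), not calling accuracy on real sequencing data.

Determinism: every stochastic step flows from one integer seed through
`numpy.random.default_rng` (PCG64), so identical configurations reproduce
byte-identical outputs across platforms.

## Pipeline ordering

After hard filtering the workflow branches: known-variant exclusion and
proband-unique selection on one side, ROH detection on the other. ROH runs
on the hard-filtered SNP backdrop because excluding known (common) SNPs
would remove precisely the polymorphic markers homozygosity scanning needs,
while the unique-variant branch requires them removed.

## Problem sizes used in the tests

Algorithm–oracle comparisons use chromosomes of ≤500 SNPs (200 random
parameterizations) and 50 random pedigrees of ≤6 generations, where
exhaustive enumeration is cheap and exact. The stochastic sib-mating
recovery check uses 50 replicates of a 10-chromosome × 200 Mb (20 Morgan)
genome with 400,000 markers and clean founders — large enough that the
realized autozygous fraction concentrates near the pedigree expectation of
0.25 (per-replicate SD ≈ 0.05) — and requires the proband's pipeline F_ROH
to exceed both outbred controls' in ≥95% of replicates. The analysis
drivers use the default desk-scale genome above. With only 4–10
chromosomes, per-individual baseline autozygosity under a shared founder
pool has large variance (chromosome-scale blocks); single-replicate control
F_ROH values in the demo can therefore sit far from 1/K even though the
across-replicate mean is calibrated.

## Degenerate inputs and tie-breaks

Empty tables partition to zero counts and summarize to an all-zero summary;
a chromosome with no markers yields no segments; `dp_quantile` must lie
strictly inside (0,1) and an empty DP list is an error; window hit-fraction
comparisons use ≥ on exact float ratios, and the brute-force oracle applies
the identical comparison, so ties cannot diverge between the two routes.
Pedigree cycles are rejected at construction; an individual with one unknown
parent has inbreeding 0 and `expected_inbreeding` returns None with a
warning.
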