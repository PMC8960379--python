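# Methods

This note documents the models, parameters and numerical choices behind
`pegtrace`, and what the synthetic validation does and does not show.

## Coordinate and data conventions

All intervals are 0-based, half-open (BED-compatible). A read overlaps a
region when they share at least one base; a read abutting a region
boundary does not count. Reads are fixed-length single-end interval
surrogates carrying MAPQ, a duplicate signature (chrom, start, end,
strand) and the bases observed at covered strain SNPs; alignment itself
is out of scope and reads are born mapped.

## The synthetic experiment

The generator emulates a reciprocal-cross design between two inbred
strains whose genomes differ at known SNPs, across mouse
pre-implantation development (PN3/PN5 zygote, early/late two-cell,
four-cell, eight-cell, blastocyst ICM; major zygotic genome activation,
ZGA, at the two-cell stage).

**Genome.** Two chromosomes of 120 gene slots (12 kb each): TSS with
±0.8 kb jitter, a 1.5-kb promoter (−1 kb/+0.5 kb of TSS) containing a
0.6-kb CpG-island interval, and ERV-family repeats (ERVK, ERVL-MaLR,
ERV1) planted near half the TSSs plus background repeats. Promoters
never overlap by construction.

**SNP map.** Poisson-scattered strain SNPs at 8/kb — PWK/PhJ and
C57BL/6 differ at roughly one site per 130–150 bp, so this is the
realistic density — with paternal ≠ maternal base at every site.

**Planted truth.** 10% of genes are PEGs (log₂ paternal/maternal effect
5); 60% of PEGs are transient, losing imprinting at the eight-cell or
ICM stage (always strictly after the ZGA window). Transient PEGs always
retain sperm H3K4me3 (12 of 13 newly described transient PEGs did in the
motivating data); stable PEGs retain it with probability 0.85. Non-PEG
promoters carry sperm/oocyte H3K4me3 at rates 0.5/0.6. Ten percent of
genes carry a maternal transcript deposit detectable before ZGA.

**ChIP reads.** Marked promoters receive Poisson(300) reads; the genome
receives background reads at 0.002/bp. In embryo stages each read's
hidden allele is Bernoulli: at paternally skewed loci (PEG, sperm-
retained, before the loss stage) the paternal odds are boosted 50-fold
over the stage's global paternal fraction (0.50–0.55 by stage, decaying
to parity by ICM — assignable early-embryo reads over-represent the
compacted paternal chromatin); elsewhere the global fraction applies.
Gamete/pronucleus compartments are single-parent by construction. Ten
percent of reads are PCR duplicates, 5% have MAPQ < 30, and each SNP
observation is flipped to the other parental base with probability 0.01.

**Allelic RNA counts.** Per biological sample (stage × cross ×
replicate), a gene's total count is Gamma–Poisson (negative binomial,
dispersion 0.1, mean 1000 scaled by a lognormal gene factor, σ = 0.5,
and a lognormal library factor, σ = 0.15); the paternal count is a
binomial split of that total at the gene's paternal share
(2^effect/(1+2^effect) while imprinted, ½ otherwise). Both allele
columns therefore come from one library: each is marginally NB with the
stated dispersion, while the allelic *ratio* carries only binomial
sampling noise — as in real data, where allelic counts partition one
library's reads. Library factors are shared by the two allele columns of
a sample for the same reason. Androgenotes (parthenogenotes) carry twice
the paternal (maternal) allele mean at the two-cell stage; amanitin-
treated embryos express only genes with a maternal deposit.

**Randomness.** One top-level seed; every routine draws from a substream
keyed by stable string/integer tags (CRC-32 of the tag into a
`SeedSequence` spawn key), so outputs are byte-identical per seed and
independent of call order.

## Allele assignment

Reads with MAPQ < 30 (strict) are removed; duplicate removal keeps the
first read per signature by (start, end, strand, read id) order and
preserves input order, making filtering idempotent. A read is paternal
iff ≥1 covered SNP shows the paternal base and none shows the maternal
base (maternal symmetric); both → conflicting; neither → unassignable.
Conflicting reads are grouped with unassignable reads and excluded from
allelic counts — only unambiguous allele-specific reads are counted.
Observations at positions absent from the SNP map carry no information
(logged, not an error). For peak calling, deduplication is applied to
the merged read set; for allelic counting it is applied to each allelic
read set after splitting.

## Broad peak calling

A deliberately simplified significance screen in the spirit of MACS2's
broad mode, not a reimplementation: coverage is binned at 10 bp (RPKM =
raw/((bin/1000)·(total/10⁶))); non-overlapping 200-bp windows are tested
with a one-sided Poisson upper tail against λ = max(genome-wide rate,
scaled local control rate), or the genome-wide rate alone without a
control (the `--nolambda` analogue); BH q-values replace MACS2's q-value
machinery; windows with q ≤ 0.05 (0.01 for the stricter ICM preset used
before promoter counting) are merged across gaps ≤ 1 kb. Window counts
use read *starts* so the tested quantity is Poisson under a homogeneous
background; the overlap-based bin track is kept for coverage output.
Tiled (rather than sliding) windows keep the window p-values independent,
so BH behaves as intended under the null. Genes are associated with a
peak by promoter overlap or a TSS within 2 kb (the association window of
the annotation step is not pinned by the motivating analysis and is
configurable); annotation is many-to-many. Replicates are pooled by
summing counts after computing Pearson r over nonzero-union bins;
r ≤ 0.96 (or undefined r) flags but does not block pooling. The
consensus rule keeps genes supported by at least two datasets.

## Allelic ChIP statistics

Counting regions intersect the ICM broad peaks (q ≤ 0.01) with promoter
intervals, falling back to the promoter when no peak overlaps. Genes
need ≥3 informative SNPs in the region ("traceable") and ≥10 allelic
reads per stage to be tested. The chi-square screen is the 1-df
goodness-of-fit against the stage-expected split with no continuity
correction (this keeps the hand-checked statistic for (90, 10) vs 0.5
exactly 64.0, and matches the default of common implementations); no
multiplicity correction is applied across genes in this screen,
mirroring the per-gene reporting of the motivating analysis — a
faithful but statistically permissive choice. The Cochran–Armitage
statistic uses equally spaced integer scores over the configured stage
order; stages with zero allelic reads are dropped with a warning and
the remaining stages re-scored. Degenerate inputs (p̄ ∈ {0,1}) return
statistic 0, p 1.

## Allelic differential expression

Library factors are 30%-trimmed-mean scaled (geometric mean 1) — a
robust simplification of TMM that is stable at two replicates.
Dispersion is method-of-moments per gene on normalized counts within
replicated conditions, clamped at 0, shrunk halfway toward the
20%-trimmed-mean common value; with no replicated condition a fallback
common dispersion (0.1) is returned with a warning, since a variance
cannot be estimated from one replicate. The exact test conditions on
each gene's total pseudo-count: group sums are NB with size n_g/φ under
the null, and the two-sided p sums conditional probabilities of outcomes
no more likely than the observed split (at φ < 10⁻⁸ the conditional law
is binomial, computed in the same code path). log₂FC uses normalized
group means with a 0.5 pseudo-count per mean so zero-count alleles give
finite fold changes. Genes with total pseudo-count < 10 are flagged
low-expression, get p = 1 and are excluded from the BH correction.
Reciprocal crosses enter as a sign-agreement requirement on per-cross
log₂FCs rather than a multivariate fit: a gene whose apparent allelic
effect flips sign between crosses is a strain effect, not imprinting,
and is disqualified. Swapping cross labels leaves results unchanged;
swapping parent labels negates every log₂FC exactly.

## Integration and transient classification

A gene has parent-of-origin zygote chromatin when a paternal-pronucleus
peak overlaps its promoter region and neither the maternal pronucleus
nor the oocyte has one. Per-stage expression labels are *paternal* when
the per-stage DE call passes (log₂FC > 1, FDR < 0.05), *biallelic* when
it fails and the pooled allelic ratio sits within 50±15% (the band makes
the label robust to low counts; both thresholds configurable). A
confirmed PEG with ≥3 assayed stages is *transient* when paternal at ≥1
ZGA stage and biallelic later; the expression loss stage is the first
biallelic stage after the last paternal one. The chromatin loss stage is
the first stage at which a previously paternal H3K4me3 direction is no
longer paternal — a reprogrammed biallelic locus can drift to "none" or
even a nominally significant maternal deviation, and both are loss of
paternal enrichment. Loss-stage *coincidence* is reported (never
asserted as causal) when the two loss stages are within one stage of
each other on the shared developmental axis; adjacent-stage slack
absorbs the screen's per-stage type-I error without changing the
qualitative statement, and the coincidence fraction is computed over
recovered transient genes that are chip-assessable (sperm-retained with
traceable SNPs), since a gene with no paternal chromatin signal has no
loss stage to compare.

## Problem sizes and what the validation shows

The default configuration (240 genes, 24 PEGs, 14 transient; ~70k ChIP
reads per stage; 2 replicates × 2 crosses of RNA) is sized so the full
pipeline and its validation battery run in minutes on one CPU while
keeping every per-gene decision well-powered; calibration experiments
use 5,000 genes and the operating-characteristics experiment 2,000 genes
× 20 seeds. Passing tests show that the *decision logic* — assignment,
screening, staged calling, classification — recovers planted truth under
the stated noise model. They do not show robustness to features the
generator omits: mapping bias toward the reference haplotype, SNP-poor
or copy-number-variable regions, fragment-length structure and
GC/chromatin coverage waves, isoform-level effects (an isoform-dependent
imprinted gene cannot be resolved by gene-level counts), or
between-replicate batch structure beyond library size. Real-data use
should treat the chi-square screen's lack of multiplicity correction and
the fixed biallelic band as reviewable choices, not facts.

## Known limitations

* The peak caller is a screen; it does not model fragment size, local
  lambda scales, or paired-end information.
* The exact NB test assumes independent groups; allelic counts from one
  library are positively correlated, making the test mildly conservative
  (the direction that preserves FDR control).
* The trend test uses the asymptotic normal reference; for very small
  per-stage counts a permutation p (validated here against the
  asymptotic one) would be preferable.
* Transient classification requires the trajectory dataset to include
  post-ZGA stages; with fewer than three assayed stages genes are
  reported inconclusive rather than forced into a class.
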