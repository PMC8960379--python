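# pegtrace

Allele-specific analysis of active chromatin and imprinted expression in
mouse pre-implantation embryos, built around a synthetic ground-truth
generator so that every stage of the pipeline can be validated end to end.

## The problem

Paternally expressed genes (PEGs) are transcribed from the paternal allele
while the maternal allele is silenced by DNA methylation or repressive
histone marks. How the *expressed* allele acquires its active state is less
clear. One candidate mechanism is transmission of the active promoter mark
H3K4me3 through sperm: although ~99% of mouse sperm histones are replaced by
protamines, a minority of nucleosomes — including those at many imprinted
loci — are retained. Testing this requires tracking the paternal allele
specifically, which is possible in reciprocal crosses of two inbred strains
(e.g. PWK/PhJ × C57BL/6): strain SNPs let each sequencing read be assigned
to its parental haplotype.

`pegtrace` implements the full analysis chain for this design, aimed at
epigenomics analysts working with allele-resolved ChIP-seq and RNA-seq:

1. **synthetic data** — a two-haplotype genome, strain SNP map, allele-tagged
   ChIP reads per developmental stage and negative-binomial allelic RNA
   counts, all with planted ground truth (`genome`, `reads`, `counts`);
2. **allele assignment** — MAPQ/duplicate filtering and SNPsplit-style
   paternal/maternal read classification (`allele`);
3. **broad peak calling** — binned RPKM coverage, a Poisson-window broad
   domain screen with BH q-values, peak→gene annotation, replicate pooling
   and the multi-dataset consensus rule (`peaks`);
4. **allelic ChIP statistics** — paternal allelic ratios over promoter
   counting regions, per-stage expected ratios, the chi-square enrichment
   screen and the Cochran–Armitage trend test (`chipstats`);
5. **allelic differential expression** — exact negative-binomial tests with
   staged PEG calling: reciprocal-cross candidates → independent-dataset
   confirmation → androgenote/parthenogenote validation with an amanitin
   (transcription-blocked) carryover control (`de`);
6. **integration** — zygote parent-of-origin chromatin status, PEG × sperm
   H3K4me3 intersection, transient-PEG classification with loss stages, and
   ERV-repeat proximity annotation (`integrate`, `pipeline`).

## The statistics

With `n_p` paternal and `n_m` maternal deduplicated reads over a promoter
region, the **paternal allelic ratio** is

    ratio (%) = n_p / (n_p + n_m) × 100.

Each stage's genome-wide imbalance `p0 = Σ n_p / Σ (n_p + n_m)` (the
"global gene average") is the expected ratio; per-gene enrichment is a 1-df
chi-square goodness-of-fit of `(n_p, n_m)` against `(p0, 1−p0)·n` without
continuity correction, with direction *paternal* when the observed fraction
exceeds `p0` at p < 0.05. **Loss of paternal enrichment** across ordered
stages is tested with the two-sided Cochran–Armitage trend statistic with
equally spaced integer scores,

    z = Σᵢ sᵢ(xᵢ − nᵢ·p̄) / √( p̄(1−p̄)·[Σ nᵢsᵢ² − (Σ nᵢsᵢ)²/N] ),

which reduces to the pooled two-proportion z-test for two stages.

Allelic expression contrasts use an **exact negative-binomial test** on
library-size-equalized pseudo-counts, conditioning on each gene's total
(the exact-test construction used by edgeR); at dispersion 0 it reduces to
an exact binomial test. The staged decision rules are: candidate when
log₂FC > 3 and BH-FDR < 0.001 with both cross directions agreeing in sign;
confirmed when the same thresholds pass in an independent dataset;
validated when androgenote-vs-parthenogenote log₂FC > 1 at FDR < 0.1, with
amanitin-treated embryos flagging maternal transcript carryover.

## Worked example

The numbered drivers under `analysis/` run each stage on the default
synthetic conditions (240 genes, 24 planted PEGs of which 14 transient).
The end-to-end run:

```
$ python analysis/06_integrate.py
genes: 240; planted PEGs: 24 (14 transient)
confirmed PEGs: 24 (true positives 24)
confirmed PEGs with sperm H3K4me3 consensus: 23/24 (96%)
transient PEGs recovered with correct loss stage: 100%
loss-stage coincidence among recovered transient genes: 100%
global gene average (% paternal) per stage: {'PN5': 59.6, 'early2c': 59.4,
'late2c': 57.2, '4c': 54.8, '8c': 53.6, 'ICM': 51.8}
```

Reading this: all 24 planted PEGs survive the candidate → confirmation →
validation chain with no false positives; 23 of 24 are in the sperm
H3K4me3 consensus set (one planted PEG was simulated without sperm
retention); every transient PEG is classified transient with the correct
loss stage; and for every recovered transient gene the stage at which
paternal H3K4me3 enrichment disappears coincides (within one stage) with
the stage at which expression becomes biallelic. The global gene average
declines from ~60% to ~52% paternal as the early paternal skew decays —
the per-gene chi-square screen tests against exactly this background.

The same pipeline is available as a CLI:

```bash
pegtrace run-all --seed 1 --out results/pipeline
pegtrace assign --reads reads_ICM.bed --snps snps.tsv --out-prefix icm
```

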