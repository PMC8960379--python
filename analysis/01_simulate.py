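#!/usr/bin/env python
"""Simulate the study's data: a two-haplotype genome with a strain SNP
map, planted PEG/transient-PEG truth, allele-tagged H3K4me3 ChIP reads
per developmental stage, and reciprocal-cross allelic RNA counts.

Writes the full synthetic bundle under results/simulated/.
"""

from pathlib import Path

from pegtrace import io
from pegtrace.config import CHIP_STAGES, CROSSES, ZGA_STAGES, SimConfig
from pegtrace.counts import simulate_allelic_counts, simulate_group_counts
from pegtrace.genome import make_genome, make_snp_map, make_truth
from pegtrace.reads import simulate_chip_reads

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed)
    genome = make_genome(config)
    snps = make_snp_map(genome, config.snp_density, config.seed)
    truth = make_truth(genome, config)

    io.write_genome(genome, OUT / "genome")
    io.write_snps(snps, OUT / "snps.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t")

    n_reads = {}
    for stage in CHIP_STAGES:
        reads = simulate_chip_reads(genome, snps, truth, stage, config)
        io.write_reads_bed(reads, OUT / f"reads_{stage}.bed", OUT / f"reads_{stage}.truth.tsv")
        n_reads[stage] = len(reads)

    rna = simulate_allelic_counts(
        genome, truth,
        {"stages": list(ZGA_STAGES), "crosses": list(CROSSES), "replicates": config.n_replicates},
        config, dataset=1,
    )
    io.write_count_matrix(rna, OUT / "rna_reciprocal_zga")
    groups = simulate_group_counts(
        genome, truth, ("androgenote", "parthenogenote", "amanitin"), config
    )
    io.write_count_matrix(groups, OUT / "rna_uniparental")

    print(f"genome: {len(genome.genes)} genes on {len(genome.chromosomes)} chromosomes "
          f"({genome.size / 1e6:.2f} Mb), {len(snps)} strain SNPs")
    print(f"planted: {int(truth.is_peg.sum())} PEGs "
          f"({int(truth.transient.sum())} transient), "
          f"{int(truth.sperm_h3k4me3.sum())} promoters marked in sperm")
    for stage, n in n_reads.items():
        print(f"  {stage}: {n} ChIP reads")
    print(f"RNA: {rna.counts.shape[1]} allelic samples at ZGA stages; "
          f"{groups.counts.shape[1]} uniparental/amanitin samples")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main()
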