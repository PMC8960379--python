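"""Allele-tagged ChIP read simulation.

Reads are fixed-length single-end interval surrogates: an interval plus
MAPQ, a duplicate signature (chrom, start, end, strand), the bases
observed at covered strain SNPs, and a hidden true allele of origin
used only for validation.  Alignment itself is out of scope; reads are
born mapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CHIP_STAGES, GAMETE_COMPARTMENTS, SimConfig
from .genome import GenomeModel, SnpMap, chip_skew_level
from .rng import substream

PATERNAL = "paternal"
MATERNAL = "maternal"


@dataclass
class ReadRecord:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    snp_obs: tuple[tuple[int, str], ...] = ()
    true_allele: str | None = None

    @property
    def signature(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def __post_init__(self) -> None:
        for pos, _ in self.snp_obs:
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"read {self.read_id}: SNP observation at {pos} outside [{self.start}, {self.end})"
                )


def skewed_fraction(p0: float, fold: float) -> float:
    """Paternal read fraction at a fully enriched promoter: the paternal
    allele's contribution is boosted ``fold``-fold over the stage's
    background paternal fraction ``p0`` (odds scaling)."""
    return fold * p0 / (fold * p0 + (1.0 - p0))


def simulate_chip_reads(
    genome: GenomeModel,
    snp_map: SnpMap,
    truth,
    stage: str,
    config: SimConfig,
    replicate: int = 0,
) -> list[ReadRecord]:
    """Simulate one ChIP library for a stage or gamete compartment.

    Marked promoters receive ~``chip_promoter_depth`` reads; the rest of
    the genome receives background reads at ``chip_background_rate`` per
    bp.  Per-read allele of origin follows the planted truth (fully
    paternal/maternal in gamete compartments, skewed at imprinted loci in
    embryo stages, the stage's global paternal fraction elsewhere).
    A ``dup_fraction`` of reads are PCR duplicates and a
    ``lowmapq_fraction`` have MAPQ < 30.
    """
    if stage not in CHIP_STAGES and stage not in GAMETE_COMPARTMENTS:
        raise ValueError(f"unknown stage {stage!r}")
    rng = substream(config.seed, "chip", stage, replicate)
    rl = config.read_length
    reads: list[ReadRecord] = []
    counter = 0

    if stage in GAMETE_COMPARTMENTS:
        forced_allele = PATERNAL if stage in ("sperm", "PN3_paternal") else MATERNAL
        mark_col = "sperm_h3k4me3" if forced_allele == PATERNAL else "oocyte_h3k4me3"
        p0 = 1.0 if forced_allele == PATERNAL else 0.0
    else:
        forced_allele = None
        mark_col = None
        p0 = float(config.global_paternal_fraction[stage])

    def emit(chrom: str, start: int, p_pat: float) -> None:
        nonlocal counter
        if forced_allele is not None:
            allele = forced_allele
        else:
            allele = PATERNAL if rng.random() < p_pat else MATERNAL
        strand = "+" if rng.random() < 0.5 else "-"
        mapq = int(rng.integers(0, 30)) if rng.random() < config.lowmapq_fraction else 60
        obs = []
        for pos in snp_map.in_interval(chrom, start, start + rl):
            pat_b, mat_b = snp_map.lookup(chrom, int(pos))
            true_b, other_b = (pat_b, mat_b) if allele == PATERNAL else (mat_b, pat_b)
            base = other_b if rng.random() < config.obs_noise else true_b
            obs.append((int(pos), base))
        reads.append(
            ReadRecord(
                read_id=f"{stage}.{replicate}.{counter}",
                chrom=chrom,
                start=start,
                end=start + rl,
                strand=strand,
                mapq=mapq,
                snp_obs=tuple(obs),
                true_allele=allele,
            )
        )
        counter += 1

    # promoter reads at marked genes
    for gene in genome.genes:
        row = truth.loc[gene.gene_id]
        if forced_allele is not None:
            marked = bool(row[mark_col])
            p_pat = p0
        else:
            marked = bool(row["sperm_h3k4me3"] or row["oocyte_h3k4me3"])
            level = chip_skew_level(row, stage)
            p_pat = skewed_fraction(p0, config.enrichment_fold) if level > 0 else p0
        if not marked:
            continue
        n = rng.poisson(config.chip_promoter_depth)
        lo, hi = gene.promoter_start, gene.promoter_end - rl
        if hi <= lo:
            continue
        for start in rng.integers(lo, hi, size=n):
            emit(gene.chrom, int(start), p_pat)

    # genome-wide background
    for chrom, length in genome.chromosomes:
        n_bg = rng.poisson(config.chip_background_rate * length)
        for start in rng.integers(0, max(1, length - rl), size=n_bg):
            emit(chrom, int(start), p0)

    # PCR duplicates: re-emit copies of randomly chosen reads
    if reads and config.dup_fraction > 0:
        n_dup = rng.binomial(len(reads), config.dup_fraction)
        for idx in rng.integers(0, len(reads), size=n_dup):
            src = reads[idx]
            reads.append(
                ReadRecord(
                    read_id=f"{stage}.{replicate}.dup{counter}",
                    chrom=src.chrom,
                    start=src.start,
                    end=src.end,
                    strand=src.strand,
                    mapq=src.mapq,
                    snp_obs=src.snp_obs,
                    true_allele=src.true_allele,
                )
            )
            counter += 1
    return reads
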