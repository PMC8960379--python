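"""Simulation configuration and stage vocabulary.

Stages follow mouse pre-implantation development: sperm and oocyte
(gametes), the PN3 zygote split into paternal/maternal pronuclei,
PN5 zygote, early/late two-cell, four-cell, eight-cell, and the inner
cell mass (ICM) of the blastocyst.  Major zygotic genome activation
(ZGA) spans the two- to four-cell stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


#: Embryo stages at which allele-split ChIP reads are simulated/analyzed,
#: in developmental order (trend-test scores follow this order).
CHIP_STAGES: tuple[str, ...] = ("PN5", "early2c", "late2c", "4c", "8c", "ICM")

#: Gamete / pronuclear compartments: reads are single-parent by construction.
GAMETE_COMPARTMENTS: tuple[str, ...] = ("sperm", "oocyte", "PN3_paternal", "PN3_maternal")

#: Stages with RNA-seq in the simulated design.
EXPR_STAGES: tuple[str, ...] = ("early2c", "late2c", "4c", "8c", "ICM")

#: Stages of major zygotic genome activation (candidate-calling window).
ZGA_STAGES: tuple[str, ...] = ("early2c", "late2c", "4c")

#: Reciprocal cross labels (father listed first).
CROSSES: tuple[str, ...] = ("PWKxB6", "B6xPWK")

ERV_FAMILIES: tuple[str, ...] = ("ERVK", "ERVL-MaLR", "ERV1")


def _default_global_paternal_fraction() -> dict[str, float]:
    # Mild genome-wide paternal skew early (protamine-exchange chromatin is
    # over-represented among assignable reads), decaying to parity by ICM.
    return {"PN5": 0.55, "early2c": 0.55, "late2c": 0.52, "4c": 0.50, "8c": 0.50, "ICM": 0.50}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-haplotype experiment.

    Defaults describe the desk-scale study conditions: a two-chromosome
    genome with 120 genes per chromosome, strain SNPs at 8/kb (the
    PWK/PhJ vs C57BL/6 density is roughly one SNP per 130-150 bp),
    promoter-scale ChIP enrichment, and negative-binomial allelic RNA
    counts with two replicates per reciprocal cross.
    """

    seed: int = 0

    # genome
    n_chromosomes: int = 2
    genes_per_chromosome: int = 120
    gene_spacing: int = 12_000  # bp between gene slots
    snp_density: float = 0.008  # per bp (8 per kb)

    # ChIP read model
    read_length: int = 100
    chip_promoter_depth: float = 300.0  # expected reads per marked promoter
    chip_background_rate: float = 2e-3  # expected reads per bp outside peaks
    enrichment_fold: float = 50.0  # paternal:maternal odds fold at fully enriched promoters
    dup_fraction: float = 0.10
    lowmapq_fraction: float = 0.05
    obs_noise: float = 0.01  # per-SNP probability of observing the wrong parental base
    global_paternal_fraction: Mapping[str, float] = field(default_factory=_default_global_paternal_fraction)

    # RNA count model
    rna_mean_expression: float = 1000.0  # mean total counts per gene per biological sample
    rna_lognorm_sigma: float = 0.5
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.15
    n_replicates: int = 2

    # planted truth
    peg_fraction: float = 0.10
    transient_fraction: float = 0.60  # of PEGs
    effect_log2: float = 5.0
    sperm_retained_frac_peg: float = 0.85  # stable PEGs; transient PEGs are always retained
    sperm_h3k4me3_frac_nonpeg: float = 0.50
    oocyte_h3k4me3_frac_nonpeg: float = 0.60
    expressed_pre_zga_frac: float = 0.10
    erv_near_tss_frac: float = 0.50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.genes_per_chromosome <= 0:
            raise ConfigurationError("chromosome and gene counts must be positive")
        if self.gene_spacing <= 3000:
            raise ConfigurationError("gene_spacing too small for non-overlapping promoters")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        if self.chip_promoter_depth < 0 or self.chip_background_rate < 0:
            raise ConfigurationError("read depths must be nonnegative")
        for name in ("dup_fraction", "lowmapq_fraction", "obs_noise", "peg_fraction",
                     "transient_fraction", "sperm_retained_frac_peg",
                     "sperm_h3k4me3_frac_nonpeg", "oocyte_h3k4me3_frac_nonpeg",
                     "expressed_pre_zga_frac", "erv_near_tss_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for stage, p in self.global_paternal_fraction.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"global paternal fraction for {stage} must be in (0, 1)")
        if self.rna_mean_expression <= 0 or self.n_replicates < 1:
            raise ConfigurationError("rna_mean_expression and n_replicates must be positive")
        if self.nb_dispersion < 0 or self.libsize_sigma < 0:
            raise ConfigurationError("nb_dispersion and libsize_sigma must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["global_paternal_fraction"] = dict(self.global_paternal_fraction)
        return d
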