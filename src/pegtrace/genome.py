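"""Two-haplotype genome model, strain SNP map, and planted ground truth.

Coordinates are 0-based, half-open (BED convention) throughout the
package.  The genome is a set of gene "slots" along each chromosome;
each gene carries a TSS, a transcript interval, a promoter interval
(1 kb upstream to 500 bp downstream of the TSS) and a promoter CpG
island.  Repeats are labeled intervals used for ERV-proximity reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHIP_STAGES, ERV_FAMILIES, ConfigurationError, SimConfig, ZGA_STAGES
from .rng import substream

_BASES = np.array(list("ACGT"))

PROMOTER_UP = 1000  # bp upstream of TSS
PROMOTER_DOWN = 500  # bp downstream
CGI_HALFWIDTH = 300


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int  # transcript interval
    end: int
    promoter_start: int
    promoter_end: int
    cgi_start: int | None = None
    cgi_end: int | None = None


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    repeats: pd.DataFrame  # columns: chrom, start, end, family

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index[gene_id]

    @property
    def _gene_index(self) -> dict[str, GeneModel]:
        idx = getattr(self, "_gene_index_cache", None)
        if idx is None:
            idx = {g.gene_id: g for g in self.genes}
            object.__setattr__(self, "_gene_index_cache", idx)
        return idx


class SnpMap:
    """Biallelic strain-distinguishing variants keyed by (chrom, position).

    Every entry carries the paternal-strain and maternal-strain base;
    the two differ at every site by construction.
    """

    def __init__(self, table: pd.DataFrame):
        expected = ["chrom", "pos", "pat_base", "mat_base"]
        if list(table.columns[:4]) != expected:
            raise ValueError(f"SNP table must have columns {expected}")
        if (table["pat_base"] == table["mat_base"]).any():
            raise ValueError("paternal and maternal bases must differ at every SNP")
        dup = table.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate SNP positions")
        self.table = table.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self._by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
        self._positions: dict[str, np.ndarray] = {}
        for chrom, sub in self.table.groupby("chrom", sort=False):
            self._by_chrom[chrom] = dict(
                zip(sub["pos"].astype(int), zip(sub["pat_base"], sub["mat_base"]))
            )
            self._positions[chrom] = sub["pos"].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, chrom: str, pos: int) -> tuple[str, str] | None:
        return self._by_chrom.get(chrom, {}).get(pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]


def make_genome(config: SimConfig) -> GenomeModel:
    """Build a deterministic gene/repeat layout from the configuration."""
    config.validate()
    rng = substream(config.seed, "genome")
    chroms: list[tuple[str, int]] = []
    genes: list[GeneModel] = []
    repeats: list[dict] = []
    spacing = config.gene_spacing
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        length = config.genes_per_chromosome * spacing + 10_000
        chroms.append((name, length))
        for gi in range(config.genes_per_chromosome):
            slot = gi * spacing + 2000
            tss = int(slot + spacing // 2 + rng.integers(-800, 801))
            strand = "+" if rng.random() < 0.5 else "-"
            tx_len = int(rng.integers(2000, spacing - 4000))
            gene_id = f"g{ci + 1:02d}{gi + 1:04d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=name,
                    strand=strand,
                    tss=tss,
                    start=tss,
                    end=tss + tx_len,
                    promoter_start=tss - PROMOTER_UP,
                    promoter_end=tss + PROMOTER_DOWN,
                    cgi_start=tss - CGI_HALFWIDTH,
                    cgi_end=tss + CGI_HALFWIDTH,
                )
            )
            # ERV-family repeat near some TSSs (within the 2.5-kb report window)
            if rng.random() < config.erv_near_tss_frac:
                dist = int(rng.integers(600, 2300))
                rep_start = tss + dist
                repeats.append(
                    {
                        "chrom": name,
                        "start": rep_start,
                        "end": rep_start + 400,
                        "family": str(rng.choice(ERV_FAMILIES)),
                    }
                )
        # distant background repeats
        for _ in range(20):
            s = int(rng.integers(0, length - 500))
            repeats.append(
                {"chrom": name, "start": s, "end": s + 400, "family": str(rng.choice(ERV_FAMILIES))}
            )
    rep_df = pd.DataFrame(repeats, columns=["chrom", "start", "end", "family"])
    genome = GenomeModel(chromosomes=chroms, genes=genes, repeats=rep_df)
    _check_genome(genome)
    return genome


def _check_genome(genome: GenomeModel) -> None:
    sizes = genome.chrom_sizes
    for g in genome.genes:
        L = sizes[g.chrom]
        if not (0 <= g.promoter_start < g.promoter_end <= L and 0 <= g.start < g.end <= L):
            raise ConfigurationError(f"gene {g.gene_id} outside chromosome bounds")
        if not (g.promoter_start <= g.tss <= g.promoter_end):
            raise ConfigurationError(f"gene {g.gene_id}: promoter must contain its TSS")


def make_snp_map(genome: GenomeModel, density: float, seed: int) -> SnpMap:
    """Scatter strain SNPs at ``density`` per bp (Poisson along each chromosome)."""
    if density <= 0:
        raise ConfigurationError("SNP density must be positive")
    rng = substream(seed, "snps")
    rows = []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(density * length)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        pat_idx = rng.integers(0, 4, size=pos.size)
        # maternal base drawn from the three alternatives -> always different
        mat_idx = (pat_idx + rng.integers(1, 4, size=pos.size)) % 4
        for p, a, b in zip(pos, _BASES[pat_idx], _BASES[mat_idx]):
            rows.append((chrom, int(p), a, b))
    return SnpMap(pd.DataFrame(rows, columns=["chrom", "pos", "pat_base", "mat_base"]))


def make_truth(genome: GenomeModel, config: SimConfig) -> pd.DataFrame:
    """Plant the ground truth: which genes are PEGs, which are transient
    (and at what stage they lose imprinting), which promoters carry
    H3K4me3 in sperm/oocyte, and which genes have maternal transcript
    deposits detectable before zygotic genome activation.

    Returns a DataFrame indexed by gene id with columns:
    is_peg, transient, effect (log2 paternal/maternal), loss_stage
    ('' for stable), sperm_h3k4me3, oocyte_h3k4me3, expressed_pre_zga.
    """
    rng = substream(config.seed, "truth")
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)
    n_peg = int(round(config.peg_fraction * n))
    peg_idx = rng.choice(n, size=n_peg, replace=False)
    is_peg = np.zeros(n, dtype=bool)
    is_peg[peg_idx] = True
    n_transient = int(round(config.transient_fraction * n_peg))
    transient_idx = rng.choice(peg_idx, size=n_transient, replace=False)
    transient = np.zeros(n, dtype=bool)
    transient[transient_idx] = True

    # loss stages strictly after the ZGA window (spec invariant: after the first stage)
    post_zga = [s for s in CHIP_STAGES if s not in ZGA_STAGES and s != "PN5"]
    loss_stage = np.array([""] * n, dtype=object)
    loss_stage[transient_idx] = rng.choice(post_zga, size=n_transient)

    effect = np.where(is_peg, config.effect_log2, 0.0)

    sperm = np.zeros(n, dtype=bool)
    oocyte = np.zeros(n, dtype=bool)
    u = rng.random(n)
    v = rng.random(n)
    for i in range(n):
        if is_peg[i]:
            sperm[i] = True if transient[i] else (u[i] < config.sperm_retained_frac_peg)
            oocyte[i] = False
        else:
            sperm[i] = u[i] < config.sperm_h3k4me3_frac_nonpeg
            oocyte[i] = v[i] < config.oocyte_h3k4me3_frac_nonpeg
    pre_zga = rng.random(n) < config.expressed_pre_zga_frac

    truth = pd.DataFrame(
        {
            "is_peg": is_peg,
            "transient": transient,
            "effect": effect,
            "loss_stage": loss_stage,
            "sperm_h3k4me3": sperm,
            "oocyte_h3k4me3": oocyte,
            "expressed_pre_zga": pre_zga,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def imprinted_at(truth_row: pd.Series, stage: str, stage_order=CHIP_STAGES) -> bool:
    """True if the gene shows paternal-specific activity at ``stage``.

    Stable PEGs are imprinted at every stage; transient PEGs lose
    imprinting at (and after) their planted loss stage.
    """
    if not truth_row["is_peg"]:
        return False
    if not truth_row["transient"]:
        return True
    loss = truth_row["loss_stage"]
    order = list(stage_order)
    if stage not in order or loss not in order:
        return True
    return order.index(stage) < order.index(loss)


def chip_skew_level(truth_row: pd.Series, stage: str) -> float:
    """Paternal H3K4me3 skew level (0 or 1) at an embryo stage.

    A gene is paternally skewed when it is a PEG whose sperm H3K4me3 was
    retained and its locus has not yet been reprogrammed (pre loss stage).
    """
    if not truth_row["sperm_h3k4me3"]:
        return 0.0
    return 1.0 if imprinted_at(truth_row, stage) else 0.0
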