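"""Plain-text interchange: GFF-like gene tables, chrom.sizes, VCF-like SNP
tables, BED6+ read tables (hidden truth in a sidecar), broadPeak-style
peak files, bedGraph coverage, and counts/metadata TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import AllelicCountMatrix
from .genome import GeneModel, GenomeModel, SnpMap
from .peaks import BinnedCoverage, Peak
from .reads import ReadRecord


def _p(prefix, suffix: str) -> Path:
    return Path(str(prefix) + suffix)


# ------------------------------------------------------------------ genome

def write_genome(genome: GenomeModel, prefix: Path) -> None:
    prefix = Path(prefix)
    with open(_p(prefix, ".chrom.sizes"), "w") as fh:
        for chrom, length in genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand, "tss": g.tss,
            "start": g.start, "end": g.end,
            "promoter_start": g.promoter_start, "promoter_end": g.promoter_end,
            "cgi_start": g.cgi_start, "cgi_end": g.cgi_end,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows).to_csv(_p(prefix, ".genes.tsv"), sep="\t", index=False)
    genome.repeats.to_csv(_p(prefix, ".repeats.tsv"), sep="\t", index=False)


def read_genome(prefix: Path) -> GenomeModel:
    prefix = Path(prefix)
    chroms = []
    with open(_p(prefix, ".chrom.sizes")) as fh:
        for line in fh:
            chrom, length = line.split()
            chroms.append((chrom, int(length)))
    genes_df = pd.read_csv(_p(prefix, ".genes.tsv"), sep="\t")
    genes = [
        GeneModel(
            gene_id=r.gene_id, chrom=r.chrom, strand=r.strand, tss=int(r.tss),
            start=int(r.start), end=int(r.end),
            promoter_start=int(r.promoter_start), promoter_end=int(r.promoter_end),
            cgi_start=int(r.cgi_start) if pd.notna(r.cgi_start) else None,
            cgi_end=int(r.cgi_end) if pd.notna(r.cgi_end) else None,
        )
        for r in genes_df.itertuples()
    ]
    repeats = pd.read_csv(_p(prefix, ".repeats.tsv"), sep="\t")
    return GenomeModel(chromosomes=chroms, genes=genes, repeats=repeats)


# ------------------------------------------------------------------ SNPs

def write_snps(snps: SnpMap, path: Path) -> None:
    df = snps.table.rename(
        columns={"chrom": "CHROM", "pos": "POS", "pat_base": "PAT", "mat_base": "MAT"}
    )
    df.to_csv(path, sep="\t", index=False)


def read_snps(path: Path) -> SnpMap:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"CHROM": "chrom", "POS": "pos", "PAT": "pat_base", "MAT": "mat_base"})
    return SnpMap(df[["chrom", "pos", "pat_base", "mat_base"]])


# ------------------------------------------------------------------ reads

def write_reads_bed(reads, path: Path, truth_sidecar: Path | None = None) -> None:
    """BED6+ with MAPQ as score and SNP observations as 'pos:base;...'.
    The hidden true allele, when present, goes to a sidecar TSV."""
    with open(path, "w") as fh:
        for r in reads:
            obs = ";".join(f"{p}:{b}" for p, b in r.snp_obs) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.mapq}\t{r.strand}\t{obs}\n")
    if truth_sidecar is not None:
        with open(truth_sidecar, "w") as fh:
            fh.write("read_id\ttrue_allele\n")
            for r in reads:
                fh.write(f"{r.read_id}\t{r.true_allele or '.'}\n")


def read_reads_bed(path: Path, truth_sidecar: Path | None = None) -> list[ReadRecord]:
    truth = {}
    if truth_sidecar is not None:
        side = pd.read_csv(truth_sidecar, sep="\t")
        truth = dict(zip(side["read_id"], side["true_allele"]))
    reads = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, mapq, strand, obs = line.rstrip("\n").split("\t")[:7]
            snp_obs = ()
            if obs != ".":
                snp_obs = tuple(
                    (int(tok.split(":")[0]), tok.split(":")[1]) for tok in obs.split(";")
                )
            reads.append(
                ReadRecord(
                    read_id=name, chrom=chrom, start=int(start), end=int(end),
                    strand=strand, mapq=int(mapq), snp_obs=snp_obs,
                    true_allele=truth.get(name) if truth.get(name) != "." else None,
                )
            )
    return reads


# ------------------------------------------------------------------ peaks / coverage

def write_peaks(peaks, path: Path) -> None:
    """broadPeak-style BED6+3: name, score=int(10*fold), fold, -log10 p, -log10 q."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            mlog10p = -np.log10(max(p.pvalue, 1e-300))
            mlog10q = -np.log10(max(p.qvalue, 1e-300))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t{min(int(10 * p.fold), 1000)}\t.\t"
                f"{p.fold:.4f}\t{mlog10p:.4f}\t{mlog10q:.4f}\n"
            )


def read_peaks(path: Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    fold=float(f[6]), pvalue=10 ** -float(f[7]), qvalue=10 ** -float(f[8]),
                    n_windows=1,
                )
            )
    return peaks


def write_bedgraph(cov: BinnedCoverage, path: Path) -> None:
    """RPKM bedGraph (zero bins skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(cov.bins):
            rpkm = cov.rpkm(chrom)
            nz = np.flatnonzero(rpkm)
            for i in nz:
                s = i * cov.bin_width
                fh.write(f"{chrom}\t{s}\t{s + cov.bin_width}\t{rpkm[i]:.4f}\n")


# ------------------------------------------------------------------ counts

def write_count_matrix(matrix: AllelicCountMatrix, prefix: Path) -> None:
    prefix = Path(prefix)
    matrix.counts.to_csv(_p(prefix, ".counts.tsv"), sep="\t")
    matrix.samples.to_csv(_p(prefix, ".samples.tsv"), sep="\t")


def read_count_matrix(prefix: Path) -> AllelicCountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(_p(prefix, ".counts.tsv"), sep="\t", index_col=0)
    samples = pd.read_csv(_p(prefix, ".samples.tsv"), sep="\t", index_col=0)
    return AllelicCountMatrix(counts, samples)


# ------------------------------------------------------------------ misc

def write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
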