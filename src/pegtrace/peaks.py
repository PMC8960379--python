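"""Binned RPKM coverage, a broad-peak caller, peak-to-gene annotation,
replicate pooling and the multi-dataset consensus rule.

The caller is a MACS2-inspired significance screen, not a
reimplementation: fixed-width window counts are tested against a
one-sided Poisson upper tail with lambda = max(genome-wide rate, scaled
local control rate) — genome-wide only when no control is supplied (the
"--nolambda" analogue) — followed by Benjamini-Hochberg q-values and
merging of significant windows separated by at most ``merge_gap`` bp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeModel
from .reads import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class BinnedCoverage:
    """Per-chromosome raw read counts on a fixed bin grid (default 10 bp).

    ``bins`` counts every bin a read overlaps (the coverage track);
    ``starts`` counts each read once, in the bin holding its 5' start —
    the Poisson-distributed quantity the peak caller tests.  When
    ``starts`` is absent (coverage built from a track, not from reads)
    the caller falls back to ``bins``.
    """

    bins: dict[str, np.ndarray]  # chrom -> per-bin overlap counts
    bin_width: int
    total_reads: int
    starts: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def rpkm(self, chrom: str) -> np.ndarray:
        """RPKM = raw / ((bin_width/1000) * (total/1e6))."""
        denom = (self.bin_width / 1000.0) * (max(self.total_reads, 1) / 1e6)
        return self.bins[chrom] / denom

    def same_grid(self, other: "BinnedCoverage") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.bins) == set(other.bins)
            and all(self.bins[c].size == other.bins[c].size for c in self.bins)
        )


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    fold: float
    pvalue: float
    qvalue: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.qvalue < self.pvalue - 1e-12:
            raise ValueError("q-value cannot be below p-value")
        if self.end <= self.start:
            raise ValueError("peak interval must be nonempty")


@dataclass(frozen=True)
class GenePeakAnnotation:
    gene_id: str
    peak: Peak
    relation: str  # "promoter-overlap" | "nearest-within-window"
    distance: int


def bin_coverage(
    reads: Iterable[ReadRecord], genome: GenomeModel, bin_width: int = 10
) -> BinnedCoverage:
    """Count reads per genome bin; a read increments every bin it overlaps."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sizes = genome.chrom_sizes
    bins = {
        chrom: np.zeros((length + bin_width - 1) // bin_width, dtype=np.int64)
        for chrom, length in genome.chromosomes
    }
    starts = {chrom: np.zeros_like(arr) for chrom, arr in bins.items()}
    total = 0
    for r in reads:
        if r.chrom not in sizes or r.start < 0 or r.end > sizes[r.chrom] or r.end <= r.start:
            raise ValueError(f"read {r.read_id} falls outside the genome ({r.chrom}:{r.start}-{r.end})")
        b0 = r.start // bin_width
        b1 = (r.end - 1) // bin_width
        bins[r.chrom][b0 : b1 + 1] += 1
        starts[r.chrom][b0] += 1
        total += 1
    return BinnedCoverage(bins=bins, bin_width=bin_width, total_reads=total, starts=starts)


def _window_counts(cov: BinnedCoverage, window: int) -> list[tuple[str, int, int, int]]:
    """Tile each chromosome into non-overlapping ``window``-bp windows;
    return (chrom, start, end, count).  Counts come from read starts when
    available (each read counted once) so the window count is Poisson
    under a homogeneous background."""
    wpb = window // cov.bin_width
    source = cov.starts if cov.starts is not None else cov.bins
    out = []
    for chrom, arr in source.items():
        n_win = arr.size // wpb
        if n_win == 0:
            continue
        sums = arr[: n_win * wpb].reshape(n_win, wpb).sum(axis=1)
        for i, k in enumerate(sums):
            out.append((chrom, i * window, (i + 1) * window, int(k)))
    return out


def call_broad_peaks(
    treatment: BinnedCoverage,
    control: BinnedCoverage | None = None,
    q_cutoff: float = 0.05,
    window: int = 200,
    merge_gap: int = 1000,
) -> list[Peak]:
    """Call broad enrichment domains from binned coverage.

    Windows with BH q <= ``q_cutoff`` are merged when separated by at
    most ``merge_gap`` bp; each peak reports its minimum window p/q and
    the summed fold enrichment over background.
    """
    if window < treatment.bin_width:
        raise ValueError("window must be at least one bin wide")
    if control is not None and not treatment.same_grid(control):
        raise ValueError("control coverage is on a different bin grid")
    wins = _window_counts(treatment, window)
    if not wins:
        return []
    counts = np.array([w[3] for w in wins], dtype=float)
    genome_rate = counts.sum() / len(counts)
    if genome_rate == 0:
        return []
    lam = np.full(len(wins), genome_rate)
    if control is not None:
        ctrl = np.array([w[3] for w in _window_counts(control, window)], dtype=float)
        scale = max(treatment.total_reads, 1) / max(control.total_reads, 1)
        lam = np.maximum(genome_rate, ctrl * scale)
    pvals = stats.poisson.sf(counts - 1, lam)
    from .de import bh_fdr  # local import to avoid a module cycle

    qvals = bh_fdr(pvals)
    sig = qvals <= q_cutoff

    peaks: list[Peak] = []
    current: list[int] = []

    def flush(idx: list[int]) -> None:
        if not idx:
            return
        chrom = wins[idx[0]][0]
        start, end = wins[idx[0]][1], wins[idx[-1]][2]
        k = counts[idx].sum()
        l = lam[idx].sum()
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                fold=float(k / l) if l > 0 else float("inf"),
                pvalue=float(pvals[idx].min()),
                qvalue=float(qvals[idx].min()),
                n_windows=len(idx),
            )
        )

    for i, w in enumerate(wins):
        if not sig[i]:
            continue
        if current and (w[0] != wins[current[-1]][0] or w[1] - wins[current[-1]][2] > merge_gap):
            flush(current)
            current = []
        current.append(i)
    flush(current)
    return peaks


def window_poisson_pvalue(count: int, lam: float) -> float:
    """One-sided Poisson upper-tail p-value of a window count (P[X >= count])."""
    return float(stats.poisson.sf(count - 1, lam))


def annotate_peaks(
    peaks: Sequence[Peak], genome: GenomeModel, window: int = 2000
) -> list[GenePeakAnnotation]:
    """Associate peaks with genes: promoter overlap, else TSS within
    ``window`` bp of the peak.  Annotation is many-to-many; ties are
    ordered by distance then gene id."""
    if window < 0:
        raise ValueError("annotation window must be >= 0")
    out: list[GenePeakAnnotation] = []
    for pk in peaks:
        hits = []
        for g in genome.genes:
            if g.chrom != pk.chrom:
                continue
            if pk.start < g.promoter_end and pk.end > g.promoter_start:
                hits.append((0, g.gene_id, "promoter-overlap"))
            else:
                dist = max(pk.start - g.tss, g.tss - (pk.end - 1), 0)
                if dist <= window:
                    hits.append((dist, g.gene_id, "nearest-within-window"))
        for dist, gid, rel in sorted(hits):
            out.append(GenePeakAnnotation(gene_id=gid, peak=pk, relation=rel, distance=dist))
    return out


def consensus_gene_sets(per_dataset_gene_sets: Sequence[set], min_datasets: int = 2) -> set:
    """Genes present in at least ``min_datasets`` of the input sets
    ("common to more than one dataset" consensus rule)."""
    if not per_dataset_gene_sets:
        raise ValueError("need at least one gene set")
    if min_datasets > len(per_dataset_gene_sets):
        warnings.warn(
            f"min_datasets={min_datasets} exceeds the number of datasets "
            f"({len(per_dataset_gene_sets)}); consensus is empty",
            stacklevel=2,
        )
        return set()
    from collections import Counter

    tally: Counter = Counter()
    for s in per_dataset_gene_sets:
        tally.update(set(s))
    return {g for g, c in tally.items() if c >= min_datasets}


@dataclass
class PooledReplicates:
    coverage: BinnedCoverage
    pearson_r: float
    low_correlation: bool


def pool_replicates(
    cov_rep1: BinnedCoverage, cov_rep2: BinnedCoverage, r_min: float = 0.96
) -> PooledReplicates:
    """Pool two replicate coverages (summed raw counts) and report their
    Pearson correlation over bins where at least one replicate is nonzero.

    Replicates with r <= r_min (or undefined r) are flagged, never refused.
    """
    if not cov_rep1.same_grid(cov_rep2):
        raise ValueError("replicates are on different bin grids")
    a = np.concatenate([cov_rep1.bins[c] for c in sorted(cov_rep1.bins)])
    b = np.concatenate([cov_rep2.bins[c] for c in sorted(cov_rep2.bins)])
    mask = (a > 0) | (b > 0)
    r = float("nan")
    if mask.sum() >= 2 and a[mask].std() > 0 and b[mask].std() > 0:
        r = float(np.corrcoef(a[mask], b[mask])[0, 1])
    low = not (r > r_min)  # NaN counts as low
    if low:
        logger.warning("replicate correlation %.4f <= %.2f (pooling anyway)", r, r_min)
    starts = None
    if cov_rep1.starts is not None and cov_rep2.starts is not None:
        starts = {c: cov_rep1.starts[c] + cov_rep2.starts[c] for c in cov_rep1.starts}
    pooled = BinnedCoverage(
        bins={c: cov_rep1.bins[c] + cov_rep2.bins[c] for c in cov_rep1.bins},
        bin_width=cov_rep1.bin_width,
        total_reads=cov_rep1.total_reads + cov_rep2.total_reads,
        starts=starts,
    )
    return PooledReplicates(coverage=pooled, pearson_r=r, low_correlation=low)
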