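"""Allelic read counting over promoter regions and the allelic statistics:

* paternal allelic ratio (%) = paternal reads / (paternal + maternal) x 100
* per-stage expected ratio from the genome-wide allelic imbalance
* 1-df chi-square goodness-of-fit test of a region's allelic counts
  against the stage's expected ratio (no continuity correction)
* two-sided Cochran-Armitage trend test of the paternal proportion
  across ordered developmental stages (equally spaced integer scores)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .reads import ReadRecord


@dataclass(frozen=True)
class RegionAllelicCounts:
    gene_id: str
    chrom: str
    start: int
    end: int
    stage: str
    n_pat: int
    n_mat: int

    def __post_init__(self) -> None:
        if self.n_pat < 0 or self.n_mat < 0:
            raise ValueError("allelic counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_pat + self.n_mat


@dataclass(frozen=True)
class StageBackground:
    """Genome-wide allelic imbalance at one stage: the expected paternal
    fraction p0 = total paternal / total allele-assigned reads (the
    'global gene average' track)."""

    stage: str
    total_paternal: int
    total_assigned: int
    p0: float

    @property
    def percent(self) -> float:
        return 100.0 * self.p0


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    stage: str
    ratio_percent: float
    chi2: float
    df: int
    pvalue: float
    direction: str  # "paternal" | "maternal" | "none"


@dataclass(frozen=True)
class TrendResult:
    gene_id: str
    stages: tuple[str, ...]
    n_pat: tuple[int, ...]
    n_mat: tuple[int, ...]
    statistic: float  # signed z statistic
    pvalue: float  # two-sided, asymptotic normal
    slope_sign: int


def count_region_alleles(
    region: tuple[str, int, int],
    pat_reads: Iterable[ReadRecord],
    mat_reads: Iterable[ReadRecord],
    gene_id: str = "",
    stage: str = "",
    chrom_sizes: Mapping[str, int] | None = None,
) -> RegionAllelicCounts:
    """Count deduplicated allelic reads overlapping a region by >= 1 bp
    (half-open intervals; an abutting read does not count)."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("region must be a nonempty interval")
    if chrom_sizes is not None:
        if chrom not in chrom_sizes or start < 0 or end > chrom_sizes[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} outside the genome")

    def n_overlapping(reads: Iterable[ReadRecord]) -> int:
        return sum(1 for r in reads if r.chrom == chrom and r.start < end and r.end > start)

    return RegionAllelicCounts(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        stage=stage,
        n_pat=n_overlapping(pat_reads),
        n_mat=n_overlapping(mat_reads),
    )


def paternal_ratio(n_pat: int, n_mat: int) -> float:
    """Paternal allelic ratio (%) = n_pat / (n_pat + n_mat) x 100.

    Undefined (NaN) when both counts are zero.
    """
    total = n_pat + n_mat
    if total == 0:
        return math.nan
    return 100.0 * n_pat / total


def stage_background(n_pat: int, n_mat: int, stage: str = "") -> StageBackground:
    """Genome-wide expected paternal fraction for one stage."""
    total = n_pat + n_mat
    if total <= 0:
        raise ValueError(f"no allele-assigned reads at stage {stage!r}")
    return StageBackground(stage=stage, total_paternal=n_pat, total_assigned=total, p0=n_pat / total)


def chisq_enrichment(
    counts: RegionAllelicCounts, bg: StageBackground, alpha: float = 0.05
) -> EnrichmentResult:
    """1-df chi-square goodness-of-fit of (n_pat, n_mat) against the
    stage-expected split (p0, 1-p0), without continuity correction.

    direction is 'paternal' when the observed fraction exceeds p0 and
    p < alpha (maternal symmetric), else 'none'.
    """
    n = counts.total
    if n <= 0:
        raise ValueError("cannot test a region with zero allelic reads")
    p0 = bg.p0
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError("degenerate expected ratio (p0 is 0 or 1)")
    expected = np.array([n * p0, n * (1.0 - p0)])
    observed = np.array([counts.n_pat, counts.n_mat], dtype=float)
    chi2, pvalue = stats.chisquare(observed, f_exp=expected)
    frac = counts.n_pat / n
    if pvalue < alpha and frac > p0:
        direction = "paternal"
    elif pvalue < alpha and frac < p0:
        direction = "maternal"
    else:
        direction = "none"
    return EnrichmentResult(
        gene_id=counts.gene_id,
        stage=counts.stage,
        ratio_percent=paternal_ratio(counts.n_pat, counts.n_mat),
        chi2=float(chi2),
        df=1,
        pvalue=float(pvalue),
        direction=direction,
    )


def ca_trend_statistic(n_pat: np.ndarray, n_mat: np.ndarray) -> tuple[float, float, int]:
    """Cochran-Armitage trend z-statistic with scores 0..k-1.

    Returns (z, two-sided p, slope sign).  With exactly two groups the
    statistic reduces to the pooled two-proportion z-test.
    """
    x = np.asarray(n_pat, dtype=float)
    n = x + np.asarray(n_mat, dtype=float)
    s = np.arange(len(x), dtype=float)
    N = n.sum()
    pbar = x.sum() / N
    num = float(np.sum(s * x) - pbar * np.sum(s * n))
    var = pbar * (1.0 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0, 0
    z = num / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0)), int(np.sign(num))


def trend_test(
    series: Sequence[tuple[str, int, int]], gene_id: str = ""
) -> TrendResult:
    """Two-sided Cochran-Armitage trend test of the paternal proportion
    across developmental stages, in the given stage order.

    ``series`` is an ordered sequence of (stage, n_pat, n_mat).  Stages
    with zero total reads are dropped with a warning; fewer than two
    usable stages is an error.  Scores are equally spaced integers over
    the retained stage order.
    """
    usable = [(st, p, m) for st, p, m in series if p + m > 0]
    dropped = [st for st, p, m in series if p + m == 0]
    if dropped:
        warnings.warn(f"stages with zero allelic reads dropped: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("trend test needs >= 2 stages with nonzero totals")
    stages = tuple(st for st, _, _ in usable)
    n_pat = tuple(p for _, p, _ in usable)
    n_mat = tuple(m for _, _, m in usable)
    z, p, sign = ca_trend_statistic(np.array(n_pat), np.array(n_mat))
    return TrendResult(
        gene_id=gene_id,
        stages=stages,
        n_pat=n_pat,
        n_mat=n_mat,
        statistic=z,
        pvalue=p,
        slope_sign=sign,
    )
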