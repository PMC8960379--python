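"""Read filtering and SNP-based parental-allele assignment.

Mirrors the SNPsplit decision rule: a read is paternal when at least one
covered strain SNP shows the paternal base and none shows the maternal
base (maternal symmetric); reads matching both parents at different SNPs
are conflicting; reads covering no informative SNP are unassignable.
Conflicting reads are grouped with unassignable reads and excluded from
allelic counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

from .genome import SnpMap
from .reads import ReadRecord

logger = logging.getLogger(__name__)

PATERNAL = "paternal"
MATERNAL = "maternal"
UNASSIGNABLE = "unassignable"
CONFLICTING = "conflicting"


def filter_reads(
    reads: Sequence[ReadRecord], mapq_min: int = 30, dedup: bool = True
) -> list[ReadRecord]:
    """Remove low-MAPQ reads (MAPQ < mapq_min, strict) and, if ``dedup``,
    collapse PCR duplicates to a single read per (chrom, start, end, strand)
    signature.  The surviving duplicate is the first by
    (start, end, strand, read_id) order; output preserves input order.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    kept = [r for r in reads if r.mapq >= mapq_min]
    if not dedup:
        return kept
    winner: dict[tuple, ReadRecord] = {}
    for r in kept:
        sig = r.signature
        cur = winner.get(sig)
        if cur is None or (r.start, r.end, r.strand, r.read_id) < (
            cur.start,
            cur.end,
            cur.strand,
            cur.read_id,
        ):
            winner[sig] = r
    return [r for r in kept if winner[r.signature] is r]


def assign_read(read: ReadRecord, snps: SnpMap) -> str:
    """Assign one read to a parental allele from its observed SNP bases."""
    n_pat = n_mat = 0
    for pos, base in read.snp_obs:
        entry = snps.lookup(read.chrom, pos)
        if entry is None:
            logger.debug("read %s: observation at %s:%d not in SNP map", read.read_id, read.chrom, pos)
            continue
        pat_base, mat_base = entry
        if base == pat_base:
            n_pat += 1
        elif base == mat_base:
            n_mat += 1
        # a base matching neither parent carries no information
    if n_pat > 0 and n_mat > 0:
        return CONFLICTING
    if n_pat > 0:
        return PATERNAL
    if n_mat > 0:
        return MATERNAL
    return UNASSIGNABLE


def split_reads(
    reads: Iterable[ReadRecord], snps: SnpMap
) -> tuple[dict[str, list[ReadRecord]], dict[str, int]]:
    """Partition reads into paternal / maternal / other (unassignable or
    conflicting) and return per-label summary counts.

    The partition is exhaustive and disjoint; summary counts sum to the
    input size.
    """
    parts: dict[str, list[ReadRecord]] = {PATERNAL: [], MATERNAL: [], "other": []}
    tally: Counter = Counter()
    n = 0
    for read in reads:
        label = assign_read(read, snps)
        tally[label] += 1
        n += 1
        if label in (PATERNAL, MATERNAL):
            parts[label].append(read)
        else:
            parts["other"].append(read)
    summary = {
        "n_total": n,
        "n_paternal": tally[PATERNAL],
        "n_maternal": tally[MATERNAL],
        "n_unassignable": tally[UNASSIGNABLE],
        "n_conflicting": tally[CONFLICTING],
    }
    return parts, summary
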