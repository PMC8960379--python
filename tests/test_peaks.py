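"""Coverage binning, the broad-peak screen, annotation, pooling and the
consensus rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pegtrace.genome import GeneModel, GenomeModel
from pegtrace.peaks import (
    BinnedCoverage,
    annotate_peaks,
    bin_coverage,
    call_broad_peaks,
    consensus_gene_sets,
    pool_replicates,
)
from pegtrace.reads import ReadRecord, simulate_chip_reads
from pegtrace.rng import substream


def _cov(bins, total=None, bw=10):
    arr = np.asarray(bins, dtype=np.int64)
    return BinnedCoverage(
        bins={"chr1": arr}, bin_width=bw,
        total_reads=int(arr.sum()) if total is None else total,
        starts={"chr1": arr},
    )


def test_rpkm_formula_single_read_in_one_bin():
    """One read in a 10-bp bin out of 1e6 mapped reads -> RPKM 100."""
    cov = _cov([1, 0, 0], total=10**6)
    assert cov.rpkm("chr1")[0] == pytest.approx(100.0)


def test_coverage_conservation_and_scaling(genome, snps, truth, small_config):
    reads = simulate_chip_reads(genome, snps, truth, "sperm", small_config)[:2000]
    cov = bin_coverage(reads, genome)
    per_read = sum((r.end - 1) // 10 - r.start // 10 + 1 for r in reads)
    assert sum(arr.sum() for arr in cov.bins.values()) == per_read
    # doubling every read doubles raw counts but leaves RPKM unchanged
    cov2 = bin_coverage(reads + reads, genome)
    chrom = reads[0].chrom
    assert np.array_equal(cov2.bins[chrom], 2 * cov.bins[chrom])
    np.testing.assert_allclose(cov2.rpkm(chrom), cov.rpkm(chrom))


def test_empty_reads_and_out_of_bounds(genome):
    cov = bin_coverage([], genome)
    assert all(arr.sum() == 0 for arr in cov.bins.values())
    bad = ReadRecord(read_id="oob", chrom="chr1", start=-5, end=95, strand="+", mapq=60)
    with pytest.raises(ValueError, match="oob"):
        bin_coverage([bad], genome)


def test_window_pvalue_matches_direct_poisson_tail():
    """The reported peak p equals an independent Poisson-tail computation."""
    base = np.zeros(2000, dtype=np.int64)
    rng = substream(42, "peak-oracle")
    base[:] = rng.poisson(1.5, size=2000)
    base[400:420] += 8  # one hot 200-bp window on the 10-bp grid
    cov = _cov(base)
    peaks = call_broad_peaks(cov, None, q_cutoff=0.05)
    assert len(peaks) == 1
    counts = base.reshape(100, 20).sum(axis=1)
    lam = counts.sum() / 100
    oracle = stats.poisson.sf(counts[20] - 1, lam)
    assert abs(np.log10(peaks[0].pvalue) - np.log10(oracle)) < 1e-9


def test_qcutoff_monotonicity():
    rng = substream(7, "mono")
    arr = rng.poisson(2.0, size=5000)
    arr[1000:1100] += 8
    arr[3000:3050] += 5
    cov = _cov(arr)
    loose = call_broad_peaks(cov, None, q_cutoff=0.20)
    strict = call_broad_peaks(cov, None, q_cutoff=0.05)
    for pk in strict:  # every strict peak is contained in a loose peak
        assert any(l.start <= pk.start and l.end >= pk.end for l in loose)


def test_empty_treatment_gives_no_peaks():
    assert call_broad_peaks(_cov(np.zeros(100)), None) == []


def test_control_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="grid"):
        call_broad_peaks(_cov(np.ones(100)), _cov(np.ones(50)))


def test_pool_replicates_identical_and_hand_pearson():
    a = _cov([1, 4, 2, 8, 5])
    res = pool_replicates(a, _cov([1, 4, 2, 8, 5]))
    assert res.pearson_r == pytest.approx(1.0)
    assert not res.low_correlation
    assert np.array_equal(res.coverage.bins["chr1"], [2, 8, 4, 16, 10])

    x, y = np.array([1.0, 4, 2, 8, 5]), np.array([2.0, 3, 2, 9, 4])
    hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    res2 = pool_replicates(_cov(x.astype(int)), _cov(y.astype(int)))
    assert res2.pearson_r == pytest.approx(hand, abs=1e-12)


def test_pool_all_zero_replicate_flagged_but_pooled():
    res = pool_replicates(_cov([3, 1, 4]), _cov([0, 0, 0]))
    assert np.isnan(res.pearson_r)
    assert res.low_correlation
    assert np.array_equal(res.coverage.bins["chr1"], [3, 1, 4])


def test_consensus_rule():
    assert consensus_gene_sets([{"A", "B"}, {"B", "C"}], 2) == {"B"}
    assert consensus_gene_sets([{"A"}, {"A"}, {"A"}], 2) == {"A"}
    with pytest.warns(UserWarning):
        assert consensus_gene_sets([{"A", "B"}], 2) == set()


@pytest.fixture()
def two_gene_genome():
    genes = [
        GeneModel("gA", "chr1", "+", 5000, 5000, 7000, 4000, 5500),
        GeneModel("gB", "chr1", "+", 11000, 11000, 13000, 10000, 11500),
    ]
    return GenomeModel(chromosomes=[("chr1", 20000)], genes=genes,
                       repeats=pd.DataFrame(columns=["chrom", "start", "end", "family"]))


def _peak(start, end):
    from pegtrace.peaks import Peak

    return Peak(chrom="chr1", start=start, end=end, fold=5.0, pvalue=1e-6,
                qvalue=1e-5, n_windows=1)


def test_annotation_relations_and_window(two_gene_genome):
    ann = annotate_peaks([_peak(4200, 4600)], two_gene_genome, window=2000)
    assert [(a.gene_id, a.relation, a.distance) for a in ann] == [("gA", "promoter-overlap", 0)]
    # peak 3 kb from the nearest TSS with a 2-kb window: no association
    assert annotate_peaks([_peak(1500, 2000)], two_gene_genome, window=2000) == []
    # equidistant genes: both reported (many-to-many)
    mid = annotate_peaks([_peak(7950, 8050)], two_gene_genome, window=4000)
    assert sorted(a.gene_id for a in mid) == ["gA", "gB"]
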