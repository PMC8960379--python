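"""Allelic ratio, stage background, chi-square enrichment screen and the
Cochran-Armitage trend test."""

import math
import warnings

import numpy as np
import pytest
from statsmodels.stats.proportion import proportions_ztest

from pegtrace.chipstats import (
    RegionAllelicCounts,
    StageBackground,
    chisq_enrichment,
    count_region_alleles,
    paternal_ratio,
    stage_background,
    trend_test,
)
from pegtrace.allele import filter_reads
from pegtrace.reads import ReadRecord


def _rc(n_pat, n_mat, stage="2c"):
    return RegionAllelicCounts(gene_id="g", chrom="chr1", start=0, end=1000,
                               stage=stage, n_pat=n_pat, n_mat=n_mat)


def _read(rid, start, end):
    return ReadRecord(read_id=rid, chrom="chr1", start=start, end=end, strand="+", mapq=60)


@pytest.mark.parametrize(
    "n_pat,n_mat,expected",
    [(10, 10, 50.0), (0, 7, 0.0), (49, 51, 49.0), (7, 0, 100.0)],
)
def test_paternal_ratio_equation(n_pat, n_mat, expected):
    assert paternal_ratio(n_pat, n_mat) == pytest.approx(expected)


def test_paternal_ratio_undefined_when_empty():
    assert math.isnan(paternal_ratio(0, 0))


def test_stage_background():
    assert stage_background(1000, 1000).p0 == pytest.approx(0.5)
    bg = stage_background(600, 400, stage="PN5")
    assert bg.p0 == pytest.approx(0.6)
    assert bg.percent == pytest.approx(60.0)
    with pytest.raises(ValueError):
        stage_background(0, 0)


def test_region_counting_overlap_rule():
    pat = [_read("p1", 100, 200), _read("p2", 950, 1050), _read("p3", 1000, 1100)]
    mat = [_read("m1", 0, 100)]  # abuts region start at 100 (half-open): excluded
    rc = count_region_alleles(("chr1", 100, 1000), pat, mat)
    assert (rc.n_pat, rc.n_mat) == (2, 0)


def test_region_counting_dedups_through_filter():
    dup1, dup2 = _read("a", 100, 200), _read("b", 100, 200)
    pat = filter_reads([dup1, dup2], mapq_min=0, dedup=True)
    rc = count_region_alleles(("chr1", 0, 1000), pat, [])
    assert rc.n_pat == 1


def test_region_outside_genome_rejected():
    with pytest.raises(ValueError, match="outside"):
        count_region_alleles(("chr1", 0, 99999), [], [], chrom_sizes={"chr1": 5000})


def test_chisq_worked_examples():
    bg5 = StageBackground(stage="s", total_paternal=500, total_assigned=1000, p0=0.5)
    r = chisq_enrichment(_rc(50, 50), bg5)
    assert r.chi2 == pytest.approx(0.0)
    assert r.pvalue == pytest.approx(1.0)
    assert r.direction == "none"

    r = chisq_enrichment(_rc(90, 10), bg5)
    assert r.chi2 == pytest.approx(64.0)  # (90-50)^2/50 + (10-50)^2/50
    assert r.direction == "paternal"
    assert r.ratio_percent == pytest.approx(90.0)

    bg6 = StageBackground(stage="s", total_paternal=600, total_assigned=1000, p0=0.6)
    r = chisq_enrichment(_rc(60, 40), bg6)
    assert r.chi2 == pytest.approx(0.0)
    assert r.direction == "none"


def test_chisq_degenerate_background_rejected():
    bad = StageBackground(stage="s", total_paternal=10, total_assigned=10, p0=1.0)
    with pytest.raises(ValueError):
        chisq_enrichment(_rc(5, 5), bad)
    with pytest.raises(ValueError):
        chisq_enrichment(_rc(0, 0), StageBackground("s", 1, 2, 0.5))


def test_background_consistency_with_single_region_ratio():
    """stage_background over one region's reads equals that region's
    paternal ratio / 100."""
    rc = _rc(37, 63)
    bg = stage_background(rc.n_pat, rc.n_mat)
    assert bg.p0 == pytest.approx(paternal_ratio(rc.n_pat, rc.n_mat) / 100.0)


def test_trend_flat_series_is_null():
    series = [(s, 60, 40) for s in ("a", "b", "c", "d")]
    res = trend_test(series)
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)
    assert res.slope_sign == 0


def test_trend_two_stages_equals_two_proportion_ztest():
    x = (80, 55)
    n = (120, 110)
    res = trend_test([("a", x[0], n[0] - x[0]), ("b", x[1], n[1] - x[1])])
    z, p = proportions_ztest(np.array(x), np.array(n))
    assert abs(res.pvalue - p) < 1e-9


def test_trend_monotone_decline_detected():
    """90% -> 50% over 5 stages at n=200/stage: significant negative slope."""
    props = [0.9, 0.8, 0.7, 0.6, 0.5]
    series = [(f"s{i}", int(200 * p), 200 - int(200 * p)) for i, p in enumerate(props)]
    res = trend_test(series)
    assert res.pvalue < 0.05
    assert res.slope_sign == -1


def test_trend_drops_empty_stages_with_warning():
    series = [("a", 50, 50), ("b", 0, 0), ("c", 30, 70)]
    with pytest.warns(UserWarning, match="dropped"):
        res = trend_test(series)
    assert res.stages == ("a", "c")
    with pytest.raises(ValueError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trend_test([("a", 10, 10), ("b", 0, 0)])
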