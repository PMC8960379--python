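"""Integration logic: zygote parent-of-origin status, set intersections,
transient classification, ERV proximity, and small pipeline runs."""

import json

import pandas as pd
import pytest

from pegtrace.config import CHIP_STAGES, SimConfig
from pegtrace.genome import GeneModel
from pegtrace.integrate import (
    classify_transient,
    erv_proximity,
    intersect_peg_chip,
    zygote_parental_status,
)
from pegtrace.peaks import Peak
from pegtrace.pipeline import run_pipeline


def _peak(start, end):
    return Peak(chrom="chr1", start=start, end=end, fold=5.0, pvalue=1e-8,
                qvalue=1e-7, n_windows=1)


REGIONS = {"g1": ("chr1", 1000, 2000)}


def test_zygote_status_requires_paternal_only():
    pat, mat, ooc = [_peak(1200, 1800)], [_peak(1100, 1900)], [_peak(1000, 2000)]
    assert zygote_parental_status(pat, [], [], REGIONS)["g1"] is True
    assert zygote_parental_status(pat, mat, [], REGIONS)["g1"] is False
    assert zygote_parental_status(pat, [], ooc, REGIONS)["g1"] is False
    assert zygote_parental_status([], [], [], REGIONS)["g1"] is False


def test_intersect_counts_and_fraction():
    res = intersect_peg_chip({"a", "b", "c"}, {"b", "c", "d"})
    assert (res["n_overlap"], res["n_peg"]) == (2, 3)
    assert res["fraction"] == pytest.approx(2 / 3)
    assert intersect_peg_chip({"a"}, {"b"})["n_overlap"] == 0
    table = res["table"]
    assert bool(table.loc["b", "peg"]) and bool(table.loc["b", "chip"])


def test_transient_classification_patterns():
    stages = CHIP_STAGES  # PN5, early2c, late2c, 4c, 8c, ICM
    expr = {"early2c": "paternal", "late2c": "paternal", "4c": "paternal",
            "8c": "biallelic", "ICM": "biallelic"}
    chip = {s: "paternal" for s in ("PN5", "early2c", "late2c", "4c")}
    chip["8c"] = "none"
    chip["ICM"] = "none"
    res = classify_transient("g", expr, chip, stages)
    assert res["class"] == "transient"
    assert res["expression_loss_stage"] == "8c"
    assert res["chip_loss_stage"] == "8c"
    assert res["coincident"] is True

    stable = classify_transient("g", {s: "paternal" for s in expr}, chip, stages)
    assert stable["class"] == "stable"

    short = classify_transient("g", {"8c": "paternal"}, chip, stages)
    assert short["class"] == "inconclusive"

    never_paternal = classify_transient(
        "g", {s: "biallelic" for s in expr}, chip, stages
    )
    assert never_paternal["class"] == "inconclusive"


def test_coincidence_allows_one_stage_slack():
    expr = {"early2c": "paternal", "late2c": "paternal", "4c": "paternal",
            "8c": "biallelic", "ICM": "biallelic"}
    chip = {"PN5": "paternal", "early2c": "paternal", "late2c": "paternal",
            "4c": "paternal", "8c": "paternal", "ICM": "none"}
    res = classify_transient("g", expr, chip, CHIP_STAGES)
    assert res["chip_loss_stage"] == "ICM"
    assert res["coincident"] is True  # |8c - ICM| = 1 stage
    chip_early = dict.fromkeys(CHIP_STAGES, "none")
    chip_early["PN5"] = "paternal"
    res2 = classify_transient("g", expr, chip_early, CHIP_STAGES)
    assert res2["coincident"] is False  # loss at early2c vs 8c


def test_erv_proximity_window():
    gene = GeneModel("g", "chr1", "+", 10_000, 10_000, 12_000, 9_000, 10_500)
    reps = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 12_400, "end": 12_800, "family": "ERVK"},
            {"chrom": "chr1", "start": 12_600, "end": 13_000, "family": "ERV1"},
            {"chrom": "chr2", "start": 10_100, "end": 10_500, "family": "ERVL-MaLR"},
        ]
    )
    out = erv_proximity([gene], reps, window=2500)
    assert out["g"] == ("ERVK",)  # edge at TSS+2400 in, TSS+2600 out, other chrom out
    assert erv_proximity([gene], reps.iloc[0:0], window=2500)["g"] == ()


@pytest.fixture(scope="module")
def tiny_pipeline_config():
    return SimConfig(
        seed=17, genes_per_chromosome=12, chip_promoter_depth=200.0,
        rna_mean_expression=600.0, peg_fraction=0.25, transient_fraction=0.5,
    )


def test_pipeline_is_deterministic_and_sound(tiny_pipeline_config, tmp_path):
    s1 = run_pipeline(tiny_pipeline_config, outdir=tmp_path / "run1")
    s2 = run_pipeline(tiny_pipeline_config)
    assert json.dumps(s1, sort_keys=True, default=str) == json.dumps(
        s2, sort_keys=True, default=str
    )
    assert (tmp_path / "run1" / "summary.json").exists()
    assert (tmp_path / "run1" / "integration_records.tsv").exists()
    assert s1["n_confirmed"] >= 1
    assert s1["confirmed_true_positive"] == s1["n_confirmed"]  # no false PEGs


def test_null_pipeline_confirms_nothing():
    cfg = SimConfig(seed=23, genes_per_chromosome=12, peg_fraction=0.0,
                    chip_promoter_depth=200.0, rna_mean_expression=600.0)
    s = run_pipeline(cfg)
    assert s["n_confirmed"] == 0
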