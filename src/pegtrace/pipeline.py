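"""End-to-end synthetic pipeline: simulate -> assign -> peaks -> allelic
ChIP statistics -> allelic differential expression -> integration.

``run_pipeline`` reproduces the full analysis on a planted-truth genome
and reports recovery metrics against that truth.  All randomness derives
from ``config.seed`` through tagged substreams, so repeated runs produce
identical summaries.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .allele import filter_reads, split_reads
from .chipstats import (
    EnrichmentResult,
    RegionAllelicCounts,
    chisq_enrichment,
    paternal_ratio,
    stage_background,
    trend_test,
)
from .config import CHIP_STAGES, CROSSES, EXPR_STAGES, ZGA_STAGES, SimConfig
from .counts import simulate_allelic_counts, simulate_group_counts
from .de import call_candidates, confirm_candidates, nb_exact_test, normalize_libsize, validate_andro_partheno
from .genome import GenomeModel, SnpMap, make_genome, make_snp_map, make_truth
from .integrate import (
    BIALLELIC_BAND,
    MIN_TRACEABLE_SNPS,
    IntegrationRecord,
    classify_transient,
    erv_proximity,
    intersect_peg_chip,
    zygote_parental_status,
)
from .peaks import annotate_peaks, bin_coverage, call_broad_peaks, consensus_gene_sets
from .reads import simulate_chip_reads

logger = logging.getLogger(__name__)

#: per-stage trajectory thresholds for the "paternal" expression call
STAGE_CALL_LFC = 1.0
STAGE_CALL_FDR = 0.05
#: minimum allelic reads at a gene-stage for the chi-square screen
MIN_REGION_READS = 10
#: ICM peak preset used before promoter read counting
ICM_Q_CUTOFF = 0.01


def build_counting_regions(genome: GenomeModel, icm_peaks) -> dict[str, tuple[str, int, int]]:
    """Counting region per gene: the intersection of the ICM broad peak
    with the promoter (CGI-containing) interval; the promoter itself
    when no ICM peak overlaps it."""
    regions = {}
    for g in genome.genes:
        best = None
        for p in icm_peaks:
            if p.chrom != g.chrom:
                continue
            s, e = max(p.start, g.promoter_start), min(p.end, g.promoter_end)
            if e > s and (best is None or (e - s) > (best[2] - best[1])):
                best = (g.chrom, s, e)
        regions[g.gene_id] = best if best is not None else (g.chrom, g.promoter_start, g.promoter_end)
    return regions


def _read_arrays(reads) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    return {
        c: (np.array([se[0] for se in v]), np.array([se[1] for se in v]))
        for c, v in by_chrom.items()
    }


def _count_region(arrays, region) -> int:
    chrom, start, end = region
    if chrom not in arrays:
        return 0
    starts, ends = arrays[chrom]
    return int(np.count_nonzero((starts < end) & (ends > start)))


def _stage_expression_calls(
    de: pd.DataFrame, ratios: pd.Series
) -> pd.Series:
    """Per-gene expression label at one stage: 'paternal' when the DE
    paternal call passes; 'biallelic' when it fails and the allelic ratio
    sits in the 50±15% band; otherwise 'other'."""
    paternal = (de["log2fc"] > STAGE_CALL_LFC) & (de["fdr"] < STAGE_CALL_FDR) & ~de["low_expression"]
    lo, hi = BIALLELIC_BAND
    biallelic = ~paternal & ratios.between(lo, hi)
    return pd.Series(
        np.where(paternal, "paternal", np.where(biallelic, "biallelic", "other")),
        index=de.index,
    )


def _allelic_ratio_percent(matrix, stage: str) -> pd.Series:
    """Pooled normalized paternal percentage per gene at one stage."""
    sub = matrix.subset(matrix.samples["stage"] == stage)
    factors = normalize_libsize(sub.counts)
    norm = sub.counts / factors
    pat = norm[sub.samples.index[sub.samples["allele"] == "paternal"]].sum(axis=1)
    mat = norm[sub.samples.index[sub.samples["allele"] == "maternal"]].sum(axis=1)
    return 100.0 * pat / (pat + mat).replace(0, np.nan)


def run_pipeline(config: SimConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic analysis; return the summary dictionary.

    When ``outdir`` is given, all intermediate tables (truth, SNPs,
    peaks, per-stage statistics, DE results, integration records) and a
    ``summary.json`` are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    genome = make_genome(config)
    snps = make_snp_map(genome, config.snp_density, config.seed)
    truth = make_truth(genome, config)
    chrom_sizes = genome.chrom_sizes

    # ---------------- sperm H3K4me3 consensus across three datasets
    sperm_sets = []
    for ds in range(3):
        reads = filter_reads(simulate_chip_reads(genome, snps, truth, "sperm", config, replicate=ds))
        pk = call_broad_peaks(bin_coverage(reads, genome), None, q_cutoff=0.05)
        ann = annotate_peaks(pk, genome, window=2000)
        sperm_sets.append({a.gene_id for a in ann})
    sperm_consensus = consensus_gene_sets(sperm_sets, min_datasets=2)

    # ---------------- zygote (PN3) parent-of-origin H3K4me3 status
    comp_peaks = {}
    for comp in ("PN3_paternal", "PN3_maternal", "oocyte"):
        reads = filter_reads(simulate_chip_reads(genome, snps, truth, comp, config))
        comp_peaks[comp] = call_broad_peaks(bin_coverage(reads, genome), None, q_cutoff=0.05)
    gene_regions = {g.gene_id: (g.chrom, g.promoter_start, g.promoter_end) for g in genome.genes}
    zygote_status = zygote_parental_status(
        comp_peaks["PN3_paternal"], comp_peaks["PN3_maternal"], comp_peaks["oocyte"], gene_regions
    )

    # ---------------- per-stage ChIP reads, allele split, region stats
    stage_reads = {
        stage: simulate_chip_reads(genome, snps, truth, stage, config) for stage in CHIP_STAGES
    }
    icm_merged = filter_reads(stage_reads["ICM"])
    icm_peaks = call_broad_peaks(bin_coverage(icm_merged, genome), None, q_cutoff=ICM_Q_CUTOFF)
    regions = build_counting_regions(genome, icm_peaks)
    traceable = {
        g: len(snps.in_interval(*regions[g])) >= MIN_TRACEABLE_SNPS for g in regions
    }

    enrich: dict[str, dict[str, EnrichmentResult]] = {g: {} for g in regions}
    region_counts: dict[str, dict[str, tuple[int, int]]] = {g: {} for g in regions}
    backgrounds = {}
    chip_rows = []
    for stage in CHIP_STAGES:
        mapq_ok = filter_reads(stage_reads[stage], dedup=False)
        parts, _ = split_reads(mapq_ok, snps)
        pat = filter_reads(parts["paternal"], mapq_min=0, dedup=True)
        mat = filter_reads(parts["maternal"], mapq_min=0, dedup=True)
        bg = stage_background(len(pat), len(mat), stage=stage)
        backgrounds[stage] = bg
        pat_arrays, mat_arrays = _read_arrays(pat), _read_arrays(mat)
        for gid, region in regions.items():
            n_pat = _count_region(pat_arrays, region)
            n_mat = _count_region(mat_arrays, region)
            rc = RegionAllelicCounts(
                gene_id=gid, chrom=region[0], start=region[1], end=region[2],
                stage=stage, n_pat=n_pat, n_mat=n_mat,
            )
            if rc.total >= MIN_REGION_READS and traceable[gid]:
                res = chisq_enrichment(rc, bg)
            else:
                res = None
            if res is not None:
                enrich[gid][stage] = res
                region_counts[gid][stage] = (n_pat, n_mat)
            chip_rows.append(
                {
                    "gene_id": gid, "stage": stage, "n_pat": n_pat, "n_mat": n_mat,
                    "ratio_percent": paternal_ratio(n_pat, n_mat),
                    "chi2": res.chi2 if res else np.nan,
                    "pvalue": res.pvalue if res else np.nan,
                    "direction": res.direction if res else "untested",
                    "global_average_percent": bg.percent,
                }
            )
    chip_table = pd.DataFrame(chip_rows)

    trend_pvalues = {}
    for gid in regions:
        series = [
            (stage, *region_counts[gid][stage])
            for stage in CHIP_STAGES
            if stage in region_counts[gid]
        ]
        if len(series) >= 2:
            trend_pvalues[gid] = trend_test(series, gene_id=gid).pvalue

    # ---------------- allelic RNA: candidates, confirmation, trajectory
    ds1 = simulate_allelic_counts(
        genome, truth,
        {"stages": list(ZGA_STAGES), "crosses": list(CROSSES), "replicates": config.n_replicates},
        config, dataset=1,
    )
    ds2 = simulate_allelic_counts(
        genome, truth,
        {"stages": list(ZGA_STAGES), "crosses": [CROSSES[0]], "replicates": config.n_replicates},
        config, dataset=2,
    )
    ds3 = simulate_allelic_counts(
        genome, truth,
        {"stages": list(EXPR_STAGES), "crosses": [CROSSES[0]], "replicates": config.n_replicates},
        config, dataset=3,
    )

    def per_stage_de(matrix, stages):
        return {
            stage: nb_exact_test(matrix.subset(matrix.samples["stage"] == stage))
            for stage in stages
        }

    de1 = per_stage_de(ds1, ZGA_STAGES)
    de2 = per_stage_de(ds2, ZGA_STAGES)
    candidates = set()
    for stage in ZGA_STAGES:
        candidates |= call_candidates(de1[stage])
    second_pass = set()
    for stage in ZGA_STAGES:
        second_pass |= call_candidates(de2[stage])
    confirmed = {g for g in candidates if g in second_pass}

    de3 = per_stage_de(ds3, EXPR_STAGES)
    expression_calls: dict[str, dict[str, str]] = {g: {} for g in truth.index}
    for stage in EXPR_STAGES:
        ratios = _allelic_ratio_percent(ds3, stage)
        calls = _stage_expression_calls(de3[stage], ratios)
        for g in truth.index:
            expression_calls[g][stage] = calls.loc[g]

    # ---------------- uniparental / amanitin validation
    groups = simulate_group_counts(
        genome, truth, ("androgenote", "parthenogenote", "amanitin"), config
    )
    validation = validate_andro_partheno(sorted(confirmed), groups)

    # ---------------- integration
    chip_overlap = intersect_peg_chip(confirmed, sperm_consensus)
    erv = erv_proximity(genome.genes, genome.repeats, window=2500)

    records = []
    for gid in sorted(confirmed):
        directions = {s: r.direction for s, r in enrich[gid].items()}
        cls = classify_transient(gid, expression_calls[gid], directions, CHIP_STAGES)
        records.append(
            IntegrationRecord(
                gene_id=gid,
                peg_status="confirmed",
                sperm_h3k4me3=gid in sperm_consensus,
                zygote_paternal_h3k4me3=zygote_status.get(gid, False),
                has_promoter_snps=traceable[gid],
                validated_ap=bool(validation.loc[gid, "validated_ap"]),
                expressed_pre_zga=bool(validation.loc[gid, "expressed_pre_zga"]),
                carryover_confounded=bool(validation.loc[gid, "carryover_confounded"]),
                transient=cls["class"],
                expression_loss_stage=cls["expression_loss_stage"],
                chip_loss_stage=cls["chip_loss_stage"],
                coincident_loss=bool(cls["coincident"]),
                trend_pvalue=trend_pvalues.get(gid),
                erv_families=erv.get(gid, ()),
            )
        )

    # ---------------- recovery metrics against the planted truth
    true_pegs = set(truth.index[truth["is_peg"]])
    true_transient = set(truth.index[truth["transient"]])
    recovered_transient = {r.gene_id for r in records if r.transient == "transient"}
    correct_loss = {
        r.gene_id
        for r in records
        if r.transient == "transient"
        and r.expression_loss_stage == truth.loc[r.gene_id, "loss_stage"]
    }
    chip_assessable = {
        r.gene_id
        for r in records
        if r.transient == "transient"
        and any(d == "paternal" for d in (enrich[r.gene_id][s].direction for s in enrich[r.gene_id]))
    }
    coincident = {r.gene_id for r in records if r.coincident_loss}

    summary = {
        "config": config.to_dict(),
        "n_genes": int(len(truth)),
        "n_true_pegs": int(len(true_pegs)),
        "n_true_transient": int(len(true_transient)),
        "n_candidates": int(len(candidates)),
        "n_confirmed": int(len(confirmed)),
        "n_validated": int(validation["validated_ap"].sum()),
        "confirmed_genes": sorted(confirmed),
        "sperm_consensus_size": int(len(sperm_consensus)),
        "peg_chip_overlap": {
            "n_overlap": chip_overlap["n_overlap"],
            "n_peg": chip_overlap["n_peg"],
            "fraction": chip_overlap["fraction"],
        },
        "confirmed_true_positive": int(len(confirmed & true_pegs)),
        "n_recovered_transient": int(len(recovered_transient & true_transient)),
        "transient_recovery_with_correct_loss": (
            len(correct_loss & true_transient) / len(true_transient) if true_transient else float("nan")
        ),
        "coincident_fraction_of_recovered": (
            len(coincident & recovered_transient & chip_assessable)
            / len(recovered_transient & chip_assessable)
            if recovered_transient & chip_assessable
            else float("nan")
        ),
        "stage_backgrounds_percent": {s: backgrounds[s].percent for s in CHIP_STAGES},
    }

    if out is not None:
        io.write_genome(genome, out / "genome")
        io.write_snps(snps, out / "snps.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t")
        io.write_peaks(icm_peaks, out / "icm_peaks.broadPeak")
        chip_table.to_csv(out / "allelic_chip_stats.tsv", sep="\t", index=False)
        pd.Series(trend_pvalues, name="trend_pvalue").rename_axis("gene_id").to_csv(
            out / "chip_trend.tsv", sep="\t"
        )
        for stage in ZGA_STAGES:
            de1[stage].to_csv(out / f"de_reciprocal_{stage}.tsv", sep="\t")
        validation.to_csv(out / "validation_andro_partheno.tsv", sep="\t")
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            out / "integration_records.tsv", sep="\t", index=False
        )
        io.write_json(summary, out / "summary.json")
        logger.info("pipeline outputs written to %s", out)
    return summary
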