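"""Validation experiments: calibration, oracle-equivalence and recovery
measurements for every stage of the pipeline.

Each function regenerates its inputs from a seed, runs the package code
path under test, and measures the outcome against an independent oracle
(brute-force classifier, closed-form test, permutation null) or against
the planted simulation truth.  The analysis drivers, the test suite and
the acceptance script all call these functions.
"""

from __future__ import annotations

import json
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .allele import split_reads
from .chipstats import (
    RegionAllelicCounts,
    chisq_enrichment,
    stage_background,
    trend_test,
)
from .config import CROSSES, SimConfig
from .counts import simulate_allelic_counts
from .de import bh_fdr, call_candidates, nb_exact_test
from .genome import SnpMap, make_genome, make_truth
from .peaks import BinnedCoverage, call_broad_peaks
from .pipeline import run_pipeline
from .reads import ReadRecord
from .rng import substream

_BASES = "ACGT"


# ------------------------------------------------------------ allele assignment

def _oracle_assign(read: ReadRecord, snps: SnpMap) -> str:
    """Literal per-read brute-force classifier (independent of allele.py):
    tally parental matches observation by observation, then apply the
    label definition verbatim."""
    matches = []
    for pos, base in read.snp_obs:
        entry = snps.lookup(read.chrom, pos)
        if entry is None:
            continue
        pat_base, mat_base = entry
        if base == pat_base:
            matches.append("P")
        if base == mat_base:
            matches.append("M")
    has_p = "P" in matches
    has_m = "M" in matches
    if has_p and has_m:
        return "other"  # conflicting
    if has_p:
        return "paternal"
    if has_m:
        return "maternal"
    return "other"  # unassignable (no covered SNP / no parental match)


def make_random_reads(seed: int, n_reads: int) -> tuple[list[ReadRecord], SnpMap]:
    """Random reads over a random SNP map, with observations that may hit
    SNP positions (paternal, maternal or junk base) or non-SNP positions."""
    rng = substream(seed, "oracle-reads")
    chroms = ["chr1", "chr2"]
    rows = []
    for chrom in chroms:
        pos = np.sort(rng.choice(100_000, size=800, replace=False))
        pat = rng.integers(0, 4, size=pos.size)
        mat = (pat + rng.integers(1, 4, size=pos.size)) % 4
        for p, a, b in zip(pos, pat, mat):
            rows.append((chrom, int(p), _BASES[a], _BASES[b]))
    snps = SnpMap(pd.DataFrame(rows, columns=["chrom", "pos", "pat_base", "mat_base"]))
    reads = []
    for i in range(n_reads):
        chrom = chroms[int(rng.integers(0, 2))]
        start = int(rng.integers(0, 99_800))
        end = start + 100
        n_obs = int(rng.integers(0, 4))
        obs = []
        in_read = snps.in_interval(chrom, start, end)
        for _ in range(n_obs):
            if in_read.size and rng.random() < 0.7:
                pos = int(rng.choice(in_read))
            else:
                pos = int(rng.integers(start, end))  # may or may not be a SNP
            obs.append((pos, _BASES[int(rng.integers(0, 4))]))
        reads.append(
            ReadRecord(
                read_id=f"r{i}", chrom=chrom, start=start, end=end, strand="+",
                mapq=60, snp_obs=tuple(obs),
            )
        )
    return reads, snps


def assign_oracle_check(seed: int, n_reads: int = 10_000) -> dict:
    """split_reads vs the brute-force per-read oracle, exact agreement."""
    reads, snps = make_random_reads(seed, n_reads)
    parts, summary = split_reads(reads, snps)
    impl = {}
    for label, rs in parts.items():
        for r in rs:
            impl[r.read_id] = label
    mismatches = sum(1 for r in reads if impl[r.read_id] != _oracle_assign(r, snps))
    assert summary["n_total"] == n_reads
    return {"n": n_reads, "n_mismatch": mismatches, "agreement": 1.0 - mismatches / n_reads}


# ------------------------------------------------------------ chi-square screen

def chisq_null_calibration(
    seed: int, n_genes: int = 5000, p_true: float = 0.55, alpha: float = 0.05
) -> dict:
    """Rejection rate of the chi-square enrichment screen on null genes
    whose counts are drawn at the stage's global skew."""
    rng = substream(seed, "chisq-null")
    n = rng.integers(50, 501, size=n_genes)
    x = rng.binomial(n, p_true)
    bg = stage_background(int(x.sum()), int((n - x).sum()), stage="null")
    rejections = 0
    for i in range(n_genes):
        counts = RegionAllelicCounts(
            gene_id=f"g{i}", chrom="chr1", start=0, end=1000, stage="null",
            n_pat=int(x[i]), n_mat=int(n[i] - x[i]),
        )
        res = chisq_enrichment(counts, bg, alpha=alpha)
        if res.pvalue < alpha:
            rejections += 1
    return {"n": n_genes, "rejection_rate": rejections / n_genes, "p0_hat": bg.p0}


# ------------------------------------------------------------ trend test

def _two_proportion_z_pvalue(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-proportion z-test (closed form, independent of chipstats)."""
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p2 - p1) / se
    return 2.0 * stats.norm.sf(abs(z))


def trend_two_stage_equivalence(seed: int, n_tables: int = 200) -> dict:
    """With exactly two stages the CA trend p must equal the pooled
    two-proportion z-test p; reports the maximum absolute difference."""
    rng = substream(seed, "trend-2stage")
    max_diff = 0.0
    for _ in range(n_tables):
        n1, n2 = rng.integers(30, 500, size=2)
        p = rng.uniform(0.2, 0.8)
        x1, x2 = rng.binomial([n1, n2], [p, rng.uniform(0.2, 0.8)])
        x1 = min(max(int(x1), 1), int(n1) - 1)
        x2 = min(max(int(x2), 1), int(n2) - 1)
        res = trend_test([("a", x1, int(n1) - x1), ("b", x2, int(n2) - x2)])
        ref = _two_proportion_z_pvalue(x1, int(n1), x2, int(n2))
        max_diff = max(max_diff, abs(res.pvalue - ref))
    return {"n": n_tables, "max_abs_diff": max_diff}


def trend_null_calibration(
    seed: int, n_genes: int = 5000, n_stages: int = 5, n_per_stage: int = 200,
    p_true: float = 0.55, alpha: float = 0.05,
) -> dict:
    """Two-sided CA rejection rate under a constant-proportion null."""
    rng = substream(seed, "trend-null")
    rejections = 0
    for _ in range(n_genes):
        x = rng.binomial(n_per_stage, p_true, size=n_stages)
        series = [(f"s{j}", int(x[j]), n_per_stage - int(x[j])) for j in range(n_stages)]
        if trend_test(series).pvalue < alpha:
            rejections += 1
    return {"n": n_genes, "rejection_rate": rejections / n_genes}


def fixed_trend_tables(n_tables: int = 20, n_per_stage: int = 400, n_stages: int = 5):
    """Deterministic tables with declining paternal proportions of graded
    strength (from borderline to strongly significant trends)."""
    tables = []
    for i, delta in enumerate(np.linspace(0.013, 0.05, n_tables)):
        props = 0.62 - delta * np.arange(n_stages)
        x = np.round(n_per_stage * props).astype(int)
        tables.append([(f"s{j}", int(x[j]), n_per_stage - int(x[j])) for j in range(n_stages)])
    return tables


def trend_permutation_check(seed: int, n_perm: int = 10_000) -> dict:
    """Asymptotic CA p vs a Monte-Carlo permutation null on fixed tables.

    The permutation null conditions on both margins: successes are
    redistributed over stages by a multivariate hypergeometric draw,
    which is exactly the label-permutation distribution.
    """
    rng = substream(seed, "trend-perm")
    max_diff = 0.0
    diffs = []
    for table in fixed_trend_tables():
        n_pat = np.array([r[1] for r in table])
        n_tot = np.array([r[1] + r[2] for r in table])
        res = trend_test(table)
        z_obs = abs(res.statistic)
        total_succ = int(n_pat.sum())
        draws = rng.multivariate_hypergeometric(n_tot, total_succ, size=n_perm)
        # the CA z of each permuted table: margins (and hence pbar and the
        # variance term) are permutation-invariant, so z is linear in the draw
        s = np.arange(len(n_tot), dtype=float)
        N = n_tot.sum()
        pbar = total_succ / N
        var = pbar * (1 - pbar) * (np.sum(n_tot * s**2) - np.sum(n_tot * s) ** 2 / N)
        zs = (draws @ s - pbar * np.sum(s * n_tot)) / math.sqrt(var)
        p_perm = float(np.mean(np.abs(zs) >= z_obs - 1e-12))
        diffs.append(abs(p_perm - res.pvalue))
        max_diff = max(max_diff, diffs[-1])
    return {"n": len(diffs), "max_abs_diff": max_diff, "diffs": diffs}


# ------------------------------------------------------------ BH-FDR

def _bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Textbook step-up, O(n^2): q_i = min over j with p_j >= p_i of
    (n * p_j / rank_j), capped at 1."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for idx_rank, i in enumerate(order):
        best = 1.0
        for jdx_rank, j in enumerate(order):
            if jdx_rank >= idx_rank:
                best = min(best, p[j] * n / (jdx_rank + 1))
        q[i] = best
    return q


def bh_check(seed: int, n_vectors: int = 1000, max_len: int = 50) -> dict:
    """bh_fdr vs the brute-force step-up, exact equality; includes the
    worked vector [0.01, 0.02, 0.03, 0.04] -> all 0.04."""
    rng = substream(seed, "bh")
    n_mismatch = 0
    for _ in range(n_vectors):
        k = int(rng.integers(1, max_len + 1))
        p = rng.random(k)
        if rng.random() < 0.2:  # exercise ties
            p = np.round(p, 2)
        if not np.array_equal(bh_fdr(p), _bh_bruteforce(p)):
            n_mismatch += 1
    worked = bh_fdr([0.01, 0.02, 0.03, 0.04])
    worked_ok = np.allclose(worked, [0.04, 0.04, 0.04, 0.04])
    return {"n": n_vectors, "n_mismatch": n_mismatch, "worked_vector_ok": bool(worked_ok)}


# ------------------------------------------------------------ NB exact test

def _count_matrix(rng, n_genes, n_a, n_b, mean_a, mean_b, dispersion):
    from .counts import AllelicCountMatrix, _nb_draw

    cols = {}
    meta = []
    for j in range(n_a):
        sid = f"a{j}"
        cols[sid] = _nb_draw(rng, np.full(n_genes, mean_a, dtype=float)
                             if np.isscalar(mean_a) else mean_a, dispersion)
        meta.append({"sample": sid, "allele": "paternal", "replicate": j})
    for j in range(n_b):
        sid = f"b{j}"
        cols[sid] = _nb_draw(rng, np.full(n_genes, mean_b, dtype=float)
                             if np.isscalar(mean_b) else mean_b, dispersion)
        meta.append({"sample": sid, "allele": "maternal", "replicate": j})
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    samples = pd.DataFrame(meta).set_index("sample")
    return AllelicCountMatrix(counts, samples)


def nb_binomial_limit_check(seed: int, n_genes: int = 1000) -> dict:
    """At dispersion 0 with equal libraries the exact NB p-value must match
    an exact binomial test of the group-A pseudo-count sum."""
    rng = substream(seed, "nb-limit")
    mat = _count_matrix(rng, n_genes, 4, 4, 100.0, 100.0, dispersion=0.0)
    de = nb_exact_test(mat, dispersion=0.0)
    max_dlog10 = 0.0
    for g in de.index:
        a, b = int(de.loc[g, "sum_a"]), int(de.loc[g, "sum_b"])
        ref = stats.binomtest(a, a + b, 4 / 8).pvalue
        d = abs(math.log10(max(de.loc[g, "pvalue"], 1e-300)) - math.log10(max(ref, 1e-300)))
        max_dlog10 = max(max_dlog10, d)
    return {"n": n_genes, "max_abs_dlog10_p": max_dlog10}


def nb_effect_recovery(
    seed: int, n_genes: int = 1000, n_planted: int = 100, effect: float = 5.0, depth: float = 500.0
) -> dict:
    """Planted log2FC recovery: paternal mean = 2^effect x maternal mean
    at ``n_planted`` genes among an otherwise balanced background (the
    background anchors the library-size normalization, as in real data)."""
    rng = substream(seed, "nb-recovery")
    share = 2.0**effect / (1.0 + 2.0**effect)
    mean_a = np.full(n_genes, depth / 2.0)
    mean_b = np.full(n_genes, depth / 2.0)
    mean_a[:n_planted] = depth * share
    mean_b[:n_planted] = depth * (1 - share)
    mat = _count_matrix(rng, n_genes, 4, 4, mean_a, mean_b, dispersion=0.1)
    de = nb_exact_test(mat)
    mean_lfc = float(de["log2fc"].iloc[:n_planted].mean())
    return {"n": n_planted, "mean_log2fc": mean_lfc, "abs_error": abs(mean_lfc - effect)}


# ------------------------------------------------------------ PEG calling OC

def peg_operating_characteristics(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 2000,
    n_peg: int = 60,
    effect: float = 5.0,
    depth: float = 500.0,
    dispersion: float = 0.1,
) -> dict:
    """Sensitivity and false-discovery proportion of the candidate rule
    (log2FC > 3, FDR < 0.001) with planted PEGs among null genes,
    2 replicates x 2 crosses, averaged over seeds."""
    sens, fdp = [], []
    for k in range(n_seeds):
        config = SimConfig(
            seed=int(substream(seed, "peg-oc", k).integers(0, 2**31 - 1)),
            n_chromosomes=2,
            genes_per_chromosome=n_genes // 2,
            peg_fraction=n_peg / n_genes,
            transient_fraction=0.0,
            effect_log2=effect,
            rna_mean_expression=depth,
            nb_dispersion=dispersion,
        )
        genome = make_genome(config)
        truth = make_truth(genome, config)
        mat = simulate_allelic_counts(
            genome, truth,
            {"stages": ["late2c"], "crosses": list(CROSSES), "replicates": 2},
            config,
        )
        de = nb_exact_test(mat)
        called = call_candidates(de)
        true_pegs = set(truth.index[truth["is_peg"]])
        sens.append(len(called & true_pegs) / len(true_pegs))
        fdp.append(len(called - true_pegs) / max(len(called), 1))
    return {
        "n": n_seeds,
        "sensitivity": float(np.mean(sens)),
        "false_discovery_proportion": float(np.mean(fdp)),
    }


# ------------------------------------------------------------ peak caller

def _poisson_coverage(rng, n_bins: int, lam_per_bin: np.ndarray) -> BinnedCoverage:
    x = rng.poisson(lam_per_bin)
    return BinnedCoverage(
        bins={"chr1": x}, bin_width=10, total_reads=int(x.sum()), starts={"chr1": x}
    )


def peak_null_check(seed: int, n_runs: int = 100, n_bins: int = 10_000, rate: float = 1.5) -> dict:
    """Fraction of pure-background runs yielding zero peaks at q <= 0.05."""
    rng = substream(seed, "peak-null")
    zero = 0
    for _ in range(n_runs):
        cov = _poisson_coverage(rng, n_bins, np.full(n_bins, rate))
        if not call_broad_peaks(cov, None, q_cutoff=0.05):
            zero += 1
    return {"n": n_runs, "zero_peak_fraction": zero / n_runs}


def peak_recovery_check(
    seed: int, n_runs: int = 100, n_bins: int = 10_000, rate: float = 1.5, fold: float = 10.0
) -> dict:
    """Recovery of one planted 2-kb domain at ``fold`` x background:
    fraction of runs with exactly one peak at interval Jaccard >= 0.8."""
    rng = substream(seed, "peak-recovery")
    lam = np.full(n_bins, rate)
    lo_bin, hi_bin = 4000, 4200  # 2 kb on the 10-bp grid
    lam[lo_bin:hi_bin] = rate * fold
    planted = (lo_bin * 10, hi_bin * 10)
    ok = 0
    jaccards = []
    for _ in range(n_runs):
        cov = _poisson_coverage(rng, n_bins, lam)
        peaks = call_broad_peaks(cov, None, q_cutoff=0.05)
        if len(peaks) == 1:
            p = peaks[0]
            inter = max(0, min(p.end, planted[1]) - max(p.start, planted[0]))
            union = (p.end - p.start) + (planted[1] - planted[0]) - inter
            j = inter / union
            jaccards.append(j)
            if j >= 0.8:
                ok += 1
    return {"n": n_runs, "recovered_fraction": ok / n_runs,
            "mean_jaccard": float(np.mean(jaccards)) if jaccards else 0.0}


# ------------------------------------------------------------ end to end

def end_to_end_check(seed: int, config: SimConfig | None = None, check_determinism: bool = True) -> dict:
    """Run the full pipeline on the default planted-truth configuration;
    report transient-PEG recovery (with correct loss stage), loss-stage
    coincidence, and whether a repeated run gives an identical summary."""
    if config is None:
        config = SimConfig(seed=int(substream(seed, "e2e").integers(0, 2**31 - 1)))
    summary = run_pipeline(config)
    identical = True
    if check_determinism:
        summary2 = run_pipeline(config)
        identical = json.dumps(summary, sort_keys=True, default=str) == json.dumps(
            summary2, sort_keys=True, default=str
        )
    return {
        "n": summary["n_true_transient"],
        "transient_recovery_with_correct_loss": summary["transient_recovery_with_correct_loss"],
        "coincident_fraction_of_recovered": summary["coincident_fraction_of_recovered"],
        "n_confirmed": summary["n_confirmed"],
        "n_true_pegs": summary["n_true_pegs"],
        "confirmed_true_positive": summary["confirmed_true_positive"],
        "deterministic": identical,
    }
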