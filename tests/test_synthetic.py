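"""Synthetic-data generator: determinism, planted-truth invariants, and
the statistical properties of simulated reads and counts."""

import numpy as np
import pytest

from pegtrace.config import CROSSES, ConfigurationError, SimConfig
from pegtrace.counts import simulate_allelic_counts, simulate_group_counts
from pegtrace.genome import make_genome, make_snp_map, make_truth
from pegtrace.reads import simulate_chip_reads, skewed_fraction


def test_genome_deterministic_and_well_formed(small_config, genome):
    again = make_genome(small_config)
    assert [g.__dict__ for g in again.genes] == [g.__dict__ for g in genome.genes]
    # promoters non-overlapping and inside chromosome bounds
    by_chrom = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append((g.promoter_start, g.promoter_end))
    for chrom, intervals in by_chrom.items():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2


def test_zero_genes_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        SimConfig(genes_per_chromosome=0)


def test_snp_density_poisson_mean(genome, small_config):
    density = 0.001  # 1 per kb
    sizes = [len(make_snp_map(genome, density, seed)) for seed in range(60)]
    expected = density * genome.size
    sd_of_mean = np.sqrt(expected / len(sizes))
    assert abs(np.mean(sizes) - expected) < 3 * sd_of_mean


def test_snp_map_invariants(snps, genome):
    assert (snps.table["pat_base"] != snps.table["mat_base"]).all()
    assert not snps.table.duplicated(["chrom", "pos"]).any()
    with pytest.raises(ConfigurationError):
        make_snp_map(genome, -1.0, 0)


def test_chip_reads_deterministic_and_conserved(genome, snps, truth, small_config):
    r1 = simulate_chip_reads(genome, snps, truth, "PN5", small_config)
    r2 = simulate_chip_reads(genome, snps, truth, "PN5", small_config)
    assert [a.__dict__ for a in r1] == [a.__dict__ for a in r2]
    assert all(r.true_allele in ("paternal", "maternal") for r in r1)


def test_unknown_stage_rejected(genome, snps, truth, small_config):
    with pytest.raises(ValueError, match="unknown stage"):
        simulate_chip_reads(genome, snps, truth, "morula", small_config)


def test_zero_depth_gives_no_reads(genome, snps, truth, small_config):
    cfg = small_config.replace(chip_promoter_depth=0.0, chip_background_rate=0.0)
    assert simulate_chip_reads(genome, snps, truth, "PN5", cfg) == []


def test_enriched_promoter_is_predominantly_paternal(genome, snps, truth, small_config):
    """At a fully skewed promoter the hidden paternal fraction follows the
    configured fold (>= 95% at the default fold of 50)."""
    pegs = truth.index[truth["is_peg"] & truth["sperm_h3k4me3"]]
    assert len(pegs) > 0
    reads = simulate_chip_reads(genome, snps, truth, "PN5", small_config)
    gene = genome.gene(pegs[0])
    over = [
        r for r in reads
        if r.chrom == gene.chrom and r.start < gene.promoter_end and r.end > gene.promoter_start
    ]
    frac = np.mean([r.true_allele == "paternal" for r in over])
    assert frac >= 0.95
    assert skewed_fraction(0.5, 50.0) == pytest.approx(50 / 51)


def test_null_genome_follows_global_fraction():
    cfg = SimConfig(seed=3, genes_per_chromosome=40, peg_fraction=0.0)
    g = make_genome(cfg)
    s = make_snp_map(g, cfg.snp_density, cfg.seed)
    t = make_truth(g, cfg)
    fracs = []
    for seed in range(10):
        reads = simulate_chip_reads(g, s, t, "4c", cfg.replace(seed=seed))
        fracs.append(np.mean([r.true_allele == "paternal" for r in reads]))
    p0 = cfg.global_paternal_fraction["4c"]
    n = 8000  # reads per run, conservative lower bound
    assert abs(np.mean(fracs) - p0) < 3 * np.sqrt(p0 * (1 - p0) / (len(fracs) * n))


def test_truth_invariants(truth):
    assert (truth.loc[~truth["is_peg"], "effect"] == 0).all()
    trans = truth[truth["transient"]]
    assert (trans["loss_stage"].isin(["8c", "ICM"])).all()
    assert trans["is_peg"].all()


def test_allelic_counts_effect_recovered_in_both_crosses(genome, truth, small_config):
    """Planted log2 effect of 5 gives a paternal/maternal mean ratio of
    ~32 in both cross directions (tied to parent, not strain)."""
    mat = simulate_allelic_counts(
        genome, truth, {"stages": ["early2c"], "crosses": list(CROSSES), "replicates": 6},
        small_config,
    )
    pegs = truth.index[truth["is_peg"]]
    for cross in CROSSES:
        sel = mat.samples["cross"] == cross
        pat_cols = mat.samples.index[sel & (mat.samples["allele"] == "paternal")]
        mat_cols = mat.samples.index[sel & (mat.samples["allele"] == "maternal")]
        ratio = mat.counts.loc[pegs, pat_cols].mean(axis=1).sum() / mat.counts.loc[
            pegs, mat_cols
        ].mean(axis=1).sum()
        assert ratio == pytest.approx(32.0, rel=0.2)


def test_zero_dispersion_counts_are_poisson(genome, truth, small_config):
    cfg = small_config.replace(nb_dispersion=0.0, peg_fraction=0.0, libsize_sigma=0.0)
    t = make_truth(genome, cfg)
    mat = simulate_allelic_counts(
        genome, t, {"stages": ["4c"], "crosses": [CROSSES[0]], "replicates": 30}, cfg
    )
    cols = mat.samples.index[mat.samples["allele"] == "paternal"]
    sub = mat.counts[cols].to_numpy(dtype=float)
    vmr = sub.var(axis=1, ddof=1) / sub.mean(axis=1)
    assert np.median(vmr) == pytest.approx(1.0, abs=0.25)


def test_empty_design_rejected(genome, truth, small_config):
    with pytest.raises(ValueError):
        simulate_allelic_counts(genome, truth, {"stages": []}, small_config)


def test_group_counts_ratios_and_amanitin(genome, small_config):
    cfg = small_config.replace(effect_log2=2.0, transient_fraction=0.0, libsize_sigma=0.0)
    t = make_truth(genome, cfg)
    mat = simulate_group_counts(
        genome, t, ("androgenote", "parthenogenote", "amanitin"), cfg.replace(n_replicates=8)
    )
    andro = mat.counts[mat.samples.index[mat.samples["group"] == "androgenote"]].mean(axis=1)
    parth = mat.counts[mat.samples.index[mat.samples["group"] == "parthenogenote"]].mean(axis=1)
    am = mat.counts[mat.samples.index[mat.samples["group"] == "amanitin"]].mean(axis=1)
    pegs = t.index[t["is_peg"]]
    nonpeg = t.index[~t["is_peg"]]
    assert andro[pegs].sum() / parth[pegs].sum() == pytest.approx(4.0, rel=0.25)
    assert andro[nonpeg].sum() / parth[nonpeg].sum() == pytest.approx(1.0, rel=0.15)
    silent = t.index[~t["expressed_pre_zga"]]
    assert am[silent].mean() < 1.0


def test_unknown_group_rejected(genome, truth, small_config):
    with pytest.raises(ValueError, match="unknown group"):
        simulate_group_counts(genome, truth, ("gynogenote",), small_config)
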