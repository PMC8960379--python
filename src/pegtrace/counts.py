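"""Allelic RNA count simulation (negative-binomial, reciprocal crosses)
and uniparental/amanitin control groups.

Counts are gene x sample matrices with sample metadata.  For a true PEG
the paternal mean is ``2**effect`` times the maternal mean in BOTH cross
directions: the effect is tied to parent of origin, not to strain.
Library-size factors are shared between the paternal and maternal
columns derived from the same biological sample (one library).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CHIP_STAGES, CROSSES, SimConfig
from .genome import GenomeModel, imprinted_at
from .rng import substream

GROUPS = ("androgenote", "parthenogenote", "amanitin")
GROUP_STAGE = "late2c"  # uniparental embryos are collected at the two-cell stage


@dataclass
class AllelicCountMatrix:
    """Genes x samples integer counts plus per-sample metadata."""

    counts: pd.DataFrame  # index: gene_id, columns: sample ids
    samples: pd.DataFrame  # index: sample ids; metadata columns

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata must align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def subset(self, mask: pd.Series) -> "AllelicCountMatrix":
        cols = self.samples.index[mask]
        return AllelicCountMatrix(self.counts[cols], self.samples.loc[cols])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def _base_means(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    sigma = config.rna_lognorm_sigma
    # mean-preserving lognormal spread around rna_mean_expression
    return config.rna_mean_expression * rng.lognormal(-0.5 * sigma**2, sigma, size=n)


def _paternal_share(truth_row: pd.Series, stage: str) -> float:
    if imprinted_at(truth_row, stage, CHIP_STAGES):
        r = 2.0 ** truth_row["effect"]
        return r / (1.0 + r)
    return 0.5


def simulate_allelic_counts(
    genome: GenomeModel,
    truth: pd.DataFrame,
    design: dict,
    config: SimConfig,
    dataset: int = 0,
) -> AllelicCountMatrix:
    """Simulate an allelic count matrix for a stages x crosses x replicates design.

    ``design`` maps ``stages`` -> list of stage names, ``crosses`` -> list of
    cross labels, ``replicates`` -> int.  Each (stage, cross, replicate)
    is one biological sample contributing a paternal and a maternal column.
    """
    stages = list(design.get("stages", []))
    crosses = list(design.get("crosses", CROSSES))
    n_rep = int(design.get("replicates", config.n_replicates))
    if not stages or n_rep < 1 or not crosses:
        raise ValueError("design needs >=1 stage, >=1 cross and >=1 replicate")
    rng = substream(config.seed, "rna", dataset)
    genes = truth.index.to_numpy()
    mu = _base_means(rng, len(genes), config)

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for stage in stages:
        share = np.array([_paternal_share(truth.loc[g], stage) for g in genes])
        for cross in crosses:
            for rep in range(1, n_rep + 1):
                lib = rng.lognormal(-0.5 * config.libsize_sigma**2, config.libsize_sigma)
                # gene total ~ NB (Gamma-Poisson), then a binomial allelic
                # split: both allele columns come from ONE library, so each
                # is marginally NB(mean, dispersion) but the allelic ratio
                # carries only binomial sampling noise, as in real data
                mean = mu * lib
                if config.nb_dispersion > 0:
                    size = 1.0 / config.nb_dispersion
                    lam = rng.gamma(size, mean * config.nb_dispersion)
                else:
                    lam = mean
                total = rng.poisson(lam)
                pat = rng.binomial(total, share)
                for allele, vals in (("paternal", pat), ("maternal", total - pat)):
                    sid = f"{stage}_{cross}_r{rep}_{allele}"
                    cols[sid] = vals.astype(np.int64)
                    meta.append(
                        {"sample": sid, "stage": stage, "cross": cross,
                         "replicate": rep, "allele": allele}
                    )
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(meta).set_index("sample")
    return AllelicCountMatrix(counts, samples)


def simulate_group_counts(
    genome: GenomeModel,
    truth: pd.DataFrame,
    groups,
    config: SimConfig,
    dataset: int = 0,
    amanitin_residual: float = 0.05,
) -> AllelicCountMatrix:
    """Simulate androgenote / parthenogenote / amanitin two-cell counts.

    Androgenotes carry two paternal genomes (mean = 2x the paternal-allele
    mean), parthenogenotes two maternal genomes; amanitin-treated embryos
    are transcriptionally blocked, so only genes with a maternal transcript
    deposit (``expressed_pre_zga``) show counts.
    """
    groups = list(groups)
    for g in groups:
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
    rng = substream(config.seed, "groups", dataset)
    genes = truth.index.to_numpy()
    mu = _base_means(rng, len(genes), config)
    share = np.array([_paternal_share(truth.loc[g], GROUP_STAGE) for g in genes])
    pre_zga = truth["expressed_pre_zga"].to_numpy()

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for group in groups:
        for rep in range(1, config.n_replicates + 1):
            lib = rng.lognormal(-0.5 * config.libsize_sigma**2, config.libsize_sigma)
            if group == "androgenote":
                mean = 2.0 * mu * share * lib
            elif group == "parthenogenote":
                mean = 2.0 * mu * (1.0 - share) * lib
            else:  # amanitin
                mean = np.where(pre_zga, mu * lib, amanitin_residual)
            sid = f"{group}_r{rep}"
            cols[sid] = _nb_draw(rng, mean, config.nb_dispersion)
            meta.append({"sample": sid, "group": group, "replicate": rep, "stage": GROUP_STAGE})
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(meta).set_index("sample")
    return AllelicCountMatrix(counts, samples)
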