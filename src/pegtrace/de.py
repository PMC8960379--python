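"""Negative-binomial allelic differential expression and staged PEG calling.

The test is a two-group exact negative-binomial test on library-size-
equalized pseudo-counts, conditioning on the per-gene total (the
Robinson-Smyth exact-test idea): under the null both group sums follow
NB distributions with a shared per-sample mean, and the two-sided
p-value sums the conditional probabilities of outcomes no more likely
than the observed split.  At dispersion zero this reduces to an exact
binomial test of the paternal sum.

The staged decision rules: reciprocal-cross candidates (log2FC > 3 and
FDR < 0.001, cross directions agreeing in sign), confirmation in an
independent dataset at the same thresholds, then androgenote vs
parthenogenote validation (log2FC > 1, FDR < 0.1) with an
amanitin-treated control flagging maternal-carryover transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .counts import AllelicCountMatrix


# ---------------------------------------------------------------- normalization

def normalize_libsize(counts: pd.DataFrame, trim: float = 0.3) -> pd.Series:
    """Per-sample scaling factors from 30%-trimmed-mean library totals,
    rescaled so the factors' geometric mean is 1."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    tm = np.array([stats.trim_mean(counts[c].to_numpy(), trim) for c in counts.columns])
    # heavily zero-inflated samples can trim to zero; fall back to the plain mean
    fallback = counts.mean(axis=0).to_numpy()
    tm = np.where(tm > 0, tm, fallback)
    log_tm = np.log(tm)
    factors = np.exp(log_tm - log_tm.mean())
    return pd.Series(factors, index=counts.columns, name="norm_factor")


@dataclass
class DispersionEstimate:
    common: float
    per_gene: pd.Series


def estimate_dispersion(
    matrix: AllelicCountMatrix,
    group_cols: tuple[str, ...] = ("allele",),
    shrink: float = 0.5,
    fallback_common: float = 0.1,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion per gene, shrunk toward the common
    (20%-trimmed mean) value.

    Within each condition (the distinct combinations of ``group_cols``)
    with >= 2 replicates, phi = (var - mean) / mean^2 on normalized
    counts; per-gene estimates pool conditions weighted by their degrees
    of freedom and are clamped at zero.  With no replicated condition
    the common fallback is returned with a warning.
    """
    counts, samples = matrix.counts, matrix.samples
    factors = normalize_libsize(counts)
    norm = counts / factors
    keys = samples[list(group_cols)].apply(tuple, axis=1)
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    any_replicated = False
    for _, cols in keys.groupby(keys).groups.items():
        if len(cols) < 2:
            continue
        any_replicated = True
        sub = norm[list(cols)].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / m**2, np.nan)
        w = len(cols) - 1
        ok = np.isfinite(phi)
        num[ok] += w * phi[ok]
        den[ok] += w
    if not any_replicated:
        warnings.warn(
            "no condition has >= 2 replicates; returning the common fallback dispersion",
            stacklevel=2,
        )
        per_gene = pd.Series(fallback_common, index=counts.index, name="dispersion")
        return DispersionEstimate(common=fallback_common, per_gene=per_gene)
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    finite = raw[np.isfinite(raw)]
    common = float(max(stats.trim_mean(np.clip(finite, 0, None), 0.2), 0.0)) if finite.size else fallback_common
    shrunk = np.where(np.isfinite(raw), (1 - shrink) * raw + shrink * common, common)
    per_gene = pd.Series(np.clip(shrunk, 0.0, None), index=counts.index, name="dispersion")
    return DispersionEstimate(common=common, per_gene=per_gene)


# ---------------------------------------------------------------- exact test

def _exact_conditional_pvalue(a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional p-value of observing group-A sum ``a`` out of
    total ``t`` given group sizes (n_a, n_b) and NB dispersion ``phi``."""
    if t == 0:
        return 1.0
    ks = np.arange(t + 1)
    if phi < 1e-8:
        # Poisson limit: conditional law is binomial(t, n_a / (n_a + n_b))
        logf = stats.binom.logpmf(ks, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)  # per-sample null mean on the pseudo-count scale
        r_a, r_b = n_a / phi, n_b / phi
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logf = stats.nbinom.logpmf(ks, r_a, p_a) + stats.nbinom.logpmf(t - ks, r_b, p_b)
        logf = logf - logsumexp(logf)
    mask = logf <= logf[a] + 1e-9
    return float(min(1.0, np.exp(logsumexp(logf[mask]))))


def nb_exact_test(
    matrix: AllelicCountMatrix,
    contrast: tuple[str, str] = ("paternal", "maternal"),
    column: str = "allele",
    dispersion: float | pd.Series | None = None,
    min_total: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Exact NB two-group test per gene (contrast[0] over contrast[1]).

    Returns a DataFrame indexed by gene with columns log2fc, pvalue, fdr,
    mean_expr, low_expression and (when a binary ``cross`` column is
    present) cross_consistent — True when the per-cross log2FCs agree in
    sign, the reciprocal-cross requirement that separates parent-of-origin
    effects from strain effects.

    Genes with total pseudo-count below ``min_total`` are flagged
    low-expression, get p = 1 and are excluded from the BH correction.
    """
    counts, samples = matrix.counts, matrix.samples
    if column not in samples.columns:
        raise ValueError(f"sample metadata lacks column {column!r}")
    group_a = samples.index[samples[column] == contrast[0]]
    group_b = samples.index[samples[column] == contrast[1]]
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError(f"contrast groups {contrast} not found in column {column!r}")

    factors = normalize_libsize(counts)
    norm = counts / factors
    pseudo = (norm.round()).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_dispersion(matrix, group_cols=(column,)).per_gene
    if np.isscalar(dispersion):
        phi = pd.Series(float(dispersion), index=counts.index)
    else:
        phi = dispersion.reindex(counts.index)

    a_sum = pseudo[group_a].sum(axis=1)
    b_sum = pseudo[group_b].sum(axis=1)
    totals = a_sum + b_sum
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    low = totals < min_total

    pvals = np.ones(len(counts))
    for i, g in enumerate(counts.index):
        if low.iloc[i]:
            continue
        pvals[i] = _exact_conditional_pvalue(
            int(a_sum.iloc[i]), int(totals.iloc[i]), len(group_a), len(group_b), float(phi.iloc[i])
        )

    fdr = np.ones(len(counts))
    tested = ~low.to_numpy()
    if tested.any():
        fdr[tested] = bh_fdr(pvals[tested])

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_expr": (mean_a + mean_b) / 2.0,
            "low_expression": low,
            "sum_a": a_sum,  # equalized pseudo-count group sums (the
            "sum_b": b_sum,  # sufficient statistics of the exact test)
        },
        index=counts.index,
    )
    out.loc[totals == 0, "log2fc"] = 0.0

    if "cross" in samples.columns:
        crosses = sorted(samples["cross"].unique())
        if len(crosses) == 2:
            per_cross_fc = []
            for cr in crosses:
                ca = [s for s in group_a if samples.loc[s, "cross"] == cr]
                cb = [s for s in group_b if samples.loc[s, "cross"] == cr]
                fc = np.log2((norm[ca].mean(axis=1) + pseudocount) / (norm[cb].mean(axis=1) + pseudocount))
                per_cross_fc.append(fc)
            out["cross_consistent"] = (per_cross_fc[0] * per_cross_fc[1] >= 0)
    return out


# ---------------------------------------------------------------- FDR & decisions

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def call_candidates(de: pd.DataFrame, lfc_min: float = 3.0, fdr_max: float = 0.001) -> set[str]:
    """PEG candidates: log2FC > lfc_min (strict, paternal direction) and
    FDR < fdr_max (strict), excluding low-expression and cross-inconsistent genes."""
    mask = (de["log2fc"] > lfc_min) & (de["fdr"] < fdr_max) & ~de["low_expression"]
    if "cross_consistent" in de.columns:
        mask &= de["cross_consistent"]
    return set(de.index[mask])


def confirm_candidates(
    candidates: set[str],
    de_second: pd.DataFrame,
    lfc_min: float = 3.0,
    fdr_max: float = 0.001,
) -> set[str]:
    """Candidates also passing the same thresholds in an independent
    second dataset; genes absent from the second dataset stay unconfirmed."""
    second_pass = call_candidates(de_second, lfc_min=lfc_min, fdr_max=fdr_max)
    return {g for g in candidates if g in de_second.index and g in second_pass}


def validate_andro_partheno(
    genes,
    group_matrix: AllelicCountMatrix,
    lfc_min: float = 1.0,
    fdr_max: float = 0.1,
    amanitin_floor: float = 5.0,
    dispersion: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Uniparental-embryo validation of PEG calls.

    validated_ap: androgenote-over-parthenogenote log2FC > lfc_min with
    FDR < fdr_max.  expressed_pre_zga: mean normalized amanitin count
    above ``amanitin_floor`` (a maternal transcript deposit).  Genes
    expressed pre-ZGA whose uniparental comparison is biallelic are
    flagged carryover_confounded: their two-cell transcripts predate
    zygotic transcription, so the uniparental result is uninformative.
    """
    samples = group_matrix.samples
    if "group" not in samples.columns:
        raise ValueError("group matrix lacks a 'group' metadata column")
    present = set(samples["group"])
    for needed in ("androgenote", "parthenogenote", "amanitin"):
        if needed not in present:
            raise ValueError(f"missing group {needed!r}")
    ap = group_matrix.subset(samples["group"].isin(["androgenote", "parthenogenote"]))
    de = nb_exact_test(
        ap, contrast=("androgenote", "parthenogenote"), column="group", dispersion=dispersion
    )
    am_cols = samples.index[samples["group"] == "amanitin"]
    am_norm = group_matrix.counts[am_cols] / normalize_libsize(group_matrix.counts)[am_cols]
    am_mean = am_norm.mean(axis=1)

    genes = list(genes)
    validated = (de["log2fc"] > lfc_min) & (de["fdr"] < fdr_max)
    out = pd.DataFrame(
        {
            "validated_ap": validated.reindex(genes, fill_value=False),
            "ap_log2fc": de["log2fc"].reindex(genes),
            "ap_fdr": de["fdr"].reindex(genes),
            "expressed_pre_zga": (am_mean > amanitin_floor).reindex(genes, fill_value=False),
            "amanitin_mean": am_mean.reindex(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out["carryover_confounded"] = out["expressed_pre_zga"] & ~out["validated_ap"]
    return out
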