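"""Library normalization, dispersion estimation, the exact NB test, BH
correction and the staged PEG decision rules."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from pegtrace.counts import AllelicCountMatrix, simulate_group_counts
from pegtrace.de import (
    bh_fdr,
    call_candidates,
    confirm_candidates,
    estimate_dispersion,
    nb_exact_test,
    normalize_libsize,
    validate_andro_partheno,
)
from pegtrace.experiments import (
    _bh_bruteforce,
    nb_binomial_limit_check,
    nb_effect_recovery,
)
from pegtrace.genome import make_genome, make_truth
from pegtrace.rng import substream


def _matrix(cols: dict, meta: dict | None = None) -> AllelicCountMatrix:
    counts = pd.DataFrame(cols)
    counts.index = [f"g{i}" for i in range(len(counts))]
    if meta is None:
        meta = {c: {"allele": "paternal" if c.startswith("a") else "maternal"} for c in cols}
    samples = pd.DataFrame(meta).T.loc[list(cols)]
    return AllelicCountMatrix(counts, samples)


# ---------------------------------------------------------------- normalization

def test_normalization_identities():
    rng = substream(1, "norm")
    base = rng.poisson(50, size=200)
    counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
    f = normalize_libsize(counts)
    assert f["s1"] == pytest.approx(f["s2"])
    assert f["s3"] / f["s1"] == pytest.approx(2.0, abs=1e-9)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)


def test_normalization_rejects_all_zero_sample():
    counts = pd.DataFrame({"ok": [1, 2, 3], "empty": [0, 0, 0]})
    with pytest.raises(ValueError, match="empty"):
        normalize_libsize(counts)


# ---------------------------------------------------------------- dispersion

def test_dispersion_clamped_at_zero_for_underdispersed_counts():
    cols = {f"a{j}": np.full(100, 50) for j in range(4)}
    cols.update({f"b{j}": np.full(100, 50) for j in range(4)})
    est = estimate_dispersion(_matrix(cols))
    assert est.common == pytest.approx(0.0, abs=1e-9)
    assert (est.per_gene >= 0).all()


def test_dispersion_single_replicate_warns():
    cols = {"a0": np.full(50, 20), "b0": np.full(50, 20)}
    with pytest.warns(UserWarning, match="replicates"):
        est = estimate_dispersion(_matrix(cols))
    assert est.common > 0  # documented fallback


# ---------------------------------------------------------------- exact NB test

def test_identical_groups_are_null():
    rng = substream(2, "nbnull")
    base = rng.poisson(100, size=150)
    cols = {"a0": base, "a1": base, "b0": base, "b1": base}
    de = nb_exact_test(_matrix(cols), dispersion=0.0)
    assert np.allclose(de["log2fc"], 0.0)
    assert (de["pvalue"] > 0.9).all()


def test_zero_gene_flagged_low_expression():
    cols = {"a0": [0, 100], "a1": [0, 110], "b0": [0, 90], "b1": [0, 105]}
    de = nb_exact_test(_matrix(cols))
    assert bool(de.loc["g0", "low_expression"])
    assert de.loc["g0", "pvalue"] == 1.0
    assert de.loc["g0", "log2fc"] == 0.0


def test_binomial_limit_small():
    assert nb_binomial_limit_check(21, 150)["max_abs_dlog10_p"] < 0.05


def test_effect_recovery_small():
    assert nb_effect_recovery(22, n_genes=400, n_planted=40)["abs_error"] <= 0.5


def test_reciprocity_parent_and_cross_swaps():
    """Swapping cross labels changes nothing; swapping parent labels
    negates every log2FC exactly and keeps p-values."""
    rng = substream(3, "recip")
    n = 80
    cols, meta = {}, {}
    for cross in ("PWKxB6", "B6xPWK"):
        for rep in (1, 2):
            tot = rng.poisson(200, size=n)
            pat = rng.binomial(tot, 0.5)
            cols[f"p_{cross}_{rep}"] = pat
            cols[f"m_{cross}_{rep}"] = tot - pat
            meta[f"p_{cross}_{rep}"] = {"allele": "paternal", "cross": cross}
            meta[f"m_{cross}_{rep}"] = {"allele": "maternal", "cross": cross}
    mat = _matrix(cols, meta)
    de = nb_exact_test(mat, dispersion=0.05)

    flipped_cross = mat.samples.copy()
    flipped_cross["cross"] = flipped_cross["cross"].map({"PWKxB6": "B6xPWK", "B6xPWK": "PWKxB6"})
    de_cross = nb_exact_test(AllelicCountMatrix(mat.counts, flipped_cross), dispersion=0.05)
    pd.testing.assert_frame_equal(de, de_cross)

    flipped_parent = mat.samples.copy()
    flipped_parent["allele"] = flipped_parent["allele"].map(
        {"paternal": "maternal", "maternal": "paternal"}
    )
    de_parent = nb_exact_test(AllelicCountMatrix(mat.counts, flipped_parent), dispersion=0.05)
    np.testing.assert_allclose(de_parent["log2fc"], -de["log2fc"], atol=1e-12)
    np.testing.assert_allclose(de_parent["pvalue"], de["pvalue"], atol=1e-9)


# ---------------------------------------------------------------- BH

def test_bh_worked_and_degenerate_vectors():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)
    np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_bruteforce_and_statsmodels():
    rng = substream(4, "bh")
    for _ in range(50):
        p = np.round(rng.random(rng.integers(1, 40)), 3)
        ours = bh_fdr(p)
        assert np.array_equal(ours, _bh_bruteforce(p))
        sm = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, sm, atol=1e-12)


# ---------------------------------------------------------------- decision rules

def _de_frame(rows):
    df = pd.DataFrame(rows, columns=["log2fc", "fdr", "low_expression"])
    df.index = [f"g{i}" for i in range(len(df))]
    return df


def test_candidate_thresholds_are_strict():
    de = _de_frame([
        (5.0, 1e-5, False),   # in
        (2.9, 1e-9, False),   # log2FC not > 3
        (5.0, 0.001, False),  # FDR not < 0.001
        (-5.0, 1e-9, False),  # maternal direction
        (5.0, 1e-5, True),    # low expression
    ])
    assert call_candidates(de) == {"g0"}


def test_cross_inconsistent_candidates_disqualified():
    de = _de_frame([(5.0, 1e-5, False), (5.0, 1e-5, False)])
    de["cross_consistent"] = [True, False]
    assert call_candidates(de) == {"g0"}


def test_confirmation_requires_second_dataset_pass():
    second = _de_frame([(5.0, 1e-5, False), (1.0, 0.5, False)])
    confirmed = confirm_candidates({"g0", "g1", "absent"}, second)
    assert confirmed == {"g0"}
    assert confirm_candidates(set(), second) == set()


def test_andro_partheno_validation_and_carryover(genome, small_config):
    cfg = small_config.replace(transient_fraction=0.0, expressed_pre_zga_frac=0.3)
    t = make_truth(genome, cfg)
    groups = simulate_group_counts(
        genome, t, ("androgenote", "parthenogenote", "amanitin"), cfg.replace(n_replicates=3)
    )
    res = validate_andro_partheno(list(t.index), groups)
    pegs = t.index[t["is_peg"]]
    nonpeg = t.index[~t["is_peg"]]
    assert res.loc[pegs, "validated_ap"].mean() >= 0.8
    assert res.loc[nonpeg, "validated_ap"].mean() <= 0.1
    # maternal-deposit genes that fail validation are carryover-confounded
    conf = res["carryover_confounded"]
    assert (conf == (res["expressed_pre_zga"] & ~res["validated_ap"])).all()
    assert res.loc[t.index[t["expressed_pre_zga"] & ~t["is_peg"]], "expressed_pre_zga"].all()


def test_missing_group_rejected(genome, truth, small_config):
    groups = simulate_group_counts(genome, truth, ("androgenote", "parthenogenote"), small_config)
    with pytest.raises(ValueError, match="amanitin"):
        validate_andro_partheno(list(truth.index), groups)
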