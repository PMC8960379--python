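#!/usr/bin/env python
"""Statistical validation battery: oracle equivalences, null
calibrations and operating characteristics for every statistical
component (the same measurements scripts/acceptance.py reports).

Writes results/validation.tsv.
"""

from pathlib import Path

import pandas as pd

from pegtrace import experiments as ex

BASE = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    rows = []

    def add(component, measure, value, n):
        rows.append({"component": component, "measure": measure, "value": value, "n": n})
        print(f"{component}: {measure} = {value:.6g} (n={n})")

    r = ex.assign_oracle_check(seed)
    add("allele assignment", "brute-force oracle agreement", r["agreement"], r["n"])
    r = ex.chisq_null_calibration(seed)
    add("chi-square screen", "null rejection rate at alpha=0.05", r["rejection_rate"], r["n"])
    r = ex.trend_null_calibration(seed)
    add("CA trend test", "null rejection rate at alpha=0.05", r["rejection_rate"], r["n"])
    r = ex.trend_permutation_check(seed)
    add("CA trend test", "max |asymptotic - permutation| p", r["max_abs_diff"], r["n"])
    r = ex.bh_check(seed)
    add("BH FDR", "brute-force mismatches", r["n_mismatch"], r["n"])
    r = ex.nb_binomial_limit_check(seed)
    add("NB exact test", "max |dlog10 p| vs binomial at dispersion 0", r["max_abs_dlog10_p"], r["n"])
    r = ex.nb_effect_recovery(seed)
    add("NB exact test", "recovered log2FC for planted effect 5", r["mean_log2fc"], r["n"])
    r = ex.peg_operating_characteristics(seed, n_seeds=5)
    add("PEG candidate rule", "sensitivity", r["sensitivity"], r["n"])
    add("PEG candidate rule", "false-discovery proportion", r["false_discovery_proportion"], r["n"])
    r = ex.peak_null_check(seed)
    add("broad-peak caller", "zero-peak fraction on pure background", r["zero_peak_fraction"], r["n"])
    r = ex.peak_recovery_check(seed)
    add("broad-peak caller", "planted 2-kb domain recovery", r["recovered_fraction"], r["n"])

    out = BASE / "validation.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"table written to {out}")


if __name__ == "__main__":
    main()
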