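#!/usr/bin/env python
"""Genetic-variance decomposition and selection calls with permutation nulls.

Per condition: V_G = V_T - V_E with a 95% bootstrap CI over mutants (both the
population-divisor estimator and its replicate-noise-corrected variant).
Antagonistic pleiotropy: (w_N, w_S) replicate pairs against the bivariate
Gaussian bulk, 3-of-3 rule, permutation null.  Transgressivity: 3-of-4 rule
against the steady-condition envelope, permutation null.  Writes
results/selection/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pulsefit.fitness import fitness_matrix, genetic_variance
from pulsefit.selection import (
    call_AP_table,
    call_transgressive_table,
    pair_replicates,
    permutation_null_AP,
    permutation_null_transgressivity,
)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "selection"
SEED = 23


def main() -> None:
    fpath = BASE / "fitness" / "fitness.tsv"
    if not fpath.exists():
        print("run analysis/03_fitness_homogenization.py first", file=sys.stderr)
        return 1
    fl = pd.read_csv(fpath, sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for cond in sorted(fl["condition"].unique()):
        W = fitness_matrix(fl, cond)
        vd = genetic_variance(W.values, n_bootstrap=1000, seed=SEED)
        rows.append(dict(condition=cond, V_T=vd.V_T, V_E=vd.V_E, V_G=vd.V_G,
                         CI_low=vd.CI_low, CI_high=vd.CI_high,
                         V_G_corrected=vd.V_G_corrected,
                         CI_corr_low=vd.CI_corrected_low,
                         CI_corr_high=vd.CI_corrected_high))
        print(f"{cond}: V_G = {vd.V_G:.2e} [{vd.CI_low:.2e}, {vd.CI_high:.2e}]"
              f" (corrected {vd.V_G_corrected:.2e})")
    pd.DataFrame(rows).to_csv(OUT / "variance_decomposition.tsv", sep="\t",
                              index=False)

    wN = fitness_matrix(fl, "N")
    wS = fitness_matrix(fl, "S")
    common = wN.index.intersection(wS.index)
    pairs = {m: pair_replicates(wN.loc[m].dropna().values,
                                wS.loc[m].dropna().values, seed=SEED + i)
             for i, m in enumerate(common)}
    ap = call_AP_table(pairs)
    ap.to_csv(OUT / "ap_calls.tsv", sep="\t")
    exp_ap, _ = permutation_null_AP(pairs, n_perm=1000, seed=SEED)
    print(f"AP: {int(ap['is_AP'].sum())} called "
          f"(permutation null expects {exp_ap:.2f})")

    wNS = fitness_matrix(fl, "NS6")
    common = wNS.index.intersection(common)
    d_ns = {m: wNS.loc[m].dropna().values for m in common}
    d_n = {m: wN.loc[m].dropna().values for m in common}
    d_s = {m: wS.loc[m].dropna().values for m in common}
    tg = call_transgressive_table(d_ns, d_n, d_s)
    tg.to_csv(OUT / "transgressive_calls.tsv", sep="\t")
    exp_tg, _ = permutation_null_transgressivity(d_ns, d_n, d_s,
                                                 n_perm=1000, seed=SEED)
    n_tg = int((tg["direction"] != "none").sum())
    print(f"transgressive: {n_tg} called "
          f"(permutation null expects {exp_tg:.2f})")


if __name__ == "__main__":
    sys.exit(main() or 0)
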