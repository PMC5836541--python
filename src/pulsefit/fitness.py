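"""Relative fitness estimation and genetic-variance decomposition.

Fitness of a mutant is its per-generation proliferation rate relative to an
artificial wild type — the pooled abundance of a configurable set of deletion
strains with no effect on growth:

    w = ((M_e / M_b) / (WT_e / WT_b)) ** (1 / g)

with M and WT the mutant and reference frequencies at the beginning (b) and
end (e) of the competition and g the number of generations in between (24 for
the standard 3-day window at 8 generations/day).  Because w is a ratio of
ratios within samples, it is invariant to per-sample scaling, so size factors
and the frequency denominator cancel.

The time-average (homogenization) null states that fitness in an environment
alternating between N and S equals the time-weighted geometric mean
``w_N**f_N * w_S**f_S``; the inhomogeneity ratio dev = w_obs / w_exp measures
the departure from it.

Genetic variance in fitness is V_G = V_T - V_E with population-divisor
formulas (no Bessel correction): V_T the total variance over all
mutant x replicate fitness values and V_E the within-mutant replicate
variance.  Bootstrap CIs resample mutants with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .processing import NormTable


def fitness(M_b: float, M_e: float, WT_b: float, WT_e: float, g: int = 24) -> float:
    """Relative fitness per generation from endpoint frequencies."""
    if g < 1:
        raise ValueError("g must be >= 1")
    for v in (M_b, M_e, WT_b, WT_e):
        if v <= 0:
            raise ValueError("frequencies must be positive")
    return float(((M_e / M_b) / (WT_e / WT_b)) ** (1.0 / g))


def expected_fitness(w_N: float, w_S: float, f_N: float, f_S: float) -> float:
    """Time-weighted geometric mean of the steady-condition fitness values."""
    if w_N <= 0 or w_S <= 0:
        raise ValueError("fitness must be positive")
    if not np.isclose(f_N + f_S, 1.0):
        raise ValueError("time fractions must sum to 1")
    return float(w_N ** f_N * w_S ** f_S)


def inhomogeneity(w_observed: float, w_expected: float) -> float:
    """dev = w_observed / w_expected; 1 means fitness is homogenized."""
    if w_expected <= 0:
        raise ValueError("w_expected must be positive")
    return float(w_observed / w_expected)


def artificial_wt(norm: NormTable | pd.DataFrame, neutral_set: list[str]) -> pd.Series:
    """Per-sample abundance of the artificial wild type: the summed
    count-scale abundance of the neutral deletion strains."""
    table = norm.scaled if isinstance(norm, NormTable) else norm
    present = [m for m in neutral_set if m in table.index]
    if not present:
        raise ValueError("no neutral-set mutant present in the table")
    return table.loc[present].sum(axis=0)


def estimate_fitness(
    norm: NormTable | pd.DataFrame,
    sample_sheet: pd.DataFrame,
    neutral_set: list[str],
    g: int = 24,
    day_b: int = 0,
    day_e: int = 3,
    pseudo_abundance: float = 0.5,
    g_by_condition: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per mutant x condition x replicate fitness table (long format).

    Endpoints are matched by replicate: replicate r at ``day_b`` against
    replicate r at ``day_e``.  Replicates missing either endpoint are skipped,
    so ragged replicate counts (e.g. a discarded day-3 sample) are handled.
    Zero abundances receive ``pseudo_abundance`` on the count scale.
    ``g_by_condition`` optionally overrides g per condition (e.g. a slower
    doubling time under stress).
    """
    table = norm.scaled if isinstance(norm, NormTable) else norm
    table = table.clip(lower=pseudo_abundance)
    wt = artificial_wt(table, neutral_set)
    ss = sample_sheet.set_index("sample_id")
    ss = ss.loc[[s for s in table.columns if s in ss.index]]
    rows = []
    for cond, sub in ss.groupby("condition", sort=False):
        g_c = (g_by_condition or {}).get(cond, g)
        for rep, reps in sub.groupby("replicate"):
            b = reps.index[reps["day"] == day_b]
            e = reps.index[reps["day"] == day_e]
            if len(b) != 1 or len(e) != 1:
                continue
            sb, se = b[0], e[0]
            ratio = (table[se] / table[sb]) / (wt[se] / wt[sb])
            w = ratio ** (1.0 / g_c)
            for mid, val in w.items():
                rows.append(dict(mutant_id=mid, condition=cond,
                                 replicate=int(rep), w=float(val)))
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no replicate had both endpoint days")
    return out


def fitness_matrix(fit_long: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Wide mutant x replicate slice of a long fitness table."""
    sub = fit_long[fit_long["condition"] == condition]
    return sub.pivot(index="mutant_id", columns="replicate", values="w")


@dataclass
class VarianceDecomposition:
    V_T: float
    V_E: float
    V_G: float
    CI_low: float
    CI_high: float
    n_bootstrap: int
    V_G_corrected: float = float("nan")
    CI_corrected_low: float = float("nan")
    CI_corrected_high: float = float("nan")


def _variance_components(W: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """(V_T, V_E, V_G, V_G_corrected) with population divisors.

    V_G = V_T - V_E equals the population variance of the per-mutant means
    (balanced case), whose null expectation under pure replicate noise is
    sigma_E^2 / R — not zero.  V_G_corrected subtracts that sampling
    contribution using the Bessel-corrected replicate variance, so it is
    centred on zero when there is no genetic signal.
    """
    M = mask.sum()
    N = W.shape[0]
    Wm = np.where(mask, W, np.nan)
    wbar = W[mask].mean()
    wbar_i = np.nanmean(Wm, axis=1)
    V_T = float(np.nansum((Wm - wbar) ** 2) / M)
    ss_within = float(np.nansum((Wm - wbar_i[:, None]) ** 2))
    V_E = ss_within / M
    V_G = V_T - V_E
    R_i = mask.sum(axis=1)
    dof = int((R_i - 1).sum())
    if dof > 0:
        sigma2_e = ss_within / dof
        V_G_corr = V_G - sigma2_e * np.mean(1.0 / R_i) * (N - 1) / N
    else:
        V_G_corr = float("nan")
    return V_T, V_E, V_G, V_G_corr


def genetic_variance(
    w_reps: pd.DataFrame | np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Decompose fitness variance for one condition.

    ``w_reps``: mutants x replicates (NaN allowed for ragged replicates).
    Population divisors for the balanced 3-replicate case, generalized to the
    actual number of observations:

        V_T = (1/M) sum_ij (w_ij - wbar)^2,   M = total observations
        V_E = (1/M) sum_ij (w_ij - wbar_i)^2
        V_G = V_T - V_E

    Because V_G so defined inherits a sigma_E^2/R sampling contribution from
    the replicate means, the corrected variant ``V_G_corrected`` (which
    removes it; zero-centred under a pure-noise null) is reported alongside,
    each with a 95% bootstrap CI over mutants.
    """
    W = np.asarray(w_reps, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need >= 2 mutants with replicate fitness values")
    mask = np.isfinite(W)
    if (mask.sum(axis=1) < 2).any():
        raise ValueError("every mutant needs >= 2 replicates")
    V_T, V_E, V_G, V_G_corr = _variance_components(W, mask)

    rng = np.random.default_rng(seed)
    n = W.shape[0]
    boots = np.empty(n_bootstrap)
    boots_corr = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        _, _, vg, vgc = _variance_components(W[idx], mask[idx])
        boots[b] = vg
        boots_corr[b] = vgc
    lo, hi = np.percentile(boots, [2.5, 97.5])
    loc, hic = np.percentile(boots_corr, [2.5, 97.5])
    return VarianceDecomposition(
        V_T, V_E, V_G, float(lo), float(hi), n_bootstrap,
        V_G_corrected=V_G_corr, CI_corrected_low=float(loc),
        CI_corrected_high=float(hic),
    )


def dev_table(
    fit_long: pd.DataFrame,
    periodic_condition: str,
    f_N: float,
    f_S: float,
) -> pd.DataFrame:
    """Observed vs time-average expected fitness per mutant.

    Per-condition fitness is the mean over replicates; returns columns
    w_obs, w_N, w_S, w_exp, dev.
    """
    means = (
        fit_long.groupby(["mutant_id", "condition"])["w"].mean().unstack("condition")
    )
    need = {"N", "S", periodic_condition}
    if not need.issubset(means.columns):
        raise ValueError(f"fitness table lacks conditions {need - set(means.columns)}")
    out = pd.DataFrame(index=means.index)
    out["w_N"] = means["N"]
    out["w_S"] = means["S"]
    out["w_obs"] = means[periodic_condition]
    out["w_exp"] = means["N"] ** f_N * means["S"] ** f_S
    out["dev"] = out["w_obs"] / out["w_exp"]
    return out.dropna()
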