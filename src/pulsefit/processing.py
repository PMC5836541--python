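"""Filtering, day-0 imputation and normalization of BAR-Seq count tables.

Samples are dropped when they are both depth-starved (total counts below a
floor, default 300,000) and poorly correlated with their replicate samples;
mutants are dropped when their grand total across all samples is below 2,000.
Normalization follows the size-factor / variance-stabilizing approach used
for RNA-seq-like count tables: median-of-ratios size factors against a
geometric-mean pseudo-reference, then a parametric negative-binomial VST whose
dispersion trend alpha(mu) = a1/mu + a0 is fitted from replicate groups.  The
VST is monotone within each sample and approximately log2-linear at high
counts, which is all the downstream fitness/GLM stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class NormTable:
    """Normalized counts plus the bookkeeping to go back to the count scale."""

    values: pd.DataFrame            # VST scale (log2-like)
    size_factors: pd.Series         # per sample
    scaled: pd.DataFrame            # raw / size factor ("count scale")
    method: str = "mor+vst"
    vst_params: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mutants(self) -> list[str]:
        return list(self.values.index)


def filter_samples(
    raw: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_total: float = 300_000,
    min_replicate_correlation: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples failing BOTH the depth floor and replicate concordance.

    A sample is discarded only when its total count is below ``min_total`` AND
    the Pearson correlation of its log frequencies with every same
    condition x day replicate is below ``min_replicate_correlation``.
    """
    ss = sample_sheet.set_index("sample_id")
    totals = raw.sum(axis=0)
    logf = np.log((raw + 0.5) / (totals + 0.5))
    discarded: list[str] = []
    for sid in raw.columns:
        if totals[sid] >= min_total:
            continue
        cond, day = ss.loc[sid, "condition"], ss.loc[sid, "day"]
        mates = [
            s for s in raw.columns
            if s != sid and ss.loc[s, "condition"] == cond and ss.loc[s, "day"] == day
        ]
        if not mates:
            continue
        corrs = [logf[sid].corr(logf[m]) for m in mates]
        if all(c < min_replicate_correlation for c in corrs):
            discarded.append(sid)
    kept = raw.drop(columns=discarded)
    if kept.shape[1] == 0:
        raise ValueError("all samples discarded")
    return kept, discarded


def filter_mutants(raw: pd.DataFrame, min_total_counts: float = 2_000) -> pd.DataFrame:
    """Keep mutants whose grand total across all samples is >= the threshold
    (strictly-below is discarded)."""
    keep = raw.sum(axis=1) >= min_total_counts
    out = raw.loc[keep]
    if out.shape[0] == 0:
        raise ValueError("all mutants discarded")
    return out


def impute_missing_day0(
    raw: pd.DataFrame, target_samples: list[str], donor_samples: list[str]
) -> pd.DataFrame:
    """Replace each target column by the per-mutant median over donor columns
    (rounded to nearest integer).  Non-target columns are untouched."""
    if not donor_samples:
        raise ValueError("no donor samples for imputation")
    missing = [s for s in donor_samples if s not in raw.columns]
    if missing:
        raise ValueError(f"donor samples absent from table: {missing}")
    med = raw[donor_samples].median(axis=1).round()
    out = raw.copy()
    for t in target_samples:
        out[t] = med
    return out


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median over mutants of the ratio to the
    geometric-mean pseudo-reference, using mutants nonzero in every sample."""
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no mutant is nonzero in every sample; cannot normalize")
    ratios = logc.loc[usable].sub(ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    if not np.isfinite(sf).all() or (sf <= 0).any():
        raise ValueError("a sample shares no nonzero mutants with the reference")
    return sf


def _dispersion_trend(
    scaled: pd.DataFrame, groups: pd.Series | None
) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0 by least squares on per-mutant moment
    estimates of dispersion, computed within replicate groups when given."""
    if groups is not None:
        mus, disps = [], []
        for _, cols in groups.groupby(groups):
            sub = scaled[cols.index]
            if sub.shape[1] < 2:
                continue
            m = sub.mean(axis=1)
            v = sub.var(axis=1, ddof=1)
            mus.append(m)
            disps.append((v - m) / m.pow(2))
        if not mus:
            groups = None
        else:
            mu = pd.concat(mus)
            disp = pd.concat(disps)
    if groups is None:
        mu = scaled.mean(axis=1)
        v = scaled.var(axis=1, ddof=1)
        disp = (v - mu) / mu.pow(2)
    ok = (mu > 0) & np.isfinite(disp) & (disp > 0)
    if ok.sum() < 10:
        return 1e-6, 0.0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok].values])
    coef, *_ = np.linalg.lstsq(X, disp[ok].values, rcond=None)
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def _vst(x: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form VST of the NB with dispersion trend a1/mu + a0; log2-linear
    for large x, variance-stabilized near zero."""
    x = np.asarray(x, dtype=float)
    return np.log2(
        (1.0 + a1 + 2.0 * a0 * x + 2.0 * np.sqrt(a0 * x * (1.0 + a1 + a0 * x)))
        / (4.0 * a0)
    )


def normalize(
    filtered: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
    method: str = "mor+vst",
) -> NormTable:
    """Size-factor normalization plus a variance-stabilizing transform.

    ``method`` is ``"mor+vst"`` (default) or ``"log2"`` for the documented
    ``log2(count/sf + 0.5)`` fallback.  Both are strictly monotone within a
    sample; two samples that are exact scalar multiples normalize identically.
    """
    if (filtered.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample present; filter first")
    sf = size_factors_median_of_ratios(filtered)
    scaled = filtered.div(sf, axis=1)
    if method == "log2":
        values = np.log2(scaled + 0.5)
        return NormTable(values, sf, scaled, method="log2")
    groups = None
    if sample_sheet is not None:
        ss = sample_sheet.set_index("sample_id")
        ids = [s for s in filtered.columns if s in ss.index]
        if len(ids) == len(filtered.columns):
            groups = ss.loc[filtered.columns].apply(
                lambda r: f"{r['condition']}_{r['day']}", axis=1
            )
    a0, a1 = _dispersion_trend(scaled, groups)
    if a0 < 1e-4:
        # essentially Poisson data: the parametric VST degenerates (its
        # argument is dominated by the constant term), so fall back to the
        # shifted-log transform
        values = np.log2(scaled + 0.5)
        return NormTable(values, sf, scaled, method="log2",
                         vst_params={"a0": a0, "a1": a1})
    values = pd.DataFrame(
        _vst(scaled.values, a0, a1), index=filtered.index, columns=filtered.columns
    )
    return NormTable(values, sf, scaled, method="mor+vst",
                     vst_params={"a0": a0, "a1": a1})
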