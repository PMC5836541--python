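"""Antagonistic-pleiotropy and transgressive-fitness calling.

A mutation is antagonistically pleiotropic (AP) when it confers an advantage
in one steady condition and a disadvantage in the other.  Replicate fitness
estimates (three w_N, four w_S per mutant) are combined into three (w_N, w_S)
pairs by randomly discarding one w_S; a pair supports AP when (1) the signs
disagree around 1 and (2) the pair is an outlier of the bivariate Gaussian
fitted to all observed pairs (Mahalanobis distance strictly greater than 2).
A mutant is called AP only when all of its pairs support it.  The expected
number of chance calls comes from a permutation null that reassigns pairs to
mutants while preserving the pairs-per-mutant structure.

Transgressivity: fitness in the oscillating regime exceeding the fitness in
both steady conditions.  A mutant is called when at least three of its four
oscillating-regime replicates fall above max(wbar_N + sd_N, wbar_S + sd_S), or
at least three fall below min(wbar_N - sd_N, wbar_S - sd_S); its permutation
null reassigns oscillating-regime replicate values to random mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GaussianModel:
    mean: np.ndarray
    cov: np.ndarray
    _prec: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        det = np.linalg.det(self.cov)
        if not np.isfinite(det) or det <= 0:
            raise ValueError("singular covariance")
        self._prec = np.linalg.inv(self.cov)

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.mean
        return np.sqrt(np.einsum("ij,jk,ik->i", d, self._prec, d))


def fit_bivariate_gaussian(pairs: np.ndarray) -> GaussianModel:
    """ML mean and covariance of all observed (w_N, w_S) pairs."""
    pts = np.asarray(pairs, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 bivariate points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)  # ML (population) covariance
    return GaussianModel(mean, cov)


def pair_replicates(
    w_N: np.ndarray, w_S: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Combine replicate fitness values into (w_N, w_S) pairs.

    When one side has more replicates, the surplus values are discarded
    uniformly at random (seeded); pairing is then by index order.
    """
    a = np.asarray(w_N, dtype=float)
    b = np.asarray(w_S, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates on each side")
    k = min(len(a), len(b))
    rng = np.random.default_rng(seed)
    if len(a) > k:
        a = a[np.sort(rng.choice(len(a), k, replace=False))]
    if len(b) > k:
        b = b[np.sort(rng.choice(len(b), k, replace=False))]
    return np.column_stack([a, b])


@dataclass
class APCall:
    mutant_id: str
    pairs: np.ndarray
    is_AP: bool
    magnitude: float            # mean of w_N / w_S over pairs
    mahalanobis: np.ndarray
    n_supporting: int


def _pair_supports_ap(pairs: np.ndarray, model: GaussianModel) -> np.ndarray:
    wn, ws = pairs[:, 0], pairs[:, 1]
    sign_ok = ((wn > 1) & (ws < 1)) | ((wn < 1) & (ws > 1))
    outlier = model.mahalanobis(pairs) > 2.0   # strict
    return sign_ok & outlier


def call_AP(mutant_id: str, pairs: np.ndarray, model: GaussianModel) -> APCall:
    pairs = np.asarray(pairs, dtype=float)
    support = _pair_supports_ap(pairs, model)
    return APCall(
        mutant_id=mutant_id,
        pairs=pairs,
        is_AP=bool(support.all()),
        magnitude=float(np.mean(pairs[:, 0] / pairs[:, 1])),
        mahalanobis=model.mahalanobis(pairs),
        n_supporting=int(support.sum()),
    )


def call_AP_table(
    pairs_by_mutant: dict[str, np.ndarray], model: GaussianModel | None = None
) -> pd.DataFrame:
    """AP calls for every mutant; the Gaussian bulk model is fitted on the
    pooled pairs unless given."""
    if model is None:
        model = fit_bivariate_gaussian(
            np.vstack(list(pairs_by_mutant.values()))
        )
    rows = []
    for mid, pr in pairs_by_mutant.items():
        c = call_AP(mid, pr, model)
        rows.append(dict(mutant_id=mid, is_AP=c.is_AP, magnitude=c.magnitude,
                         n_supporting=c.n_supporting))
    return pd.DataFrame(rows).set_index("mutant_id")


def permutation_null_AP(
    pairs_by_mutant: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
    model: GaussianModel | None = None,
) -> tuple[float, np.ndarray]:
    """Expected number of AP calls under reassignment of pairs to mutants.

    Pairs are pooled and re-partitioned into the original pairs-per-mutant
    blocks; the bulk Gaussian is fitted once on the pooled pairs (it is
    invariant to the reassignment).  Returns (mean count, per-permutation
    counts).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(pairs_by_mutant) < 2:
        raise ValueError("need >= 2 mutants")
    sizes = [len(p) for p in pairs_by_mutant.values()]
    pool = np.vstack(list(pairs_by_mutant.values()))
    if model is None:
        model = fit_bivariate_gaussian(pool)
    support = _pair_supports_ap(pool, model)  # support is per-pair: precompute
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(pool))
        s = support[perm]
        c = 0
        pos = 0
        for k in sizes:
            if s[pos:pos + k].all():
                c += 1
            pos += k
        counts[b] = c
    return float(counts.mean()), counts


def classify_direction(
    w_by_period: dict[int, np.ndarray], ambiguous_threshold: int = 4
) -> tuple[dict[int, str], str]:
    """Direction of selection per oscillating period and the overall label.

    Per period: positive if mean - sd > 1, negative if mean + sd < 1, else
    ambiguous.  Overall: "unclear" when ambiguous at >= ``ambiguous_threshold``
    periods; "always_positive"/"always_negative" when every unambiguous
    direction agrees; "period_dependent" otherwise.
    """
    per_period: dict[int, str] = {}
    for period, w in w_by_period.items():
        w = np.asarray(w, dtype=float)
        if len(w) < 2:
            per_period[period] = "ambiguous"
            continue
        m, s = w.mean(), w.std(ddof=1)
        if m - s > 1:
            per_period[period] = "positive"
        elif m + s < 1:
            per_period[period] = "negative"
        else:
            per_period[period] = "ambiguous"
    dirs = [d for d in per_period.values() if d != "ambiguous"]
    n_ambig = sum(d == "ambiguous" for d in per_period.values())
    if n_ambig >= ambiguous_threshold or not dirs:
        label = "unclear"
    elif all(d == "positive" for d in dirs):
        label = "always_positive"
    elif all(d == "negative" for d in dirs):
        label = "always_negative"
    else:
        label = "period_dependent"
    return per_period, label


@dataclass
class TransgressivityCall:
    mutant_id: str
    direction: str              # high | low | none
    n_supporting: int
    envelope: tuple[float, float]


def call_transgressive(
    mutant_id: str,
    w_NS: np.ndarray,
    w_N: np.ndarray,
    w_S: np.ndarray,
    min_supporting: int = 3,
) -> TransgressivityCall:
    """3-of-4 rule against the steady-condition envelope.

    Envelope: upper = max(wbar_N + sd_N, wbar_S + sd_S); lower =
    min(wbar_N - sd_N, wbar_S - sd_S).  "high" when >= ``min_supporting`` of
    the oscillating-regime replicates exceed the upper bound, "low" when
    >= ``min_supporting`` fall below the lower bound.
    """
    w_NS = np.asarray(w_NS, dtype=float)
    w_N = np.asarray(w_N, dtype=float)
    w_S = np.asarray(w_S, dtype=float)
    mN, sN = w_N.mean(), w_N.std(ddof=1) if len(w_N) > 1 else 0.0
    mS, sS = w_S.mean(), w_S.std(ddof=1) if len(w_S) > 1 else 0.0
    upper = max(mN + sN, mS + sS)
    lower = min(mN - sN, mS - sS)
    if len(w_NS) < min_supporting:
        return TransgressivityCall(mutant_id, "none", 0, (upper, lower))
    n_hi = int((w_NS > upper).sum())
    n_lo = int((w_NS < lower).sum())
    if n_hi >= min_supporting:
        return TransgressivityCall(mutant_id, "high", n_hi, (upper, lower))
    if n_lo >= min_supporting:
        return TransgressivityCall(mutant_id, "low", n_lo, (upper, lower))
    return TransgressivityCall(mutant_id, "none", max(n_hi, n_lo), (upper, lower))


def call_transgressive_table(
    w_NS_by_mutant: dict[str, np.ndarray],
    w_N_by_mutant: dict[str, np.ndarray],
    w_S_by_mutant: dict[str, np.ndarray],
) -> pd.DataFrame:
    rows = []
    for mid, wns in w_NS_by_mutant.items():
        c = call_transgressive(mid, wns, w_N_by_mutant[mid], w_S_by_mutant[mid])
        rows.append(dict(mutant_id=mid, direction=c.direction,
                         n_supporting=c.n_supporting,
                         envelope_high=c.envelope[0], envelope_low=c.envelope[1]))
    return pd.DataFrame(rows).set_index("mutant_id")


def permutation_null_transgressivity(
    w_NS_by_mutant: dict[str, np.ndarray],
    w_N_by_mutant: dict[str, np.ndarray],
    w_S_by_mutant: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Expected transgressive-call count when oscillating-regime replicate
    values are reassigned to random mutants (steady envelopes kept fixed;
    replicate-count structure preserved)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mids = list(w_NS_by_mutant)
    sizes = [len(w_NS_by_mutant[m]) for m in mids]
    pool = np.concatenate([np.asarray(w_NS_by_mutant[m], dtype=float) for m in mids])
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(pool))
        pos = 0
        c = 0
        for mid, k in zip(mids, sizes):
            wns = pool[perm[pos:pos + k]]
            pos += k
            call = call_transgressive(mid, wns, w_N_by_mutant[mid], w_S_by_mutant[mid])
            if call.direction != "none":
                c += 1
        counts[b] = c
    return float(counts.mean()), counts
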