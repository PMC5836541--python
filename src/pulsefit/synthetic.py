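"""Forward simulation of pooled barcoded-mutant competitions.

The generator reproduces the structure of a pooled serial-dilution competition
read out by barcode sequencing: a library of deletion mutants, each present at
~320 copies initially, grows through 3-h transfer slots (one generation per
slot, eight per day) under steady or periodically alternating media.  Each
mutant carries a per-generation relative fitness in each medium (``w_N``,
``w_S``) and optionally an inhomogeneity effect: a per-medium-change increment
of log abundance (``beta3``), which is exactly the alternative hypothesis of
the downstream count GLM.  Sequencing is emulated by negative-binomial
sampling of per-mutant reads followed by multinomial rescaling to the sample's
depth, so column totals are controlled.

Every downstream stage (demultiplexing, normalization, fitness estimation,
GLM inference, selection calls, cytometry gating) can therefore be tested for
parameter recovery against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schedule import Schedule, design_row, standard_schedules

# Universal flanks of the uptag barcode (PCR priming sites in the deletion
# collection); reads are emitted as index9 + U1 + uptag + U2.
U1 = "GATGTCCACGAGGTCTCT"
U2 = "GTCGACCTGCAGCGTACG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Conditions of a pooled competition experiment.

    Defaults mirror the salt-oscillation study design: quadruplicate
    populations per condition, a 3-h transfer grid (eight generations/day),
    72 h of regime after a 6-h initialization in N, sampling at days 0-3.
    """

    n_mutants: int = 100
    init_copies_per_mutant: int = 320
    periods: tuple[int, ...] = (6, 12, 18, 24, 42)
    include_steady: bool = True
    n_replicates: int = 4
    transfer_interval_h: int = 3
    total_h: int = 72
    init_h: int = 6
    sampling_days: tuple[int, ...] = (0, 1, 2, 3)
    generations_per_day: int = 8
    depth_per_sample: float = 1_000_000
    nb_dispersion: float = 0.01
    dilution_rates: tuple[float, float, float] = (0.85, 0.55, 0.32)
    first_condition: str = "S"
    bottlenecks: bool = False
    lag_penalty: float = 0.0   # mechanistic alternative: penalized first slot after a change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("need at least one mutant")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not all(0 < f <= 1 for f in self.dilution_rates):
            raise ValueError("dilution rates must be in (0, 1]")
        for p in self.periods:
            if p % (2 * self.transfer_interval_h):
                raise ValueError(
                    f"period {p} not a multiple of 2 x {self.transfer_interval_h} h"
                )

    def schedules(self) -> list[Schedule]:
        out: list[Schedule] = []
        if self.include_steady:
            out += [
                Schedule("N", 0, steady_medium="N", total_h=self.total_h),
                Schedule("S", 0, steady_medium="S", total_h=self.total_h),
            ]
        for p in self.periods:
            out.append(
                Schedule(
                    f"NS{p}", p,
                    first_condition=self.first_condition,
                    transfer_interval_h=self.transfer_interval_h,
                    total_h=self.total_h,
                )
            )
        return out


@dataclass
class TrueParams:
    """Ground-truth per-mutant parameters of the generative model."""

    mutant_ids: list[str]
    w_N: np.ndarray
    w_S: np.ndarray
    beta3: np.ndarray
    neutral_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w_N = np.asarray(self.w_N, dtype=float)
        self.w_S = np.asarray(self.w_S, dtype=float)
        self.beta3 = np.asarray(self.beta3, dtype=float)
        n = len(self.mutant_ids)
        if not (len(self.w_N) == len(self.w_S) == len(self.beta3) == n):
            raise ValueError("one parameter entry per mutant required")
        if np.any(self.w_N <= 0) or np.any(self.w_S <= 0):
            raise ValueError("fitness multipliers must be positive")

    @classmethod
    def neutral(cls, n_mutants: int, prefix: str = "mut") -> "TrueParams":
        ids = [f"{prefix}{i:05d}" for i in range(n_mutants)]
        ones = np.ones(n_mutants)
        return cls(ids, ones.copy(), ones.copy(), np.zeros(n_mutants),
                   neutral_ids=list(ids))

    @classmethod
    def random(
        cls,
        n_mutants: int,
        n_neutral: int = 11,
        sd_w: float = 0.02,
        frac_inhomogeneous: float = 0.0,
        beta3_effect: float = 0.05,
        beta3_signs: str = "mixed",
        seed: int = 0,
        prefix: str = "mut",
    ) -> "TrueParams":
        """Fitness effects drawn around neutrality; the first ``n_neutral``
        mutants are exactly neutral and serve as the artificial-WT reference.

        ``beta3_signs``: "mixed" randomizes the sign of the inhomogeneity
        effect per gene; "fixed" applies ``beta3_effect`` as given.  Effects
        should stay in a minority of genes (as in real pools): counts are
        relative abundances, so a common effect shared by most of the pool is
        absorbed by normalization and is not identifiable.
        """
        rng = np.random.default_rng(seed)
        ids = [f"{prefix}{i:05d}" for i in range(n_mutants)]
        w_n = np.exp(rng.normal(0.0, sd_w, n_mutants))
        w_s = np.exp(rng.normal(0.0, sd_w, n_mutants))
        b3 = np.zeros(n_mutants)
        n_inh = int(round(frac_inhomogeneous * (n_mutants - n_neutral)))
        if n_inh:
            idx = rng.choice(np.arange(n_neutral, n_mutants), n_inh, replace=False)
            if beta3_signs == "mixed":
                b3[idx] = beta3_effect * rng.choice([-1.0, 1.0], n_inh)
            else:
                b3[idx] = beta3_effect
        w_n[:n_neutral] = 1.0
        w_s[:n_neutral] = 1.0
        b3[:n_neutral] = 0.0
        return cls(ids, w_n, w_s, b3, neutral_ids=ids[:n_neutral])


def _expected_abundance(
    cfg: SimConfig, truth: TrueParams, sch: Schedule, day: int
) -> np.ndarray:
    """Expected copy number of each mutant at sampling day ``day`` (relative
    scale; the initialization growth in N is included but cancels in every
    frequency ratio)."""
    init_gens = cfg.init_h // cfg.transfer_interval_h
    mu = float(cfg.init_copies_per_mutant) * truth.w_N ** init_gens
    if day == 0:
        return mu
    row = design_row(sch, day)
    g_n = row.t_N / cfg.transfer_interval_h
    g_s = row.t_S / cfg.transfer_interval_h
    if cfg.lag_penalty > 0 and sch.is_periodic:
        # mechanistic lag: the first slot after each change grows at a
        # penalized exponent (shared across media for simplicity)
        media = sch.slot_media(24 * day // cfg.transfer_interval_h)
        lag_n = lag_s = 0.0
        prev = "N"  # initialization medium
        for m in media:
            if m != prev:
                if m == "N":
                    lag_n += cfg.lag_penalty
                else:
                    lag_s += cfg.lag_penalty
            prev = m
        g_n -= lag_n
        g_s -= lag_s
    mu = mu * truth.w_N ** g_n * truth.w_S ** g_s * np.exp(truth.beta3 * row.n_changes)
    return mu


def simulate_experiment(
    cfg: SimConfig, truth: TrueParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the pooled competition and sequencing readout.

    Returns
    -------
    counts
        mutant x sample table.  Integer when ``nb_dispersion > 0``; exact
        real-valued expected abundances (scaled to depth) when
        ``nb_dispersion == 0``, so noiseless runs are identifiable to
        floating-point precision.
    sample_sheet
        columns sample_id, condition, period_h, day, replicate.
    """
    if len(truth.mutant_ids) != cfg.n_mutants:
        raise ValueError("truth must have one entry per mutant")
    rng = np.random.default_rng(cfg.seed)
    schedules = cfg.schedules()
    if not schedules:
        raise ValueError("no conditions configured")

    cols: dict[str, np.ndarray] = {}
    meta = []
    for sch in schedules:
        for rep in range(1, cfg.n_replicates + 1):
            drift = None
            if cfg.bottlenecks and cfg.nb_dispersion > 0:
                drift = _simulate_drift(cfg, truth, sch, rng)
            for day in cfg.sampling_days:
                sid = f"{sch.condition}_d{day}_r{rep}"
                if drift is not None:
                    mu = drift[day]
                else:
                    mu = _expected_abundance(cfg, truth, sch, day)
                if cfg.nb_dispersion == 0:
                    col = cfg.depth_per_sample * mu / mu.sum()
                else:
                    n_shape = 1.0 / cfg.nb_dispersion
                    lam = rng.negative_binomial(
                        n_shape, n_shape / (n_shape + mu)
                    ).astype(float)
                    tot = lam.sum()
                    if tot == 0:
                        lam[:] = 1.0
                        tot = lam.sum()
                    col = rng.multinomial(
                        int(cfg.depth_per_sample), lam / tot
                    ).astype(float)
                cols[sid] = col
                meta.append(
                    dict(sample_id=sid, condition=sch.condition,
                         period_h=sch.period_h, day=day, replicate=rep)
                )
    counts = pd.DataFrame(cols, index=pd.Index(truth.mutant_ids, name="mutant_id"))
    sheet = pd.DataFrame(meta)
    return counts, sheet


def _simulate_drift(
    cfg: SimConfig, truth: TrueParams, sch: Schedule, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Slot-by-slot population trajectory with dilution bottlenecks
    (binomial thinning at each transfer); returns copy numbers per sampling day."""
    init_gens = cfg.init_h // cfg.transfer_interval_h
    pop = rng.poisson(
        float(cfg.init_copies_per_mutant) * truth.w_N ** init_gens
    ).astype(float)
    out = {0: pop.copy()}
    n_slots = cfg.total_h // cfg.transfer_interval_h
    slots_per_day = 24 // cfg.transfer_interval_h
    keep = cfg.dilution_rates[0]
    for k in range(1, n_slots + 1):
        m = sch.slot_medium(k)
        w = truth.w_N if m == "N" else truth.w_S
        pop = pop * 2.0 * w  # one doubling per slot, modulated by fitness
        pop = rng.binomial(np.maximum(pop.round().astype(np.int64), 0), keep).astype(float)
        if k % slots_per_day == 0:
            out[k // slots_per_day] = pop.copy()
    return out


# ---------------------------------------------------------------------------
# sequence-level emulation


def random_index_codebook(
    n_samples: int | Sequence[str], length: int = 9, min_distance: int = 3,
    seed: int = 0,
) -> dict[str, str]:
    """Random index set with pairwise Hamming distance >= ``min_distance``
    (single-error correction needs >= 3), mapping index -> sample_id."""
    if isinstance(n_samples, int):
        sample_ids = [f"sample{i:03d}" for i in range(n_samples)]
    else:
        sample_ids = list(n_samples)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    tries = 0
    while len(chosen) < len(sample_ids):
        cand = "".join(rng.choice(list("ACGT"), length))
        if all(_hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not build codebook; reduce n or min_distance")
    return dict(zip(chosen, sample_ids))


def random_barcode_library(
    mutant_ids: Sequence[str], length: int = 20, min_distance: int = 3, seed: int = 0
) -> dict[str, str]:
    """Random uptag library, mutant_id -> barcode, pairwise edit distance
    >= ``min_distance`` so distance-1 mapping is unambiguous."""
    import edlib

    rng = np.random.default_rng(seed)
    codes: list[str] = []
    tries = 0
    while len(codes) < len(mutant_ids):
        cand = "".join(rng.choice(list("ACGT"), length))
        ok = all(
            edlib.align(cand, c, k=min_distance - 1)["editDistance"] == -1
            for c in codes
        )
        if ok:
            codes.append(cand)
        tries += 1
        if tries > 200_000:
            raise RuntimeError("could not build barcode library")
    return dict(zip(mutant_ids, codes))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def emit_fastq(
    counts: pd.DataFrame,
    library: dict[str, str],
    codebook: dict[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
    handle=None,
) -> list[str] | None:
    """Emit BAR-Seq-like reads: ``index9 + U1 + uptag + U2`` with uniform
    per-base substitution errors; dummy Phred+33 qualities.

    ``counts`` columns must appear in ``codebook`` values (sample ids) and
    rows in ``library`` keys.  Returns the list of FASTQ lines unless a file
    ``handle`` is given.  Fixed seed => byte-identical output.
    """
    if len(set(library.values())) != len(library):
        raise ValueError("duplicate barcodes in library")
    sample_to_index = {s: idx for idx, s in codebook.items()}
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    read_no = 0
    for sid in counts.columns:
        index = sample_to_index[sid]
        for mid, c in counts[sid].items():
            c = int(round(c))
            if c <= 0:
                continue
            seq = index + U1 + library[mid] + U2
            arr = np.frombuffer(seq.encode(), dtype="S1")
            for _ in range(c):
                read = arr.copy()
                if error_rate > 0:
                    hits = np.nonzero(rng.random(len(read)) < error_rate)[0]
                    for pos in hits:
                        read[pos] = _BASES[rng.integers(4)]
                read_no += 1
                rec = (
                    f"@read{read_no}:{sid}:{mid}\n"
                    + read.tobytes().decode()
                    + "\n+\n" + "I" * len(read) + "\n"
                )
                if handle is None:
                    lines.append(rec)
                else:
                    handle.write(rec)
    return None if handle is not None else lines


# ---------------------------------------------------------------------------
# flow-cytometry emulation


def simulate_cytometry(
    mix_fraction: float,
    n_events: int,
    gfp_modes: tuple[float, float] = (200.0, 800.0),
    seed: int = 0,
    fl1_sd: float = 50.0,
    scatter_center: tuple[float, float] = (480.0, 420.0),
    scatter_sd: float = 45.0,
    outlier_fraction: float = 0.03,
) -> pd.DataFrame:
    """Synthetic cytometry event table (FSC/SSC/FL1 on the 0-1023 scale).

    Scatter channels form one dense Gaussian mode plus uniform outliers; FL1
    is a two-component Gaussian mixture with weight ``mix_fraction`` on the
    GFP-positive (second) mode.  Values are clipped to the instrument range,
    so modes placed at the range edge produce saturated events.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    lo, hi = 0.0, 1023.0
    if not all(lo <= m <= hi for m in gfp_modes):
        raise ValueError("FL1 modes must lie within 0-1023")
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must be a probability")
    rng = np.random.default_rng(seed)
    n_out = int(round(outlier_fraction * n_events))
    n_core = n_events - n_out
    fsc = np.concatenate([
        rng.normal(scatter_center[0], scatter_sd, n_core),
        rng.uniform(lo, hi, n_out),
    ])
    ssc = np.concatenate([
        rng.normal(scatter_center[1], scatter_sd, n_core),
        rng.uniform(lo, hi, n_out),
    ])
    is_pos = rng.random(n_events) < mix_fraction
    fl1 = np.where(
        is_pos,
        rng.normal(gfp_modes[1], fl1_sd, n_events),
        rng.normal(gfp_modes[0], fl1_sd, n_events),
    )
    df = pd.DataFrame({
        "FSC": np.clip(np.round(fsc), lo, hi).astype(int),
        "SSC": np.clip(np.round(ssc), lo, hi).astype(int),
        "FL1": np.clip(np.round(fl1), lo, hi).astype(int),
    })
    df.attrs["true_gfp_positive"] = is_pos
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="mutant_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mutant_id")


def write_sample_sheet_tsv(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
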