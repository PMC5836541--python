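# Methods

## Experimental design being modelled

A pooled library of barcoded deletion mutants is propagated by robotic serial
dilution on a 3-h transfer grid (one generation per slot, eight per day),
after a 6-h initialization in the permissive medium N. Regimes are steady N,
steady S, or alternation between N and S with period 6, 12, 18, 24 or 42 h
(each half-period a whole number of slots). Four replicate populations run
per condition; populations are sampled at days 0–3 and barcodes sequenced to
~10⁶ reads per sample. Analysis is phase-agnostic; the generator exposes
`first_condition` (default S — the first switch follows immediately on the
N initialization) because the downstream covariates only depend on the slot
sequence.

### Schedule algebra

For condition c and day d, slots 1..8d are enumerated; `t_N`/`t_S` are summed
slot durations (`t_N + t_S = 24d` always) and `N_changes` counts medium
switches at the end boundary of each slot in (0, 24d] (comparing slot k with
slot k+1). Under this convention the 6-h period gives 8 changes on day 1 and
the 42-h period (half-period 21 h, starting in S) gives switches at 21, 42
and 63 h by day 3, with exposures (t_S, t_N) = (42, 30) h. The alternative
convention that also counts the day-0 switch only rescales β3's covariate by
a constant and does not affect its test.

Time fractions f_N = t_N/24d, f_S = 1 − f_N. For the symmetric periods
(6–24 h) these are exactly 0.5 at day 3; the 42-h period gives f_N = 30/72.

## Synthetic data generator

Expected copies of mutant i at day d of condition c:

μ_i(c, d) = n₀ · w_N,i^{g_N} · w_S,i^{g_S} · exp(β3,i · N_changes(c, d)),

with g_N = t_N/3 generations in N (etc.), n₀ = 320 initial copies, and the
6-h initialization included (it cancels in every frequency ratio). The
per-change log increment β3 is exactly the alternative hypothesis of the
downstream GLM; a mechanistic alternative (`lag_penalty`: the first slot
after each switch grows at a penalized exponent) is provided for robustness
tests, and per-slot dilution bottlenecks (85/55/32% kept, by transfer type)
are available behind `bottlenecks=True` (default off — the estimators ignore
them).

Sequencing noise: per-mutant NB draws with Var = μ + αμ² (α shared across
mutants, default 0.01 — typical technical overdispersion for amplicon
counting), then multinomial rescaling to the sample depth (default 10⁶) so
column totals are controlled. With α = 0 the generator emits exact expected
abundances as real numbers — no NB draw, no multinomial, no rounding — so
noiseless runs are identifiable to floating-point precision; with noise on,
counts are integers. Fixed seeds reproduce byte-identical outputs.

Effects should be planted in a minority of genes. Counts are relative
abundances: an effect shared by most of the pool is absorbed by any
normalization and is not identifiable (with random ± signs at high
prevalence the median-of-ratios factor is bimodal and unstable). The
defaults keep ≤ ~20% of genes non-null, as in real pools.

The generator also emits reads (`index9 + U1 + uptag + U2`, uniform
substitution errors, Phred+33 dummy qualities) for the sequence-level path,
and flow-cytometry event tables (FSC/SSC single dense mode plus uniform
outliers, bimodal FL1, clipped to the 0–1023 instrument range). What it does
**not** emulate: PCR amplification bias and duplicates, GC/length effects,
index hopping, chimeric reads, batch effects, frequency-dependent fitness and
de-novo mutation. Passing tests therefore show the estimators are correct
under the stated stochastic model, not that real libraries are free of these
artefacts.

## Demultiplexing

Sample indices are 9-nt words from a codebook with pairwise Hamming
distance ≥ 3, so every single substitution has a unique nearest codeword;
`decode_index` accepts distance ≤ 1 and returns UNASSIGNED otherwise. The
exact index set used by any given experiment is user-supplied (a generator
for valid codebooks ships with the simulator). Barcodes are located by flank
matching (≤ 1 mismatch in each of U1/U2 — tolerant of the one-base shift a
single indel implies) and mapped at Levenshtein distance ≤ 1 via edlib;
reads equidistant from two barcodes are dropped rather than guessed, trading
a little yield for freedom from systematic misassignment between
near-identical tags. Conservation (assigned + unassigned + unmapped = total)
is enforced by construction and tested.

## Normalization

Median-of-ratios size factors against the geometric-mean pseudo-reference,
then a parametric NB variance-stabilizing transform: gene-wise moment
dispersions (within condition × day replicate groups when a sample sheet is
given) are regressed on 1/μ to fit α(μ) = a₁/μ + a₀, and

vst(x) = log2[(1 + a₁ + 2a₀x + 2√(a₀x(1 + a₁ + a₀x))) / (4a₀)],

which is strictly monotone and asymptotically log2-linear. When the fitted
asymptotic dispersion a₀ is below 10⁻⁴ the transform degenerates (its
argument is dominated by the constant term), so the implementation falls
back to log2(x/sf + 0.5) and records the method. Downstream stages consume
the size-factor-scaled counts (`NormTable.scaled`); the VST surface exists
for inspection and plotting. The fitness estimator is a within-sample ratio
of ratios, so it is invariant to per-sample scaling altogether.

## Fitness estimation

w = ((M_e/M_b)/(WT_e/WT_b))^{1/g} with g = 24 (day 0 → day 3 endpoints;
per-day endpoints behind a flag), WT the summed count-scale abundance of the
neutral reference set, and replicate pairing by population identity. Zero
abundances receive a pseudo-abundance of 0.5 on the count scale (logged by
the clip; the original zero policy is unstated, and at the depths involved
zeros essentially only occur for strongly depleted mutants). A
condition-specific g (`g_by_condition`) accommodates a slower doubling time
under stress for robustness checks; it rescales w_S smoothly and leaves the
inhomogeneity ranking essentially unchanged.

Noiseless identifiability is exact (≤ 10⁻⁶ relative, measured ~10⁻¹⁶). At
depth 10⁶ and α = 0.01, per-replicate w has ~0.6% noise. One caveat worth
knowing: the artificial WT built from 11 neutral genes carries its own
sampling noise (CV ≈ √(α/11) per sample), which shifts *all* mutants of a
run coherently by ~0.1–0.2%. Estimator bias is therefore measured on
mutant-level errors pooled across independent simulations (median bias
≈ 10⁻⁴, well under the 0.002 budget); a single run's median reflects that
run's WT draw as much as the estimator.

## Time-average null and the GLM

w_exp = w_N^{f_N} · w_S^{f_S} (day-3 fractions), dev = w_obs/w_exp. For genes
simulated under the null, dev ∈ [0.99, 1.01] for ≥ 95% of genes at depth 10⁶
(measured 97–98%).

Statistical inference uses the count trajectories directly: one NB GLM per
mutant and oscillating period, pooling that period's samples with steady N
and S (days 0–3, all replicates, ~48 samples per fit):

log λ = offset_c + β1·t_N + β2·t_S + β3·N_changes,  y ~ NB(λ, α).

Design choices that matter:

- **Offsets.** `offset_mode="estimate"` (default) fits offset_c as free
  per-condition intercepts. The alternative `"day0_median"` fixes offset_c at
  the log median of the mutant's day-0 normalized counts (coefficient 1, not
  estimated). The fixed variant propagates the sampling noise of a median of
  four counts as a coherent per-condition lack of fit and makes the β3 Wald
  test strongly anti-conservative under the generative model (~35% of null
  genes at p < 0.05); the estimated variant is calibrated (~5%). Both modes
  agree on strongly inhomogeneous genes (tested); the default buys
  calibration at the cost of 2–3 extra parameters.
- **Dispersion.** α is per-mutant, re-estimated alternately with the IRLS
  coefficient fit by solving Pearson χ² = residual df (floored at 10⁻⁸).
  The df correction matters: profile ML at the fitted mean ignores the 5–6
  estimated mean parameters and is biased low, leaving the test mildly
  anti-conservative (~7% at nominal 5%). Plain profile ML is kept as an
  internal reference.
- **Test.** Wald with a t reference on residual df (small-sample correction;
  LRT behind `use_lrt=True`). Measured on 1,000-gene null simulations:
  KS p-values 0.15–0.95 across seeds, 4.9–6.5% of genes at p < 0.05.
- **Fitting scale.** Normalized counts are rounded to integers on the
  size-factor scale. A robustness test confirms call stability versus the
  alternative offset parametrization.
- Non-convergent fits are flagged (`converged=False`) and excluded from FDR
  calling.

Power: a planted β3 = 0.05 in ~20% of a 1,000-gene pool is recovered with
mean estimate ≈ 0.046 (within the ±0.005 budget; the ~8% shrinkage is the
residual compositional absorption of a 20%-prevalent effect) and 100% sign
agreement. At the 42-h period only 3 changes accumulate by day 3, so power
there is intrinsically low — a property of the design, not the estimator.

q-values use Storey's estimator with a cubic-spline smoother for π0 over the
λ grid 0.05–0.95, clamped to (0, 1]; when the spline gives an unusable π0
the implementation falls back to Benjamini–Hochberg (π0 = 1). Unstated in
the original: the smoothing span; the spline's default smoothing is used and
the choice only rescales q-values by a constant factor π0.

## Genetic variance

V_T = (1/M) ΣΣ (w_ij − w̄)², V_E = (1/M) ΣΣ (w_ij − w̄_i)², V_G = V_T − V_E,
population divisors with M the total observation count (ragged replicate
counts supported). This V_G equals the population variance of the per-mutant
means in the balanced case — which under pure replicate noise has
expectation σ_E²/R, not zero. The implementation therefore also reports
`V_G_corrected` = V_G − σ̂_E²·mean(1/R_i)·(N−1)/N with σ̂_E² the
Bessel-corrected replicate variance; the corrected estimator is zero-centred
under an i.i.d.-noise null (bootstrap CI covers 0 in 92–94% of runs,
measured) while the uncorrected one reproduces the printed definition. Both
get 95% percentile bootstrap CIs from 1,000 resamples of mutants.

## Selection calls

**Antagonistic pleiotropy.** Three (w_N, w_S) pairs per mutant (one of four
w_S discarded uniformly at random, seeded; pairing by index). A pair supports
AP iff the signs disagree around 1 AND the pair's Mahalanobis distance under
the bivariate Gaussian fitted by ML to all pooled pairs is strictly > 2
("two standard deviations from the model" read in Mahalanobis units, which
respects the correlated w_N–w_S cloud; a per-axis variant exists for
sensitivity analysis). A mutant is AP iff all three pairs support it;
magnitude is the mean w_N/w_S. On a standard bivariate normal the >2 rule
captures e^(−2) ≈ 13.5% of points (χ²₂ tail) — the planted-AP fixture
(bulk SD 0.02, effect ±0.1, replicate SD 0.01) is detected at 100%
sensitivity with a permutation expectation of ~0.06 calls.

**Permutation nulls** reassign observations across mutants while preserving
the per-mutant observation counts (3 pairs / 4 replicates), so null and
observed statistics are directly comparable. The Gaussian bulk is fitted
once on the pooled pairs (it is permutation-invariant). For transgressivity
the oscillating-regime replicate values are permuted while each mutant's
steady-condition envelope stays fixed.

**Direction and period dependence.** Per period: positive if w̄ − σ > 1,
negative if w̄ + σ < 1, else ambiguous; overall label "unclear" when
ambiguous at ≥ 4 of the 5 periods, "always positive/negative" when all
unambiguous directions agree, "period dependent" otherwise.

**Transgressivity.** "High" when ≥ 3 of 4 oscillating replicates exceed
max(w̄_N + σ_N, w̄_S + σ_S); "low" symmetrically below the minimum;
antisymmetric under w → 1/w (tested).

## Cytometry

Gating removes saturated events (any channel ≤ 0 or ≥ 1023), rejects samples
with < 2,000 events, and keeps the 40% of events with the highest Gaussian-KDE
density on (FSC, SSC) — the upper level set whose mass is closest to 0.40;
"perimeter of peak density" is read as a density contour, not a convex hull.
Samples retaining ≤ 4,000 gated events are rejected (note this floor means
usable samples need > 10,000 acquired events). For tractability the KDE is
fitted on a 2,000-event subsample strided over a canonically sorted copy
(order-invariant) and evaluated on all events. The GFP threshold is the
deepest valley of a 1-D KDE of FL1 between the two highest modes; unimodal
samples raise a flag for control handling. Fitness from (GFP−, GFP+) counts
at begin/end reuses the pooled-assay estimator verbatim (one
implementation, tested for agreement). Classification error for 6-SD-
separated modes is < 1% (measured ~0.3%); estimated mix fractions are
unbiased within binomial error.

## Problem sizes and seeds

The test-suite and acceptance-script simulations use 100–1,000 mutants,
depth 10⁶, 4 replicates, NB α = 0.01 — chosen as the package's standard
verification conditions (calibration checks use 1,000-gene nulls; bias is
pooled over 5 runs; permutation/bootstrap counts 100–1,000). All randomness
flows through explicit integer seeds; fixed seeds give byte-identical
simulator output and bit-reproducible analyses.

## Known limitations

- The GLM treats replicates as exchangeable NB draws; shared environmental
  shocks within a replicate population (the ε term in a random-effects
  reading) are absorbed into α rather than modelled.
- The artificial-WT reference is assumed strictly neutral; mild
  non-neutrality of the reference set shifts all w coherently.
- Compositional identifiability: pool-wide effects are invisible; effect
  estimates shrink by roughly the prevalence of the affected genes.
- Permutation nulls assume exchangeability of observations across mutants
  under the null; heavy-tailed fitness distributions make the
  transgressivity null conservative.
- The demultiplexer ignores base qualities and paired-end information;
  downtags are out of scope.
- No batch-effect or spike-in normalization; no frequency-dependent fitness.
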