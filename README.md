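# pulsefit

Tools for analysing pooled fitness competitions of barcoded mutant libraries
under steady and periodically fluctuating environments, with a forward
simulator that generates every input the pipeline consumes.

## The problem

When a genome-wide pool of barcoded deletion mutants (e.g. the yeast deletion
collection) is propagated by serial dilution while the medium alternates
between two conditions N and S (say, no salt / 0.2 M NaCl, switching with
period 6–42 h on a 3-h transfer grid), does each mutant's proliferation rate
in the fluctuating regime follow from its rates in the two steady conditions —
or does the *dynamics* of the environment itself select? `pulsefit`
implements the full analysis chain for this question:

1. **Demultiplexing** — 9-nt sample indices decoded with single-error
   Hamming correction; uptag barcodes located between the universal flanks
   U1/U2 and mapped to mutants tolerating one edit (ambiguous hits dropped).
2. **Count processing** — sample filters (total-count floor 300,000 plus
   replicate-correlation check), mutant filter (≥ 2,000 counts overall),
   missing day-0 imputation by donor medians, median-of-ratios size factors
   and a parametric negative-binomial variance-stabilizing transform.
3. **Fitness estimation** — per replicate, against an "artificial wild type"
   (the pooled counts of a configurable set of neutral deletion strains):

   `w = ((M_e/M_b) / (WT_e/WT_b))^(1/g)`,   g = 24 generations (day 0 → 3).

4. **Time-average (homogenization) null** — expected fitness under a
   fluctuating regime is the time-weighted geometric mean
   `w_exp = w_N^f_N · w_S^f_S`; the inhomogeneity ratio is
   `dev = w_obs / w_exp`.
5. **Inhomogeneity GLM** — per mutant and oscillation period, normalized
   counts are modelled as NB(λ, α) with
   `log λ = offset_c + β1·t_N + β2·t_S + β3·N_changes`;
   under homogenized fitness the change count carries no information
   (β3 = 0), so inhomogeneity is the significance of β3 (Wald t test,
   q-values across genes; Storey's π0 with BH fallback).
6. **Genetic variance** — `V_G = V_T − V_E` per condition with bootstrap CIs
   over mutants (population-divisor estimator plus a replicate-noise-corrected
   variant that is zero-centred under a pure-noise null).
7. **Selection calls** — antagonistic pleiotropy (sign-discordant (w_N, w_S)
   pairs that are Mahalanobis-distance > 2 outliers of the bivariate-Gaussian
   bulk, 3-of-3 replicate rule) and transgressive fitness (3-of-4 oscillating
   replicates beyond the steady-condition envelope), each with a permutation
   null preserving the per-mutant replicate structure.
8. **Cytometry assays** — the individual-competition route: saturation
   removal, 40% peak-density gating on FSC/SSC, automatic GFP threshold at
   the FL1 density valley, and the same fitness estimator on GFP−/GFP+
   counts.

It is aimed at experimental-evolution and functional-genomics groups running
BAR-Seq-style pooled competitions, and at method developers who need a
ground-truthed synthetic test bed for count-based fitness inference.

## Worked example

The numbered scripts under `analysis/` form the narrative pipeline; each
writes its tables under `results/`:

```bash
python analysis/01_simulate_pool.py
python analysis/03_fitness_homogenization.py
python analysis/04_inhomogeneity_glm.py
```

Output of the run bundled as the default configuration (500 mutants of which
73 carry a planted per-change effect of |β3| = 0.05, 112 samples, depth 10⁶,
NB dispersion 0.01):

```
simulated 500 mutants x 112 samples (73 genes carry an inhomogeneity effect)
500 mutants passed QC (0 samples discarded); median |w_N error| = 0.0026
NS6: f_N=0.500; dev in [0.99,1.01] for 98.1% of homogenized genes
NS42: f_N=0.417; dev in [0.99,1.01] for 98.1% of homogenized genes
NS6: 80 called at FDR 0.05 (sensitivity 100.0%, realized FDR 8.8%)
NS24: 55 called at FDR 0.05 (sensitivity 69.9%, realized FDR 7.3%)
NS42: 2 called at FDR 0.05 (sensitivity 2.7%, realized FDR 0.0%)
```

Read: per-replicate fitness is recovered to ~0.3% at this depth; genes
simulated under the time-average null stay within 1% of dev = 1; the GLM
detects essentially every planted effect at short periods, while power decays
toward the 42-h period because only 3 medium changes accumulate in 3 days —
the covariate the test keys on barely varies.

The same stages are scriptable through the CLI (`pulsefit simulate|demux|
process|fitness|glm|select|cyto|run`), e.g.

```bash
pulsefit simulate --n-mutants 200 --seed 1 --out-dir run1
pulsefit glm --counts run1/counts.tsv --samplesheet run1/sample_sheet.tsv \
         --period 6 --fdr 1e-4 --out run1/glm_NS6.tsv
```

## Layout

```
src/pulsefit/      schedule, synthetic, demux, processing, fitness, glm,
                   selection, cytometry, pipeline, cli
analysis/          numbered narrative drivers (simulate → ... → cytometry)
tests/             pytest suite incl. end-to-end property checks
docs/methods.md    models, estimators, numerical choices, limitations
```
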