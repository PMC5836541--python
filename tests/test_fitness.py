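import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pulsefit.fitness import (
    artificial_wt,
    dev_table,
    estimate_fitness,
    expected_fitness,
    fitness,
    fitness_matrix,
    genetic_variance,
    inhomogeneity,
)
from pulsefit.processing import normalize
from pulsefit.synthetic import SimConfig, TrueParams, simulate_experiment


class TestFitnessEstimator:
    def test_no_relative_change_gives_one(self):
        assert fitness(0.1, 0.2, 0.3, 0.6) == pytest.approx(1.0)

    def test_relative_doubling_over_24_generations(self):
        w = fitness(0.1, 0.2, 0.4, 0.4, g=24)
        assert w == pytest.approx(2 ** (1 / 24))
        assert w == pytest.approx(1.0293, abs=1e-4)

    def test_halving_is_reciprocal_of_doubling(self):
        up = fitness(0.1, 0.2, 0.4, 0.4)
        down = fitness(0.2, 0.1, 0.4, 0.4)
        assert up * down == pytest.approx(1.0)
        assert down == pytest.approx(0.9715, abs=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 10),
           st.floats(0.01, 10), st.floats(0.1, 100))
    def test_scale_invariance(self, mb, me, wb, we, k):
        """Multiplying all abundances of a sample by a constant leaves w fixed."""
        assert fitness(mb * k, me, wb * k, we) == pytest.approx(
            fitness(mb, me, wb, we), rel=1e-9)
        assert fitness(mb, me * k, wb, we * k) == pytest.approx(
            fitness(mb, me, wb, we), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fitness(0.0, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            fitness(0.1, 0.1, 0.1, 0.1, g=0)


class TestExpectedFitnessAndDev:
    def test_equal_fitness_passes_through(self):
        assert expected_fitness(1.07, 1.07, 0.5, 0.5) == pytest.approx(1.07)

    def test_weighted_geometric_mean(self):
        assert expected_fitness(1.1, 0.9, 0.5, 0.5) == pytest.approx(
            np.sqrt(0.99))
        assert expected_fitness(1.1, 0.9, 0.5, 0.5) == pytest.approx(
            0.99499, abs=1e-5)

    def test_degenerate_fraction(self):
        assert expected_fitness(1.1, 0.9, 1.0, 0.0) == pytest.approx(1.1)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            expected_fitness(1.0, 1.0, 0.5, 0.6)

    def test_dev_identity_and_antisymmetry(self):
        assert inhomogeneity(1.05, 1.05) == pytest.approx(1.0)
        assert inhomogeneity(1.05, 1.00) == pytest.approx(1.05)
        a, b = 1.07, 0.93
        assert inhomogeneity(a, b) == pytest.approx(1 / inhomogeneity(b, a))


class TestArtificialWT:
    def test_single_neutral_equals_its_trace(self, noiseless_run):
        _, truth, counts, sheet = noiseless_run
        norm = normalize(counts, sheet)
        one = truth.neutral_ids[0]
        wt = artificial_wt(norm, [one])
        assert np.allclose(wt.values, norm.scaled.loc[one].values)

    def test_two_equal_neutrals_double_the_trace(self, noiseless_run):
        _, truth, counts, sheet = noiseless_run
        norm = normalize(counts, sheet)
        a, b = truth.neutral_ids[:2]   # neutral => identical noiseless traces
        wt = artificial_wt(norm, [a, b])
        assert np.allclose(wt.values, 2 * norm.scaled.loc[a].values)

    def test_missing_neutral_set_is_error(self, noiseless_run):
        _, _, counts, sheet = noiseless_run
        norm = normalize(counts, sheet)
        with pytest.raises(ValueError):
            artificial_wt(norm, ["nonexistent"])


class TestEstimateFitness:
    def test_noiseless_recovery_is_exact(self, noiseless_run):
        _, truth, counts, sheet = noiseless_run
        norm = normalize(counts, sheet)
        fl = estimate_fitness(norm, sheet, truth.neutral_ids)
        wN = fitness_matrix(fl, "N").mean(axis=1)
        assert np.max(np.abs(wN.values / truth.w_N - 1)) < 1e-6
        wS = fitness_matrix(fl, "S").mean(axis=1)
        assert np.max(np.abs(wS.values / truth.w_S - 1)) < 1e-6

    def test_all_neutral_pool_gives_unit_fitness(self):
        cfg = SimConfig(n_mutants=30, periods=(6,), depth_per_sample=1e6,
                        nb_dispersion=0.005, seed=7)
        truth = TrueParams.neutral(30)
        counts, sheet = simulate_experiment(cfg, truth)
        fl = estimate_fitness(normalize(counts, sheet), sheet, truth.neutral_ids)
        assert fl["w"].median() == pytest.approx(1.0, abs=0.01)

    def test_ragged_replicates_are_skipped_not_fatal(self, noiseless_run):
        _, truth, counts, sheet = noiseless_run
        # discard N replicate 4 day 3 (as when one sample fails QC)
        drop = sheet.query("condition == 'N' and day == 3 and replicate == 4")
        counts2 = counts.drop(columns=drop["sample_id"].tolist())
        norm = normalize(counts2, sheet)
        fl = estimate_fitness(norm, sheet, truth.neutral_ids)
        wN = fitness_matrix(fl, "N")
        assert wN.shape[1] == 3
        wNS = fitness_matrix(fl, "NS6")
        assert wNS.shape[1] == 4

    def test_homogenized_genes_have_unit_dev(self, noiseless_run):
        _, truth, counts, sheet = noiseless_run
        norm = normalize(counts, sheet)
        fl = estimate_fitness(norm, sheet, truth.neutral_ids)
        dv = dev_table(fl, "NS6", 0.5, 0.5)
        assert np.allclose(dv["dev"].values, 1.0, atol=1e-9)


class TestGeneticVariance:
    def _brute(self, W):
        """Independent loop-based oracle for the printed formulas."""
        N, R = W.shape
        wbar = W.mean()
        vt = sum((W[i, j] - wbar) ** 2 for i in range(N) for j in range(R))
        ve = sum((W[i, j] - W[i].mean()) ** 2 for i in range(N) for j in range(R))
        return vt / (N * R), ve / (N * R)

    def test_matches_brute_force(self, rng):
        W = rng.normal(1.0, 0.05, (25, 3))
        vd = genetic_variance(W, n_bootstrap=10, seed=0)
        vt, ve = self._brute(W)
        assert vd.V_T == pytest.approx(vt)
        assert vd.V_E == pytest.approx(ve)
        assert vd.V_G == pytest.approx(vt - ve)

    def test_identical_replicates_have_no_environmental_variance(self, rng):
        means = rng.normal(1.0, 0.1, 40)
        W = np.repeat(means[:, None], 3, axis=1)
        vd = genetic_variance(W, n_bootstrap=10, seed=0)
        assert vd.V_E == pytest.approx(0.0, abs=1e-18)
        assert vd.V_G == pytest.approx(vd.V_T)

    def test_known_genetic_spread_recovered(self, rng):
        N = 1000
        means = rng.normal(1.0, 0.1, N)
        W = np.repeat(means[:, None], 3, axis=1)
        vd = genetic_variance(W, n_bootstrap=50, seed=0)
        pop_var = means.var()  # population variance of the sampled means
        assert vd.V_G == pytest.approx(pop_var, rel=1e-9)

    def test_shift_invariance(self, rng):
        W = rng.normal(1.0, 0.05, (30, 3))
        a = genetic_variance(W, n_bootstrap=5, seed=1)
        b = genetic_variance(W + 0.37, n_bootstrap=5, seed=1)
        assert a.V_G == pytest.approx(b.V_G)

    def test_ragged_replicates_allowed(self, rng):
        W = rng.normal(1.0, 0.05, (20, 4))
        W[:5, 3] = np.nan
        vd = genetic_variance(W, n_bootstrap=5, seed=0)
        assert np.isfinite(vd.V_G)

    def test_single_mutant_is_error(self):
        with pytest.raises(ValueError):
            genetic_variance(np.ones((1, 3)))
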