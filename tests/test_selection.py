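import numpy as np
import pytest

from pulsefit.selection import (
    call_AP,
    call_AP_table,
    call_transgressive,
    call_transgressive_table,
    classify_direction,
    fit_bivariate_gaussian,
    pair_replicates,
    permutation_null_AP,
    permutation_null_transgressivity,
)


def _planted_dataset(rng, n_bulk=200, n_ap=10, bulk_sd=0.02, rep_sd=0.01):
    """Bulk of neutral mutants around (1, 1) plus planted AP mutants at
    (1.1, 0.9) — the stated planted-AP fixture."""
    pairs = {}
    for i in range(n_bulk):
        centre = rng.normal(1.0, bulk_sd, 2)
        pairs[f"bulk{i}"] = centre + rng.normal(0, rep_sd, (3, 2))
    for i in range(n_ap):
        pairs[f"ap{i}"] = np.array([1.1, 0.9]) + rng.normal(0, rep_sd, (3, 2))
    return pairs


class TestPairReplicates:
    def test_identical_surplus_values_pairing_invariant(self):
        out = pair_replicates([1.0, 1.1, 0.9], [1.2] * 4, seed=0)
        assert out.shape == (3, 2)
        assert (out[:, 1] == 1.2).all()

    def test_fixed_seed_reproducible(self):
        a = pair_replicates([1, 2, 3], [4, 5, 6, 7], seed=11)
        b = pair_replicates([1, 2, 3], [4, 5, 6, 7], seed=11)
        assert (a == b).all()

    def test_each_surplus_value_discarded_uniformly(self):
        w_s = np.array([4.0, 5.0, 6.0, 7.0])
        dropped = np.zeros(4)
        n = 10_000
        for seed in range(n):
            kept = pair_replicates([1, 2, 3], w_s, seed=seed)[:, 1]
            (missing,) = set(w_s) - set(kept)
            dropped[int(missing) - 4] += 1
        assert np.allclose(dropped / n, 0.25, atol=0.02)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            pair_replicates([1.0], [1.0, 2.0], seed=0)


class TestBivariateGaussian:
    def test_chi2_tail_fraction_beyond_two(self, rng):
        """P(Mahalanobis > 2) = exp(-2) ~ 13.5% for a bivariate normal."""
        pts = rng.standard_normal((10_000, 2))
        model = fit_bivariate_gaussian(pts)
        frac = (model.mahalanobis(pts) > 2).mean()
        assert frac == pytest.approx(np.exp(-2), abs=0.01)

    def test_mean_point_has_zero_distance(self, rng):
        pts = rng.standard_normal((500, 2)) + [3.0, -1.0]
        model = fit_bivariate_gaussian(pts)
        assert model.mahalanobis(model.mean[None, :])[0] == pytest.approx(0.0)

    def test_boundary_distance_two_is_not_outlier(self):
        """Strict > 2 convention: a point at exactly 2 SD is kept."""
        from pulsefit.selection import _pair_supports_ap, GaussianModel

        model = GaussianModel(np.array([1.0, 1.0]), np.eye(2) * 0.01)
        at_two = np.array([[1.2, 1.0]])  # distance exactly 2.0
        assert model.mahalanobis(at_two)[0] == pytest.approx(2.0)
        assert not _pair_supports_ap(np.array([[1.2, 0.99]]), model)[0] or \
            model.mahalanobis(np.array([[1.2, 0.99]]))[0] > 2

    def test_singular_covariance_rejected(self):
        pts = np.repeat([[1.0, 2.0]], 10, axis=0)
        with pytest.raises(ValueError):
            fit_bivariate_gaussian(pts)


class TestAPCalls:
    def test_planted_ap_mutants_called_with_high_sensitivity(self, rng):
        pairs = _planted_dataset(rng)
        tab = call_AP_table(pairs)
        planted = tab.loc[[m for m in tab.index if m.startswith("ap")]]
        assert planted["is_AP"].mean() >= 0.95
        assert planted["magnitude"].mean() == pytest.approx(1.1 / 0.9, abs=0.05)

    def test_pair_with_both_advantages_breaks_the_call(self, rng):
        pairs = _planted_dataset(rng, n_ap=1)
        pairs["ap0"][0] = [1.1, 1.1]   # advantage in both => not AP
        tab = call_AP_table(pairs)
        assert not tab.loc["ap0", "is_AP"]

    def test_sign_ok_but_inside_bulk_not_called(self, rng):
        pairs = _planted_dataset(rng, n_ap=0)
        pairs["subtle"] = np.array([[1.003, 0.997]] * 3)  # inside 2-SD ellipse
        tab = call_AP_table(pairs)
        assert not tab.loc["subtle", "is_AP"]

    def test_call_invariant_to_mutant_relabeling(self, rng):
        pairs = _planted_dataset(rng, n_bulk=50, n_ap=3)
        tab1 = call_AP_table(pairs)
        renamed = {f"x_{k}": v for k, v in pairs.items()}
        tab2 = call_AP_table(renamed)
        assert tab1["is_AP"].sum() == tab2["is_AP"].sum()


class TestAPPermutationNull:
    def test_null_far_below_planted_count(self, rng):
        pairs = _planted_dataset(rng)
        tab = call_AP_table(pairs)
        observed = tab["is_AP"].sum()
        expected, _ = permutation_null_AP(pairs, n_perm=200, seed=3)
        assert observed >= 9
        assert expected < 0.05 * observed

    def test_exchangeable_data_matches_observed(self, rng):
        """With i.i.d. observations across mutants, permuting cannot change
        the expected call count."""
        pairs = {f"m{i}": rng.normal(1.0, 0.05, (3, 2)) for i in range(150)}
        tab = call_AP_table(pairs)
        observed = tab["is_AP"].sum()
        expected, counts = permutation_null_AP(pairs, n_perm=300, seed=4)
        # the observed count is itself one draw from the null, so compare on
        # the scale of the null count's SD
        sd = counts.std(ddof=1)
        assert abs(expected - observed) <= max(2 * sd, 2.0)

    def test_single_permutation_reproducible(self, rng):
        pairs = {f"m{i}": rng.normal(1.0, 0.05, (3, 2)) for i in range(20)}
        e1, c1 = permutation_null_AP(pairs, n_perm=1, seed=9)
        e2, c2 = permutation_null_AP(pairs, n_perm=1, seed=9)
        assert e1 == e2 and (c1 == c2).all()

    def test_invalid_inputs(self, rng):
        pairs = {f"m{i}": rng.normal(1.0, 0.05, (3, 2)) for i in range(5)}
        with pytest.raises(ValueError):
            permutation_null_AP(pairs, n_perm=0)
        with pytest.raises(ValueError):
            permutation_null_AP({"only": pairs["m0"]}, n_perm=10)


class TestDirectionClassification:
    def test_clear_positive(self):
        per, _ = classify_direction({6: np.array([1.04, 1.05, 1.06])})
        assert per[6] == "positive"

    def test_noisy_is_ambiguous(self):
        per, _ = classify_direction({6: np.array([0.95, 1.05, 1.15])})
        assert per[6] == "ambiguous"

    def test_clear_negative(self):
        per, _ = classify_direction({6: np.array([0.94, 0.95, 0.96])})
        assert per[6] == "negative"

    def test_mixed_directions_are_period_dependent(self):
        w = {
            6: np.array([1.04, 1.05, 1.06]),     # positive
            12: np.array([1.04, 1.05, 1.06]),    # positive
            18: np.array([0.9, 1.1, 1.0]),       # ambiguous
            24: np.array([0.94, 0.95, 0.96]),    # negative
            42: np.array([0.9, 1.1, 1.0]),       # ambiguous
        }
        _, label = classify_direction(w)
        assert label == "period_dependent"

    def test_mostly_ambiguous_is_unclear(self):
        w = {p: np.array([0.9, 1.1]) for p in (6, 12, 18, 24)}
        w[42] = np.array([1.04, 1.05, 1.06])
        _, label = classify_direction(w)
        assert label == "unclear"

    def test_agreeing_directions(self):
        w = {p: np.array([1.04, 1.05, 1.06]) for p in (6, 12)}
        w[18] = np.array([0.9, 1.1])
        _, label = classify_direction(w)
        assert label == "always_positive"


class TestTransgressivity:
    def test_three_of_four_above_envelope_is_high(self):
        c = call_transgressive("m", [1.02, 1.03, 1.02, 0.99],
                               np.array([1.0] * 4), np.array([0.95] * 4))
        assert c.direction == "high" and c.n_supporting == 3

    def test_inside_envelope_is_none(self):
        c = call_transgressive("m", [1.0, 1.0, 1.0, 1.0],
                               np.array([0.98, 1.02, 1.0, 1.0]),
                               np.array([0.93, 0.97, 0.95, 0.95]))
        assert c.direction == "none"

    def test_direction_flips_under_fitness_inversion(self, rng):
        """Antisymmetry: w -> 1/w maps high calls to low calls."""
        w_ns = np.array([1.06, 1.07, 1.06, 1.05])
        w_n = np.array([1.0, 1.01, 0.99, 1.0])
        w_s = np.array([0.95, 0.96, 0.94, 0.95])
        up = call_transgressive("m", w_ns, w_n, w_s)
        down = call_transgressive("m", 1 / w_ns, 1 / w_n, 1 / w_s)
        assert up.direction == "high" and down.direction == "low"

    def test_too_few_replicates_gives_none(self):
        c = call_transgressive("m", [1.5, 1.5], np.ones(4), np.ones(4))
        assert c.direction == "none"

    def test_zero_variance_null_expectation_is_zero(self):
        d_ns = {f"m{i}": np.ones(4) for i in range(10)}
        d_n = {f"m{i}": np.ones(4) for i in range(10)}
        d_s = {f"m{i}": np.ones(4) for i in range(10)}
        expected, _ = permutation_null_transgressivity(d_ns, d_n, d_s,
                                                       n_perm=20, seed=0)
        assert expected == 0.0

    def test_exchangeable_null_matches_observed(self, rng):
        d_ns, d_n, d_s = {}, {}, {}
        for i in range(150):
            d_ns[f"m{i}"] = rng.normal(1.0, 0.03, 4)
            d_n[f"m{i}"] = rng.normal(1.0, 0.03, 4)
            d_s[f"m{i}"] = rng.normal(1.0, 0.03, 4)
        tab = call_transgressive_table(d_ns, d_n, d_s)
        observed = (tab["direction"] != "none").sum()
        expected, counts = permutation_null_transgressivity(
            d_ns, d_n, d_s, n_perm=100, seed=5)
        sd = counts.std(ddof=1)
        assert abs(expected - observed) <= max(2 * sd, 2.0)

    def test_permutation_reproducible(self, rng):
        d = {f"m{i}": rng.normal(1.0, 0.05, 4) for i in range(10)}
        e1, _ = permutation_null_transgressivity(d, d, d, n_perm=5, seed=2)
        e2, _ = permutation_null_transgressivity(d, d, d, n_perm=5, seed=2)
        assert e1 == e2
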