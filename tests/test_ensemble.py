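import numpy as np
import pytest

from saxsemble.ensemble import (EnsembleSolution, brute_force_select,
                                compact_fraction, ensemble_average_profile,
                                rg_distribution, ses_select)
from saxsemble.saxscalc import SaxsProfile
from saxsemble.structmodel import ResidueSet


def decoy_pool(rng, q, n, return_params=False):
    """Smooth decaying decoy profiles with varied apparent size."""
    params = rng.uniform(100, 900, size=n)
    profiles = np.array([(1 + rng.random()) * np.exp(-q ** 2 * p / 3.0)
                         + 0.01 * rng.random() for p in params])
    return (profiles, params) if return_params else profiles


class TestSesSelect:
    def test_perfect_match_recovery(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 0.4, 100)
        pool = decoy_pool(rng, q, 100)
        exp = SaxsProfile(q, pool[42], sigma=0.01 * pool[42])
        sol = ses_select(pool, exp, k_max=5, seed=1)
        assert sol.K == 1
        assert sol.member_indices[0] == 42
        assert sol.weights[0] == pytest.approx(1.0)
        assert sol.chi < 1e-8

    def test_two_state_mixture_weights_recovered(self):
        # two distinguishable true states (sphere form factors, whose
        # oscillations identify the size) among 500 decoys kept out of a
        # window around the true radii, so exact-member recovery is well
        # posed
        from saxsemble.saxscalc import sphere_profile
        rng = np.random.default_rng(1)
        q = np.linspace(0.01, 0.4, 120)
        radii = rng.uniform(15, 45, size=500)
        for lo, hi in ((19.0, 21.0), (38.0, 42.0)):
            inside = (radii > lo) & (radii < hi)
            radii[inside] = rng.choice([lo - 1.0, hi + 1.0],
                                       size=inside.sum())
        radii[10], radii[400] = 20.0, 40.0
        pool = np.array([sphere_profile(q, r).I for r in radii])
        truth = 0.7 * pool[10] + 0.3 * pool[400]
        sigma = 0.01 * truth
        exp = SaxsProfile(q, truth + rng.normal(size=len(q)) * sigma,
                          sigma=sigma)
        sol = ses_select(pool, exp, k_max=6, seed=2)
        assert sol.weight_of(10) == pytest.approx(0.7, abs=0.05)
        assert sol.weight_of(400) == pytest.approx(0.3, abs=0.05)

    def test_chi_non_increasing_in_k_max(self):
        rng = np.random.default_rng(2)
        q = np.linspace(0.01, 0.4, 80)
        pool = decoy_pool(rng, q, 40)
        truth = 0.5 * pool[0] + 0.3 * pool[1] + 0.2 * pool[2]
        exp = SaxsProfile(q, truth, sigma=0.01 * truth)
        chis = [ses_select(pool, exp, k_max=k, seed=3, tol=1e-9).chi
                for k in (1, 2, 3, 4)]
        assert all(a >= b - 1e-12 for a, b in zip(chis, chis[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_on_small_pools(self, seed):
        rng = np.random.default_rng(seed)
        q = np.linspace(0.01, 0.4, 80)
        pool = decoy_pool(rng, q, 12)
        truth = 0.6 * pool[3] + 0.4 * pool[7]
        sigma = 0.005 * truth
        exp = SaxsProfile(q, truth + rng.normal(size=len(q)) * sigma,
                          sigma=sigma)
        greedy = ses_select(pool, exp, k_max=3, seed=0, tol=1e-6)
        brute = brute_force_select(pool, exp, k_max=3)
        assert greedy.chi <= brute.chi * 1.01

    def test_weights_form_probability_vector(self):
        rng = np.random.default_rng(4)
        q = np.linspace(0.01, 0.4, 80)
        pool = decoy_pool(rng, q, 60)
        truth = pool[:5].mean(axis=0)
        exp = SaxsProfile(q, truth, sigma=0.01 * truth)
        for k in (1, 3, 6):
            sol = ses_select(pool, exp, k_max=k, seed=5, tol=1e-9)
            sol.validate()
            assert np.all(sol.weights > 0)
            assert sol.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        q = np.linspace(0.01, 0.4, 80)
        pool = decoy_pool(rng, q, 50)
        truth = 0.6 * pool[8] + 0.4 * pool[9]
        exp = SaxsProfile(q, truth, sigma=0.01 * truth)
        a = ses_select(pool, exp, seed=11)
        b = ses_select(pool, exp, seed=11)
        np.testing.assert_array_equal(a.member_indices, b.member_indices)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestDerivedQuantities:
    def test_average_profile_cases(self):
        q = np.linspace(0.01, 0.4, 50)
        d = 20.0
        curve_a = 2 * (1 + np.sin(q * d) / (q * d))
        curve_b = 2 * (1 + np.sin(q * 2 * d) / (q * 2 * d))
        profiles = np.array([curve_a, curve_b])
        one = EnsembleSolution(np.array([0]), np.array([1.0]), 0.0)
        np.testing.assert_allclose(
            ensemble_average_profile(one, profiles, q=q).I, curve_a)
        mix = EnsembleSolution(np.array([0, 1]), np.array([0.25, 0.75]), 0.0)
        np.testing.assert_allclose(
            ensemble_average_profile(mix, profiles, q=q).I,
            0.25 * curve_a + 0.75 * curve_b)

    def test_rg_distribution_mode_and_uniform_limit(self):
        pool_rgs = np.array([30.0, 37.0, 44.0, 51.0])
        one = EnsembleSolution(np.array([1]), np.array([1.0]), 0.0)
        dist = rg_distribution(one, pool_rgs, bins=np.arange(28, 54, 2))
        assert dist.mode == pytest.approx(37.0, abs=1.0)
        uniform = EnsembleSolution(np.arange(4), np.full(4, 0.25), 0.0)
        dist_u = rg_distribution(uniform, pool_rgs, bins=np.arange(28, 54, 2))
        unweighted, _ = np.histogram(pool_rgs, bins=np.arange(28, 54, 2))
        np.testing.assert_allclose(dist_u.counts * 4, unweighted)

    def test_compact_fraction_limits_and_planted_split(self, toy, toy_pool):
        topology, _ = toy
        d1, d2 = topology.rigid_domains[:2]
        s1 = ResidueSet.from_range("A", d1.start, d1.end)
        s2 = ResidueSet.from_range("A", d2.start, d2.end)
        sol = EnsembleSolution(np.array([0, 1]), np.array([0.8, 0.2]), 0.0)
        assert compact_fraction(sol, toy_pool, s1, s2, np.inf) == 1.0
        assert compact_fraction(sol, toy_pool, s1, s2, 0.0) == 0.0
        # threshold between the two members' interdomain distances isolates
        # the planted 80/20 split
        from saxsemble.structmodel import center_of_mass_distance
        d_a = center_of_mass_distance(toy_pool[0], s1, s2)
        d_b = center_of_mass_distance(toy_pool[1], s1, s2)
        lo, hi = sorted([d_a, d_b])
        frac = compact_fraction(sol, toy_pool, s1, s2, 0.5 * (lo + hi))
        expected = 0.8 if d_a < d_b else 0.2
        assert frac == pytest.approx(expected)
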