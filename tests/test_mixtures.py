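"""Mixture likelihood arithmetic, allocation Gibbs sampling, DP machinery."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from phylocv.likelihood import LikelihoodEngine, sitewise_log_likelihoods
from phylocv.mixtures import (
    MixtureModel,
    SiteAllocation,
    dp_update,
    gibbs_resample_allocations,
    resample_concentration,
    site_mixture_likelihood,
    site_mixture_log_likelihood,
)
from phylocv.simulate import sample_random_model, simulate_alignment
from phylocv.substitution import Exchangeabilities, FrequencyProfile
from phylocv.tree import random_tree, tree_from_newick


class TestSiteMixtureLikelihood:
    def test_single_component_identity(self):
        assert site_mixture_likelihood([0.37], [1.0]) == pytest.approx(0.37, rel=1e-15)

    def test_equal_component_likelihoods(self):
        val = site_mixture_likelihood([0.2, 0.2, 0.2], [0.5, 0.3, 0.2])
        assert val == pytest.approx(0.2, rel=1e-14)

    def test_extreme_underflow_handled_in_log_space(self):
        logval = site_mixture_log_likelihood([1e-300, 1e-310], [0.3, 0.7])
        expected = math.log(0.3e-300 + 0.7e-310)
        # agreement to 1 ulp of the log value
        assert abs(logval - expected) <= math.ulp(abs(expected))
        val = site_mixture_likelihood([1e-300, 1e-310], [0.3, 0.7])
        assert val == pytest.approx(0.3e-300 + 0.7e-310, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            site_mixture_likelihood([0.1, 0.2], [1.0])


class TestGibbsAllocations:
    def test_single_component_always_zero(self, rng):
        tree = random_tree(["a", "b", "c"], rng)
        model = sample_random_model("single", seed=1)
        model = MixtureModel(kind="finite", profiles=model.profiles,
                             weights=np.array([1.0]), rho=model.rho)
        aln, _ = simulate_alignment(tree, model, 20, seed=2)
        alloc = gibbs_resample_allocations(aln, tree, model, rng)
        assert (alloc.z == 0).all()

    def test_near_impossible_component_excluded(self, rng):
        # component 1 puts ~floor mass on A; an all-A column must pick comp 0
        tree = tree_from_newick("(a:0.01,b:0.01);")
        rich_a = FrequencyProfile.from_values([0.97, 0.01, 0.01, 0.01])
        no_a = FrequencyProfile.from_values([0.0, 0.4, 0.3, 0.3])
        model = MixtureModel(kind="finite", profiles=[rich_a, no_a],
                             weights=np.array([0.5, 0.5]), rho=None)
        from phylocv.alignment import Alignment
        aln = Alignment.from_sequences([("a", "AAAA"), ("b", "AAAA")])
        for _ in range(200):
            alloc = gibbs_resample_allocations(aln, tree, model, rng)
            assert (alloc.z == 0).all()

    def test_matches_enumerated_conditional_distribution(self, rng):
        # 3 sites, 2 components with fixed parameters: empirical allocation
        # frequencies vs the exact per-site conditional posterior
        tree = tree_from_newick("(a:0.2,b:0.3);")
        model = MixtureModel(
            kind="finite",
            profiles=[FrequencyProfile.from_values([0.7, 0.1, 0.1, 0.1]),
                      FrequencyProfile.from_values([0.1, 0.1, 0.1, 0.7])],
            weights=np.array([0.4, 0.6]), rho=None)
        from phylocv.alignment import Alignment
        aln = Alignment.from_sequences([("a", "ATC"), ("b", "AAC")])
        engine = LikelihoodEngine(aln, tree)
        comp_logl = engine.component_site_logl(model, tree.lengths)
        log_post = comp_logl + np.log(model.weights)[None, :]
        exact = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
        n_draws = 20000
        hits = np.zeros((3, 2))
        for _ in range(n_draws):
            alloc = gibbs_resample_allocations(aln, tree, model, rng,
                                               component_logl=comp_logl)
            for n in range(3):
                hits[n, alloc.z[n]] += 1
        emp = hits / n_draws
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert (np.abs(emp - exact) <= 3 * se + 1e-9).all()


def _uniform_dp_state(n_sites, concentration, gamma=None, rho=None):
    mix = MixtureModel(kind="dp", profiles=[FrequencyProfile.uniform()],
                       rho=rho, gamma=gamma, concentration=concentration)
    alloc = SiteAllocation(np.zeros(n_sites, dtype=int), n_components=1)
    return mix, alloc


class TestDPUpdate:
    def test_small_concentration_collapses_to_one_component(self):
        rng = np.random.default_rng(5)
        tree = random_tree(["a", "b", "c", "d"], rng)
        model = sample_random_model("single", seed=6, free_exchangeabilities=False)
        aln, _ = simulate_alignment(tree, model, 100, seed=7)
        mix, alloc = _uniform_dp_state(100, concentration=1e-4)
        occupied = []
        for sweep in range(80):
            mix, alloc = dp_update(aln, tree, (mix, alloc), rng,
                                   update_concentration=False)
            mix = MixtureModel(kind="dp", profiles=mix.profiles,
                               weights=mix.weights, concentration=1e-4)
            if sweep >= 20:
                occupied.append(mix.n_components)
        assert np.mean(np.array(occupied) == 1) >= 0.99

    def test_prior_only_occupancy_matches_crp_partition_law(self):
        # likelihood disabled: the sweep must sample the Chinese restaurant
        # process exactly; compare K-distribution to the Stirling closed form
        n, conc = 8, 1.0
        rng = np.random.default_rng(11)
        mix, alloc = _uniform_dp_state(n, conc)
        ks = []
        for sweep in range(25000):
            mix, alloc = dp_update(None, None, (mix, alloc), rng,
                                   prior_only=True, update_concentration=False)
            mix = MixtureModel(kind="dp", profiles=mix.profiles,
                               weights=mix.weights, concentration=conc)
            if sweep % 5 == 0:
                ks.append(mix.n_components)
        ks = np.array(ks)
        stirling = np.zeros((n + 1, n + 1))
        stirling[0, 0] = 1.0
        for i in range(1, n + 1):
            for k in range(1, i + 1):
                stirling[i, k] = stirling[i - 1, k - 1] + (i - 1) * stirling[i - 1, k]
        rising = math.prod(conc + j for j in range(n))
        exact = np.array([stirling[n, k] * conc ** k / rising for k in range(n + 1)])
        emp = np.bincount(ks, minlength=n + 1) / len(ks)
        se = np.sqrt(exact * (1 - exact) / len(ks))
        assert (np.abs(emp - exact) <= 3 * se + 1e-9).all()

    def test_no_orphan_profiles_and_bounded_occupancy(self, rng):
        tree = random_tree(["a", "b", "c", "d", "e"], rng)
        model = sample_random_model("finite", ncomp=3, seed=8,
                                    profile_concentration=0.3,
                                    free_exchangeabilities=False)
        aln, _ = simulate_alignment(tree, model, 60, seed=9)
        mix, alloc = _uniform_dp_state(60, concentration=1.0)
        for _ in range(15):
            mix, alloc = dp_update(aln, tree, (mix, alloc), rng)
            assert mix.n_components == alloc.counts.shape[0]
            assert (alloc.counts >= 1).all()          # emptied components removed
            assert mix.n_components <= 60
            assert abs(mix.weights.sum() - 1.0) < 1e-12

    def test_relabeling_symmetry_of_allocated_likelihood(self, rng):
        tree = random_tree(["a", "b", "c", "d"], rng)
        model = sample_random_model("finite", ncomp=3, seed=10,
                                    free_exchangeabilities=False)
        aln, _ = simulate_alignment(tree, model, 40, seed=11)
        engine = LikelihoodEngine(aln, tree)
        comp = engine.component_site_logl(model, tree.lengths)
        z = rng.integers(0, 3, size=40)
        base = comp[np.arange(40), z].sum()
        perm = np.array([2, 0, 1])
        permuted = MixtureModel(kind="finite",
                                profiles=[model.profiles[i] for i in perm],
                                weights=model.weights[perm], rho=model.rho)
        comp_p = engine.component_site_logl(permuted, tree.lengths)
        inv = np.argsort(perm)
        relabeled = comp_p[np.arange(40), inv[z]].sum()
        assert abs(base - relabeled) < 1e-12


class TestResampleConcentration:
    def test_one_component_shifts_mass_down(self):
        rng = np.random.default_rng(3)
        few = [resample_concentration(1, 500, 1.0, rng) for _ in range(10000)]
        rng = np.random.default_rng(3)
        many = [resample_concentration(500, 500, 1.0, rng) for _ in range(10000)]
        assert np.mean(few) < 2.0
        assert np.mean(many) > 50.0
        assert np.mean(few) < np.mean(many)

    def test_joint_prior_chain_recovers_exponential_prior(self):
        # alternate CRP partition draws and concentration draws with the
        # likelihood off: the marginal of the concentration is its prior,
        # Exponential with mean 10 (variance 100)
        rng = np.random.default_rng(17)
        n = 10
        conc = 10.0
        mix, alloc = _uniform_dp_state(n, conc)
        draws = []
        for _ in range(30000):
            mix, alloc = dp_update(None, None, (mix, alloc), rng,
                                   prior_only=True, update_concentration=True,
                                   concentration_prior=(1.0, 0.1))
            draws.append(mix.concentration)
        draws = np.array(draws[2000:])
        batches = draws.reshape(40, -1).mean(axis=1)
        se_mean = batches.std(ddof=1) / math.sqrt(len(batches))
        assert abs(draws.mean() - 10.0) <= 3 * se_mean
        var_batches = draws.reshape(40, -1).var(axis=1)
        se_var = var_batches.std(ddof=1) / math.sqrt(len(var_batches))
        assert abs(draws.var() - 100.0) <= 4 * se_var + 10.0


def test_finite_one_component_reproduces_single_matrix(rng):
    tree = random_tree(["a", "b", "c", "d", "e"], rng)
    single = sample_random_model("single", seed=21, gamma=True)
    finite = MixtureModel(kind="finite", profiles=single.profiles,
                          weights=np.array([1.0]), rho=single.rho,
                          gamma=single.gamma)
    aln, _ = simulate_alignment(tree, single, 120, seed=22)
    l_single = sitewise_log_likelihoods(aln, tree, single).log_likelihoods
    l_finite = sitewise_log_likelihoods(aln, tree, finite).log_likelihoods
    assert np.abs(l_single - l_finite).max() < 1e-12
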