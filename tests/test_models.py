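import math
import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from stratatips.datamodel import CharacterMatrix, DatedTree, ModelParams
from stratatips.models import (
    PriorConfig, bdss_log_density, branch_rate_log_prior,
    discrete_gamma_rates, hyperprior_terms, log_prior, mk_log_likelihood,
    mk_transition_prob,
)
from conftest import random_dated_tree, random_matrix
from oracles import bdss_loglik_ode, enumeration_loglik


class TestDiscreteGamma:
    def test_zero_variance_limit(self):
        g = discrete_gamma_rates(1e6, 4)
        assert np.all(np.abs(g.rates - 1.0) < 1e-2)

    @pytest.mark.parametrize("shape", [0.05, 0.3, 1.0, 3.7, 50.0])
    def test_mean_is_one(self, shape):
        g = discrete_gamma_rates(shape, 4)
        assert g.rates.mean() == pytest.approx(1.0, abs=1e-9)

    def test_bin_means_match_quadrature(self):
        """Oracle: direct numerical integration of x * pdf over each
        equal-probability bin of Gamma(0.5, rate 0.5)."""
        shape, ncat = 0.5, 4
        g = discrete_gamma_rates(shape, ncat)
        edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), shape,
                                scale=1 / shape)
        for i in range(ncat):
            hi = edges[i + 1] if np.isfinite(edges[i + 1]) else np.inf
            mass, _ = quad(
                lambda x: x * stats.gamma.pdf(x, shape, scale=1 / shape),
                edges[i], hi,
            )
            assert g.rates[i] == pytest.approx(mass * ncat, abs=1e-6)

    def test_rates_increase_and_variance_shrinks_with_shape(self):
        g1 = discrete_gamma_rates(0.5, 4)
        g2 = discrete_gamma_rates(5.0, 4)
        assert np.all(np.diff(g1.rates) >= 0)
        assert np.all(np.diff(g2.rates) >= 0)
        assert g2.rates.var() < g1.rates.var()

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestMkTransition:
    def test_zero_time_identity(self):
        assert np.allclose(mk_transition_prob(2, 0.0), np.eye(2))

    def test_stationary_limit(self):
        p = mk_transition_prob(3, 1e9)
        assert np.allclose(p, 1.0 / 3, atol=1e-9)

    def test_known_value_k2_t1(self):
        p = mk_transition_prob(2, 1.0)
        assert p[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2), abs=1e-12)

    def test_rows_are_distributions(self):
        for k in (2, 3, 5):
            p = mk_transition_prob(k, 0.37)
            assert np.allclose(p.sum(axis=1), 1.0)
            assert np.all(p >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mk_transition_prob(2, -0.1)


class TestMkLikelihood:
    def test_short_branch_same_state_approaches_root_frequency(self):
        tree = DatedTree(
            parent={0: 2, 1: 2}, children={2: (0, 1)},
            age={0: 0.0, 1: 0.0, 2: 1e-9}, labels={0: "a", 1: "b"}, root=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant character is the point
            m = CharacterMatrix(["a", "b"], np.array([[0], [0]]), k=[2])
        assert mk_log_likelihood(tree, m) == pytest.approx(math.log(0.5),
                                                           abs=1e-6)

    @pytest.mark.parametrize("half_path", [0.01, 0.3, 1.0, 7.5])
    def test_mkv_two_tip_variable_pattern_is_exactly_half(self, half_path):
        """Conditioned on being variable, a 2-tip binary character splits
        its mass evenly over the two variable patterns for every t > 0,
        with or without gamma rate mixing."""
        tree = DatedTree(
            parent={0: 2, 1: 2}, children={2: (0, 1)},
            age={0: 0.0, 1: 0.0, 2: half_path}, labels={0: "a", 1: "b"},
            root=2,
        )
        m = CharacterMatrix(["a", "b"], np.array([[0], [1]]), k=[2])
        g = discrete_gamma_rates(0.7, 4)
        for gamma in (None, g):
            ll = mk_log_likelihood(tree, m, gamma=gamma,
                                   conditioning="variable")
            assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_mkv_normalisation_over_variable_patterns(self):
        """The conditioned likelihoods of all variable 2-tip binary
        patterns sum to 1."""
        tree = DatedTree(
            parent={0: 2, 1: 2}, children={2: (0, 1)},
            age={0: 0.0, 1: 0.0, 2: 0.8}, labels={0: "a", 1: "b"}, root=2,
        )
        total = 0.0
        for pattern in ([0, 1], [1, 0]):
            m = CharacterMatrix(["a", "b"], np.array(pattern).reshape(2, 1),
                                k=[2])
            total += math.exp(
                mk_log_likelihood(tree, m, conditioning="variable")
            )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("conditioning", ["none", "variable"])
    def test_pruning_matches_enumeration(self, seed, conditioning):
        """Brute-force ancestral-state enumeration oracle on <=4-tip trees
        with <=3 states, missing data, gamma mixing and a relaxed clock."""
        rng = np.random.default_rng(seed)
        tree = random_dated_tree(rng, int(rng.integers(2, 5)))
        matrix = random_matrix(rng, tree.taxa(), n_char=3)
        mult = {n: float(rng.lognormal(0, 0.3))
                for n in tree.nodes if n != tree.root}
        g = discrete_gamma_rates(0.8, 3)
        got = mk_log_likelihood(tree, matrix, clock_rate=0.4,
                                branch_rate_mult=mult, gamma=g,
                                conditioning=conditioning)
        want = enumeration_loglik(tree, matrix, clock_rate=0.4,
                                  branch_rate_mult=mult,
                                  gamma_rates=g.rates,
                                  conditioning=conditioning)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matrix_taxon_missing_from_tree_rejected(self, two_tip_tree):
        m = CharacterMatrix(["a", "zz"], np.array([[0], [1]]), k=[2])
        with pytest.raises(ValueError, match="absent from tree"):
            mk_log_likelihood(two_tip_tree, m)


class TestBdssDensity:
    def test_invariant_under_tip_relabelling(self, three_tip_tree):
        relabelled = DatedTree(
            three_tip_tree.parent, three_tip_tree.children,
            three_tip_tree.age, {0: "c", 1: "a", 2: "b"},
            three_tip_tree.root,
        )
        a = bdss_log_density(three_tip_tree, 0.3, 0.2, 0.1, 8.0)
        b = bdss_log_density(relabelled, 0.3, 0.2, 0.1, 8.0)
        assert a == b

    @pytest.mark.parametrize("rates", [(0.3, 0.2, 0.1), (0.9, 0.1, 0.4),
                                       (0.05, 0.3, 0.2)])
    def test_matches_ode_oracle(self, three_tip_tree, rates):
        lam, mu, psi = rates
        got = bdss_log_density(three_tip_tree, lam, mu, psi, 8.0)
        want = bdss_loglik_ode(three_tip_tree, lam, mu, psi, 8.0)
        assert got == pytest.approx(want, abs=1e-8)

    def test_time_rescaling_preserves_ordering(self, rng):
        """Scaling all ages by s and all rates by 1/s preserves which of
        two trees has the higher density."""
        t1 = random_dated_tree(rng, 5)
        t2 = random_dated_tree(rng, 5)
        lam, mu, psi = 0.5, 0.2, 0.3
        s = 7.0
        def scaled(t):
            return DatedTree(
                t.parent, t.children,
                {n: a * s for n, a in t.age.items()}, t.labels, t.root,
            )
        for a, b in [(t1, t2)]:
            orig = (bdss_log_density(a, lam, mu, psi, max(a.age.values()) + 2)
                    > bdss_log_density(b, lam, mu, psi, max(b.age.values()) + 2))
            resc = (bdss_log_density(scaled(a), lam / s, mu / s, psi / s,
                                     (max(a.age.values()) + 2) * s)
                    > bdss_log_density(scaled(b), lam / s, mu / s, psi / s,
                                       (max(b.age.values()) + 2) * s))
            assert orig == resc

    def test_origin_below_root_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="origin_age"):
            bdss_log_density(three_tip_tree, 0.3, 0.2, 0.1, 5.0)

    def test_nonpositive_rate_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="death_rate"):
            bdss_log_density(three_tip_tree, 0.3, 0.0, 0.1, 8.0)


class TestPriors:
    def test_clock_rate_below_offset_is_impossible(self):
        p = ModelParams(clock_rate=0.0015, origin_age=10.0)
        assert log_prior(p) == -math.inf

    def test_clock_rate_term_at_offset_plus_mean(self):
        p = ModelParams(clock_rate=0.0046, origin_age=10.0)
        terms = hyperprior_terms(p, PriorConfig())
        assert terms["clock_rate"] == pytest.approx(-math.log(0.003) - 1.0,
                                                    abs=1e-12)

    def test_shape_term_is_uniform_density(self):
        p = ModelParams(gamma_shape=5.0, origin_age=10.0)
        terms = hyperprior_terms(p, PriorConfig())
        assert terms["gamma_shape"] == pytest.approx(math.log(0.1))
        p11 = ModelParams(gamma_shape=10.5, origin_age=10.0)
        assert hyperprior_terms(p11, PriorConfig())["gamma_shape"] == -math.inf

    def test_birth_prior_mean_in_real_space(self, rng):
        """Monte-Carlo check of the lognormal parameterisation: E[X] must
        equal the configured real-space mean."""
        pc = PriorConfig()
        draws = rng.lognormal(pc.birth_mulog, pc.birth_sdlog, 200_000)
        assert draws.mean() == pytest.approx(0.14, rel=0.02)

    def test_log_prior_continuous_on_support_interior(self):
        base = dict(clock_rate=0.004, clock_sd=0.7, gamma_shape=3.0,
                    birth_rate=0.2, death_rate=0.05, sampling_rate=0.02,
                    origin_age=10.0)
        v0 = log_prior(ModelParams(**base))
        for key in ("clock_rate", "gamma_shape", "birth_rate"):
            bumped = dict(base)
            bumped[key] = base[key] * (1 + 1e-9)
            assert log_prior(ModelParams(**bumped)) == pytest.approx(v0, abs=1e-5)

    def test_branch_rate_prior_matches_scipy(self, rng):
        sd = 0.6
        mults = rng.lognormal(-sd ** 2 / 2, sd, 5)
        want = stats.lognorm.logpdf(mults, s=sd, scale=math.exp(-sd ** 2 / 2)).sum()
        assert branch_rate_log_prior(mults, sd) == pytest.approx(want, abs=1e-9)
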