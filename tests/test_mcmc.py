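import math
import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad, solve_ivp

from stratatips.datamodel import (
    CharacterMatrix, DatedTree, FossilSite, ModelParams, StratSequence,
    validate_state,
)
from stratatips.io import AnalysisConfig
from stratatips.mcmc import (
    AnalysisData, Trace, build_initial_tree, initial_site_ages, run_analysis,
    run_chain, sample_prior,
)
from stratatips.summaries import ess
from stratatips.synthdata import make_fixture_dataset
from conftest import LOCH_HI, LOCH_LO


@pytest.fixture(scope="module")
def small_fixture():
    return make_fixture_dataset(3, n_tips_target=10, n_char=30)


def _small_cfg(**kw):
    base = dict(chain_length=20_000, log_interval=100, seed=7,
                log_trees=True)
    base.update(kw)
    return AnalysisConfig(**base)


class TestDriverContracts:
    def test_zero_length_chain_logs_exactly_the_initial_state(
        self, small_fixture
    ):
        cfg = _small_cfg(chain_length=0)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        res = run_chain(cfg, data)
        assert res.trace.n_samples == 1
        assert res.trace.column("generation")[0] == 0

    def test_same_seed_gives_bit_identical_traces(self, small_fixture):
        cfg = _small_cfg(chain_length=5_000)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        a = run_chain(cfg, data).trace.values
        b = run_chain(cfg, data).trace.values
        assert np.array_equal(a, b)

    def test_posterior_column_is_likelihood_plus_prior(self, small_fixture):
        cfg = _small_cfg(chain_length=10_000)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        tr = run_chain(cfg, data).trace
        np.testing.assert_allclose(
            tr.column("posterior"),
            tr.column("likelihood") + tr.column("prior"),
            atol=1e-8,
        )

    def test_every_logged_sample_is_a_valid_state(self, small_fixture):
        """Linked-ages run: each logged tree + site ages must satisfy all
        invariants, including tips sharing their site's age."""
        cfg = _small_cfg(chain_length=10_000, log_interval=500)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        res = run_chain(cfg, data)
        multi = [s for s in small_fixture.sites if len(s.taxa) > 1]
        for i, tree in enumerate(res.trees):
            sites_i = [
                FossilSite(s.site_id, s.taxa, s.min_age, s.max_age,
                           float(res.trace.column(f"age_{s.site_id}")[i]))
                for s in multi
            ]
            assert validate_state(tree, sites_i, small_fixture.seq) == []

    def test_zero_probability_initial_state_names_component(
        self, small_fixture
    ):
        bad = ModelParams(clock_rate=0.0046, clock_sd=0.5, gamma_shape=11.0,
                          origin_age=small_fixture.params_true.origin_age)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree,
                            params=bad)
        with pytest.raises(ValueError, match="gamma_shape"):
            run_chain(_small_cfg(), data)

    def test_all_rejecting_chain_warns(self):
        """A chain whose only move always hard-rejects (narrow exchange
        blocked by node ages) must raise an acceptance warning."""
        tree = DatedTree(
            parent={0: 3, 1: 3, 2: 4, 3: 4}, children={3: (0, 1), 4: (3, 2)},
            age={0: 0.0, 1: 0.0, 2: 5.0, 3: 1.0, 4: 10.0},
            labels={0: "a", 1: "b", 2: "c"}, root=4,
        )
        sites = [FossilSite(lab, (lab,), tree.age[t], tree.age[t],
                            tree.age[t])
                 for t, lab in ((0, "a"), (1, "b"), (2, "c"))]
        params = ModelParams(origin_age=15.0)
        w = {"site_ages": 0, "node_slide": 0, "root": 0, "origin": 0,
             "narrow": 1.0, "clock_rate": 0, "clock_sd": 0,
             "gamma_shape": 0, "birth_rate": 0, "death_rate": 0,
             "sampling_rate": 0, "rate_mult": 0}
        cfg = AnalysisConfig(chain_length=200, log_interval=50,
                             prior_only=True, log_trees=False,
                             operator_weights=w)
        data = AnalysisData(None, sites, StratSequence(), tree=tree,
                            params=params)
        with pytest.warns(UserWarning, match="acceptance rate 0"):
            run_chain(cfg, data)

    def test_acceptance_counts_are_logged_per_operator(self, small_fixture):
        cfg = _small_cfg(chain_length=5_000, log_trees=False)
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        res = run_chain(cfg, data)
        assert set(res.acceptance) >= {"site", "node_slide", "clock_rate"}
        for proposed, accepted in res.acceptance.values():
            assert 0 <= accepted <= proposed


class TestInitialisation:
    def test_site_midpoints_adjusted_for_ordering(self):
        sites = [FossilSite("A", ("a",), 410, 418, 414),
                 FossilSite("B", ("b",), 414, 420, 417)]
        seq = StratSequence([("A", "B")])  # A below: must not be younger
        ages = initial_site_ages(sites, seq)
        assert ages["A"] >= ages["B"]
        assert 410 <= ages["A"] <= 418 and 414 <= ages["B"] <= 420

    def test_random_initial_tree_is_valid_and_spans_tips(self, rng):
        tip_ages = {"a": 412.0, "b": 415.5, "c": 0.0, "d": 407.0}
        tree = build_initial_tree(tip_ages, rng)
        assert tree.check() == []
        assert {tree.labels[t] for t in tree.tips()} == set(tip_ages)
        assert tree.age[tree.root] > 415.5

    def test_chain_builds_its_own_tree_when_none_given(self, small_fixture):
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq)
        cfg = _small_cfg(chain_length=2_000, log_trees=False)
        res = run_chain(cfg, data)
        assert res.trace.n_samples == 21


class TestPriorSampling:
    def test_unconstrained_site_age_marginal_is_uniform(
        self, four_tip_fossil_tree
    ):
        sites = [FossilSite("moth", ("a", "b"), LOCH_LO, LOCH_HI, 415.0)]
        params = ModelParams(clock_rate=0.0046, clock_sd=0.5, gamma_shape=5.0,
                             birth_rate=1e-6, death_rate=1e-6,
                             sampling_rate=1e-6, origin_age=446.0)
        w = {"node_slide": 0, "root": 0, "origin": 0, "narrow": 0,
             "clock_rate": 0, "clock_sd": 0, "gamma_shape": 0,
             "birth_rate": 0, "death_rate": 0, "sampling_rate": 0,
             "rate_mult": 0}
        cfg = AnalysisConfig(chain_length=300_000, log_interval=30, seed=12,
                             log_trees=False, operator_weights=w)
        res = sample_prior(cfg, AnalysisData(None, sites, StratSequence(),
                                             tree=four_tip_fossil_tree,
                                             params=params))
        a = res.trace.column("age_moth")[1000:]
        ks = stats.kstest(a, stats.uniform(LOCH_LO, LOCH_HI - LOCH_LO).cdf)
        assert ks.statistic < 0.02
        assert np.all(res.trace.column("likelihood") == 0.0)

    def test_ordered_pair_prior_separates_site_means(
        self, four_tip_fossil_tree
    ):
        sites = [FossilSite("A", ("a", "b"), LOCH_LO, LOCH_HI, 415.0),
                 FossilSite("B", ("c",), LOCH_LO, LOCH_HI, 415.0)]
        seq = StratSequence([("A", "B")])
        params = ModelParams(clock_rate=0.0046, clock_sd=0.5, gamma_shape=5.0,
                             birth_rate=1e-6, death_rate=1e-6,
                             sampling_rate=1e-6, origin_age=446.0)
        w = {"node_slide": 0, "root": 0, "origin": 0, "narrow": 0,
             "clock_rate": 0, "clock_sd": 0, "gamma_shape": 0,
             "birth_rate": 0, "death_rate": 0, "sampling_rate": 0,
             "rate_mult": 0}
        cfg = AnalysisConfig(chain_length=200_000, log_interval=50, seed=13,
                             log_trees=False, operator_weights=w)
        res = sample_prior(cfg, AnalysisData(None, sites, seq,
                                             tree=four_tip_fossil_tree,
                                             params=params))
        a = res.trace.column("age_A")[500:]
        b = res.trace.column("age_B")[500:]
        se = math.sqrt(a.var() / ess(a) + b.var() / ess(b))
        assert a.mean() - b.mean() > 2 * se

    def test_posterior_matches_fine_grid_oracle_on_two_tip_problem(self):
        """Fixed 2-tip tree, one variable binary character: the sampled
        fossil-age posterior must match a numerically integrated posterior
        (closed-form likelihood x ODE-integrated tree prior) to KS < 0.05."""
        tree = DatedTree(
            parent={0: 2, 1: 2}, children={2: (0, 1)},
            age={0: 415.0, 1: 412.0, 2: 425.0}, labels={0: "A", 1: "B"},
            root=2,
        )
        mat = CharacterMatrix(["A", "B"], np.array([[0], [1]]), k=[2])
        lam, mu, psi, r = 0.3, 0.2, 0.1, 0.05
        params = ModelParams(clock_rate=r, clock_sd=0.5, gamma_shape=5.0,
                             birth_rate=lam, death_rate=mu,
                             sampling_rate=psi, origin_age=430.0)
        sites = [FossilSite("A", ("A",), LOCH_LO, LOCH_HI, 415.0),
                 FossilSite("B", ("B",), 412.0, 412.0, 412.0)]
        w = {"node_slide": 0, "root": 0, "origin": 0, "narrow": 0,
             "clock_rate": 0, "clock_sd": 0, "gamma_shape": 0,
             "birth_rate": 0, "death_rate": 0, "sampling_rate": 0,
             "rate_mult": 0}
        cfg = AnalysisConfig(chain_length=250_000, log_interval=25, seed=3,
                             log_trees=False, conditioning="none",
                             gamma_ncat=1, operator_weights=w)
        res = run_chain(cfg, AnalysisData(mat, sites, StratSequence(),
                                          tree=tree, params=params))
        a = res.trace.column("age_A")[1000:]

        sol = solve_ivp(
            lambda t, y: [-(lam + mu + psi) * y[0] + mu + lam * y[0] ** 2],
            (0, 431), [1.0], dense_output=True, rtol=1e-11, atol=1e-13,
        ).sol

        def logq(t):
            v, _ = quad(lambda s: -(lam + mu + psi) + 2 * lam * sol(s)[0],
                        0, t, limit=300, epsabs=1e-11, epsrel=1e-11)
            return v

        grid = np.linspace(LOCH_LO, LOCH_HI, 1200)
        dens = np.array([
            0.25 * (1 - math.exp(-2 * r * ((425.0 - x) + 13.0)))
            * math.exp(-logq(x) + logq(415.0))
            for x in grid
        ])
        dens /= np.trapezoid(dens, grid)
        cdf = np.concatenate(
            [[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))]
        )
        cdf /= cdf[-1]
        ks = stats.kstest(a, lambda v: np.interp(v, grid, cdf)).statistic
        assert ks < 0.05


class TestMultiRun:
    def test_independent_runs_agree_on_site_age_means(self, small_fixture):
        """Four seeds, post-burn-in site-age means within 2 combined
        Monte-Carlo standard errors of each other."""
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            small_fixture.seq, tree=small_fixture.tree)
        runs = []
        for seed in (101, 202, 303, 404):
            cfg = AnalysisConfig(chain_length=300_000, log_interval=200,
                                 seed=seed, log_trees=False,
                                 operator_weights={"narrow": 0.0})
            runs.append(run_chain(cfg, data).trace.burnin(0.10))
        for sid in small_fixture.multi_sites:
            stats_ = []
            for tr in runs:
                x = tr.column(f"age_{sid}")
                stats_.append((x.mean(), math.sqrt(x.var() / max(ess(x), 1))))
            for i in range(len(stats_)):
                for j in range(i + 1, len(stats_)):
                    diff = abs(stats_[i][0] - stats_[j][0])
                    se = math.hypot(stats_[i][1], stats_[j][1])
                    assert diff < 2.5 * se, (sid, i, j, diff, se)


class TestRunAnalysis:
    def test_unlinked_mode_splits_sites_and_drops_relations(
        self, small_fixture, tmp_path
    ):
        data = AnalysisData(small_fixture.matrix, small_fixture.sites,
                            StratSequence([("site_lower", "site_upper")]),
                            tree=small_fixture.tree)
        cfg = _small_cfg(chain_length=1_000, log_trees=False,
                         link_site_ages=False,
                         output_prefix=str(tmp_path / "run"))
        with pytest.warns(UserWarning, match="relations"):
            res = run_analysis(cfg, data=data)
        lower_taxa = next(s.taxa for s in small_fixture.sites
                          if s.site_id == "site_lower")
        for taxon in lower_taxa:
            assert f"age_{taxon}" in res.trace.columns
        assert (tmp_path / "run.trace.tsv").exists()


class TestTraceObject:
    def test_burnin_slices_rows(self):
        tr = Trace(["generation", "x"],
                   np.column_stack([np.arange(10.0), np.arange(10.0)]))
        assert tr.burnin(0.1).n_samples == 9
        with pytest.raises(ValueError):
            tr.burnin(1.0)

    def test_unknown_column_raises(self):
        tr = Trace(["generation"], np.zeros((1, 1)))
        with pytest.raises(KeyError):
            tr.column("nope")
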