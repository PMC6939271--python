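"""Evolutionary lifecycle: proportional reproduction, mutation, mortality,
density-regulated recruitment, and whole-replicate runs."""

import numpy as np
import pytest

from bethedge import (
    GrainParams,
    PayoffParams,
    SimConfig,
    initialize_population,
    mutate,
    recruit,
    reproduce,
    run_replicate,
    survive_adults,
)


class TestInitializePopulation:
    def test_size_and_gene_distribution(self, rng):
        cfg = SimConfig(K=5000)
        pop = initialize_population(cfg, rng)
        assert pop.size == 5000
        se = np.sqrt(1 / 12 / 5000)  # uniform variance 1/12
        assert abs(pop.genes.mean() - 0.5) <= 3 * se
        assert pop.genes.min() >= 0 and pop.genes.max() <= 1

    def test_seeded_determinism(self):
        cfg = SimConfig(K=100)
        a = initialize_population(cfg, np.random.default_rng(9))
        b = initialize_population(cfg, np.random.default_rng(9))
        assert np.array_equal(a.genes, b.genes)


class TestReproduce:
    def test_zero_payoff_means_no_offspring(self, rng):
        pool = reproduce(np.array([0.3]), np.array([0.0]), rng)
        assert pool.size == 0

    def test_integer_payoff_is_deterministic(self, rng):
        pool = reproduce(np.array([0.7]), np.array([9.0]), rng)
        assert pool.size == 9
        assert np.all(pool == 0.7)

    def test_stochastic_rounding_is_unbiased(self, rng):
        N = 100_000
        pool = reproduce(np.zeros(N), np.full(N, 1.8), rng)
        se = np.sqrt(0.8 * 0.2 / N)  # Bernoulli(0.8) on the fraction
        assert abs(pool.size / N - 1.8) <= 3 * se

    def test_poisson_rounding_is_unbiased(self, rng):
        N = 100_000
        pool = reproduce(np.zeros(N), np.full(N, 1.8), rng, rounding="poisson")
        se = np.sqrt(1.8 / N)
        assert abs(pool.size / N - 1.8) <= 3 * se

    def test_offspring_inherit_parent_gene(self, rng):
        genes = np.array([0.1, 0.9])
        pool = reproduce(genes, np.array([3.0, 2.0]), rng)
        assert sorted(pool) == [0.1, 0.1, 0.1, 0.9, 0.9]

    def test_negative_payoffs_rejected(self, rng):
        with pytest.raises(ValueError):
            reproduce(np.array([0.5]), np.array([-1.0]), rng)


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        pool = np.linspace(0, 1, 50)
        assert np.array_equal(mutate(pool, 0.0, 0.05, rng), pool)

    def test_clamping_builds_point_mass_at_zero(self, rng):
        pool = np.full(20_000, 0.01)
        out = mutate(pool, 1.0, 0.05, rng)
        assert out.min() >= 0.0
        assert np.sum(out == 0.0) > 0

    def test_mutation_kernel_sd(self, rng):
        # away from the boundaries clamping is negligible
        pool = np.full(100_000, 0.5)
        out = mutate(pool, 1.0, 0.05, rng)
        assert np.std(out - 0.5) == pytest.approx(0.05, rel=0.02)

    def test_untouched_offspring_keep_exact_gene(self, rng):
        pool = np.full(10_000, 0.37)
        out = mutate(pool, 0.3, 0.05, rng)
        assert np.sum(out == 0.37) > 0.5 * pool.size  # ~70% untouched


class TestSurviveAdults:
    def test_certain_mortality_gives_discrete_generations(self, rng):
        assert survive_adults(np.ones(100), 1.0, rng).size == 0

    def test_no_mortality_keeps_everyone(self, rng):
        assert survive_adults(np.ones(100), 0.0, rng).size == 100

    def test_binomial_survival(self, rng):
        N = 10_000
        out = survive_adults(np.ones(N), 0.5, rng)
        se = np.sqrt(0.25 / N)
        assert abs(out.size / N - 0.5) <= 3 * se


class TestRecruit:
    def test_truncation_to_capacity(self, rng):
        nxt = recruit(np.zeros(10_000), np.array([]), 5000, rng)
        assert nxt.size == 5000

    def test_all_recruit_below_capacity(self, rng):
        nxt = recruit(np.zeros(100), np.array([]), 5000, rng)
        assert nxt.size == 100

    def test_full_population_recruits_nobody(self, rng):
        nxt = recruit(np.zeros(100), np.ones(50), 50, rng)
        assert nxt.size == 50 and np.all(nxt == 1)

    def test_double_extinction_is_empty_not_an_error(self, rng):
        nxt = recruit(np.array([]), np.array([]), 100, rng)
        assert nxt.size == 0

    def test_recruitment_is_gene_blind(self, rng):
        # pool with known gene proportion; recruited proportion matches
        pool = np.concatenate([np.ones(3000), np.zeros(7000)])
        nxt = recruit(pool, np.array([]), 5000, rng)
        se = np.sqrt(0.3 * 0.7 / 5000)
        assert abs(nxt.mean() - 0.3) <= 3 * se


class TestRunReplicate:
    SCALED = dict(K=200, seasons=50, replicates=1, master_seed=3)

    def test_zero_seasons_returns_initial_state(self):
        cfg = SimConfig(seasons=0, K=100, master_seed=1)
        s = run_replicate(cfg, GrainParams(), PayoffParams())
        assert s.survived and s.final_N == 100 and s.extinction_season is None
        assert 0 <= s.final_mean_gene <= 1

    def test_seeded_determinism(self):
        cfg = SimConfig(n=2, **self.SCALED)
        a = run_replicate(cfg, GrainParams(g_r=0.5), PayoffParams(), replicate_id=4)
        b = run_replicate(cfg, GrainParams(g_r=0.5), PayoffParams(), replicate_id=4)
        assert a == b

    def test_rich_environment_holds_population_at_capacity(self):
        # mean payoff far above 1 refills every vacancy each season
        cfg = SimConfig(n=10, **self.SCALED)
        s = run_replicate(cfg, GrainParams(g_r=0.0), PayoffParams(a=0.0, b=0.9))
        assert s.survived and s.final_N == cfg.K

    def test_starving_population_goes_extinct(self):
        # expected offspring ~0.05 per adult with certain adult mortality
        cfg = SimConfig(n=1, alpha=1.0, K=50, seasons=200, master_seed=2)
        s = run_replicate(cfg, GrainParams(), PayoffParams(mu=0.05, a=0.0, b=0.5))
        assert not s.survived
        assert s.extinction_season is not None and s.final_N == 0
        assert np.isnan(s.final_mean_gene)

    def test_asexual_heritability_without_mutation(self, rng):
        # with m_p = 0 every gene value in every later season already
        # existed among the K initial uniform draws
        from bethedge import Population, run_season_model1

        cfg = SimConfig(n=5, m_p=0.0, K=100, seasons=30)
        pop = initialize_population(cfg, rng)
        initial = set(pop.genes)
        grain, params = GrainParams(g_r=0.5), PayoffParams()
        for _ in range(15):
            W = run_season_model1(pop, grain, params, cfg, rng)
            pool = mutate(reproduce(pop.genes, W, rng), cfg.m_p, cfg.m_sigma, rng)
            survivors = survive_adults(pop.genes, cfg.alpha, rng)
            pop = Population(genes=recruit(pool, survivors, cfg.K, rng))
            assert set(pop.genes) <= initial

    def test_trajectory_recording(self):
        cfg = SimConfig(n=1, K=100, seasons=10, master_seed=1, track_trajectory=True)
        s = run_replicate(cfg, GrainParams(), PayoffParams())
        assert s.gene_trajectory is not None and s.gene_trajectory.size == 11
        assert np.all((s.gene_trajectory >= 0) & (s.gene_trajectory <= 1))

    def test_discrete_vs_overlapping_generations_agree(self):
        """Between-season adult mortality does not change the evolved
        endpoint beyond replicate noise (matched parameters)."""
        results = {}
        for alpha in (1.0, 0.5):
            cfg = SimConfig(
                n=10, alpha=alpha, K=300, seasons=400, master_seed=5
            )
            finals = [
                run_replicate(cfg, GrainParams(g_r=0.0), PayoffParams(), replicate_id=r).final_mean_gene
                for r in range(5)
            ]
            results[alpha] = (np.mean(finals), np.std(finals, ddof=1))
        diff = abs(results[1.0][0] - results[0.5][0])
        assert diff < max(results[1.0][1], results[0.5][1]) + 0.05
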