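import numpy as np
import pytest

import extractopt as eo
from extractopt.ann import TrainConfig, n_weights
from extractopt.evaluate import SplitSpec
from extractopt.gaaco import (ConvergenceTrace, GAACOConfig, PheromoneField,
                              ant_construct, ga_step, run_gaaco, train_gaaco_bp,
                              update_pheromone)


@pytest.fixture
def field():
    return PheromoneField(n_slots=6, m=5)


class TestAntConstruct:
    def test_single_candidate_per_slot_is_forced(self):
        f = PheromoneField(n_slots=4, m=1, candidate_range=(0.3, 0.3))
        for seed in range(3):
            assert np.allclose(ant_construct(f, seed), 0.3)

    def test_alpha_one_always_takes_argmax(self):
        f = PheromoneField(n_slots=5, m=4, alpha=1.0)
        f.tau = np.tile([0.1, 0.9, 0.2, 0.4], (5, 1))
        expected = f.candidates[np.arange(5), 1]
        for seed in range(5):
            assert np.array_equal(ant_construct(f, seed), expected)

    def test_uniform_pheromone_alpha_zero_samples_uniformly(self):
        """With unit pheromones and no greedy moves, slot frequencies match
        the uniform multinomial to within binomial noise."""
        m, n_draws = 5, 10_000
        f = PheromoneField(n_slots=2, m=m, alpha=0.0)
        rng = np.random.default_rng(42)
        draws = np.array([ant_construct(f, rng) for _ in range(n_draws)])
        for slot in range(2):
            _, counts = np.unique(draws[:, slot], return_counts=True)
            assert len(counts) == m
            # 4-sigma binomial envelope around n/m
            sigma = np.sqrt(n_draws * (1 / m) * (1 - 1 / m))
            assert np.all(np.abs(counts - n_draws / m) < 4 * sigma)


class TestUpdatePheromone:
    def test_pure_volatilization_scales_by_rho_exactly(self, field):
        before = field.tau.copy()
        update_pheromone(field, [(np.zeros(6), 1.0)], n_elite=0)
        assert np.array_equal(field.tau, before * 0.9)

    def test_two_evaporations_compose(self, field):
        before = field.tau.copy()
        for _ in range(2):
            update_pheromone(field, [(np.zeros(6), 1.0)], n_elite=0)
        assert np.allclose(field.tau, before * 0.81)

    def test_single_ant_deposit_is_q_over_fitness(self):
        f = PheromoneField(n_slots=1, m=3, candidate_range=(-1.0, 1.0))
        vec = np.array([1.0])  # nearest candidate: index 2
        update_pheromone(f, [(vec, 0.5)], n_elite=1, q=1.0)
        assert f.tau[0, 2] == pytest.approx(0.9 * 1.0 + 1.0 / 0.5)
        assert np.allclose(f.tau[0, :2], 0.9)

    def test_positivity_preserved(self, field):
        for _ in range(50):
            update_pheromone(field, [(np.zeros(6), 2.0)], n_elite=1)
        assert np.all(field.tau > 0)

    def test_non_finite_fitness_skipped_with_warning(self, field):
        before = field.tau.copy()
        with pytest.warns(UserWarning):
            update_pheromone(field, [(np.zeros(6), np.nan)], n_elite=1)
        assert np.array_equal(field.tau, before * 0.9)

    def test_no_ants_rejected(self, field):
        with pytest.raises(ValueError):
            update_pheromone(field, [])


class TestGaStep:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.pop = rng.uniform(-1, 1, (8, 10))
        self.fit = rng.uniform(0.1, 2.0, 8)

    def test_identical_parents_cross_to_identical_child(self):
        pop = np.tile(self.pop[0], (4, 1))
        cfg = GAACOConfig(crossover_rate=1.0, mutation_rate=0.0)
        child = ga_step(pop, np.ones(4), cfg, rng=1)
        assert np.allclose(child, pop)

    def test_elitism_keeps_best_unchanged(self):
        cfg = GAACOConfig(crossover_rate=1.0, mutation_rate=0.5)
        best = int(np.argmin(self.fit))
        child = ga_step(self.pop, self.fit, cfg, rng=3)
        assert np.array_equal(child[best], self.pop[best])

    def test_zero_rates_leave_population_unchanged(self):
        cfg = GAACOConfig(crossover_rate=0.0, mutation_rate=0.0)
        child = ga_step(self.pop, self.fit, cfg, rng=5)
        assert np.array_equal(child, self.pop)

    def test_population_of_one_rejected(self):
        with pytest.raises(ValueError):
            ga_step(self.pop[:1], self.fit[:1], GAACOConfig(), rng=0)


class TestRunGaaco:
    def small_config(self, **kw):
        base = dict(n_ants=8, n_generations=15, m_candidates=5, seed=0)
        base.update(kw)
        return GAACOConfig(**base)

    def test_best_fitness_trace_is_non_increasing(self, fixture_table):
        _, trace = run_gaaco(fixture_table, 4, self.small_config())
        assert np.all(np.diff(trace.best) <= 0)

    def test_seeded_run_is_bit_reproducible(self, fixture_table):
        w1, t1 = run_gaaco(fixture_table, 4, self.small_config(seed=11))
        w2, t2 = run_gaaco(fixture_table, 4, self.small_config(seed=11))
        assert np.array_equal(w1, w2)
        assert np.array_equal(t1.best, t2.best)

    def test_degenerate_single_candidate_is_a_fixed_point(self, fixture_table):
        cfg = self.small_config(m_candidates=1, candidate_range=(0.2, 0.2),
                                crossover_rate=0.0, mutation_rate=0.0,
                                n_generations=12)
        w, trace = run_gaaco(fixture_table, 4, cfg)
        assert np.allclose(w, 0.2)
        assert np.ptp(trace.best) == 0  # repeated evaluation of one vector

    def test_plateau_stops_before_generation_cap(self, fixture_table):
        cfg = self.small_config(n_generations=400, seed=1)
        _, trace = run_gaaco(fixture_table, 4, cfg)
        assert trace.n_iterations < 400

    def test_exponent_alpha_mode_runs(self, fixture_table):
        _, trace = run_gaaco(fixture_table, 4,
                             self.small_config(alpha_mode="exponent"))
        assert trace.n_iterations >= 1


class TestTrainGaacoBp:
    def test_hybrid_protocol_beats_its_initial_fitness(self, fixture_table):
        spec = SplitSpec(21, 8, seed=0)
        cfg = GAACOConfig(n_ants=10, n_generations=20, seed=0)
        net, fit, trace = train_gaaco_bp(fixture_table, spec, cfg,
                                         TrainConfig(max_epochs=300))
        assert fit.n == 29
        assert fit.r2 is not None and fit.r2 > 0.5
        assert np.all(np.diff(trace.best) <= 0)

    def test_ga_aco_initialization_helps_on_average(self, fixture_table):
        """Paired over seeds, the hybrid-initialized net has lower mean
        validation RMSE than the random-initialized net after identical BP
        refinement (with a small search budget the margin is modest)."""
        from extractopt.ann import MLPSurrogate, Normalization, init_weights, \
            predict_mlp, train_bp
        from extractopt.evaluate import metrics, split
        tcfg = TrainConfig()
        v_bp, v_ga = [], []
        for seed in range(10):
            spec = SplitSpec(21, 8, seed=seed)
            train_t, valid_t = split(fixture_table, spec)
            norm = Normalization.fit(fixture_table.factors, fixture_table.yields)
            net = MLPSurrogate(4, init_weights(4, seed=seed), norm)
            bp, _ = train_bp(net, train_t, tcfg)
            v_bp.append(metrics(valid_t.yields, predict_mlp(bp, valid_t.factors)).rmse)
            ga, _, _ = train_gaaco_bp(fixture_table, spec,
                                      GAACOConfig(seed=seed), tcfg)
            v_ga.append(metrics(valid_t.yields, predict_mlp(ga, valid_t.factors)).rmse)
        assert np.mean(v_ga) < np.mean(v_bp)
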