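"""ACO wrapper selection: probabilities, pheromone dynamics, recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromasense import aco
from chromasense.aco import (
    ACOConfig,
    ACOFeatureSelector,
    AntSolution,
    FrequencyTable,
    PheromoneTable,
    best_cost,
    construct_subset,
    deposit_amount,
    evaluate_subset,
    repeat_runs,
    run,
    run_on_costs,
    select_by_frequency,
    selection_probabilities,
    update_pheromone,
)
from chromasense.bpnn import TrainConfig


class TestSelectionProbabilities:
    def test_hand_computed_ratio(self):
        p = selection_probabilities((2.0, 1.0), (1.0, 1.0))
        assert p == pytest.approx([2 / 3, 1 / 3])

    def test_symmetry(self):
        assert selection_probabilities((3.0, 3.0), (2.0, 2.0)) == \
            pytest.approx([0.5, 0.5])

    def test_zero_beta_ignores_visibility(self):
        p = selection_probabilities((1.0, 1.0), (9.0, 1.0), beta=0.0)
        assert p == pytest.approx([0.5, 0.5])

    @given(st.tuples(*[st.floats(0.01, 100)] * 4),
           st.floats(0, 3), st.floats(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, vals, alpha, beta):
        p = selection_probabilities(vals[:2], vals[2:], alpha, beta)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)


class TestConstructSubset:
    def test_dominant_include_pheromone_selects_everything(self):
        cfg = ACOConfig(seed=0)
        table = PheromoneTable(tau=np.tile([1.0, 1e6], (36, 1)),
                               eta=np.ones((36, 2)))
        rng = np.random.default_rng(0)
        masks = [construct_subset(table, cfg, rng) for _ in range(100)]
        assert np.all([m.all() for m in masks])

    def test_forcing_rule_guarantees_minimum_size(self):
        cfg = ACOConfig(seed=0, min_subset_size=1)
        table = PheromoneTable(tau=np.tile([1e6, 1e-6 + 1e-7], (36, 1)),
                               eta=np.ones((36, 2)))
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert construct_subset(table, cfg, rng).sum() == 1

    def test_empirical_frequency_matches_probability(self):
        cfg = ACOConfig(seed=0)
        tau = np.tile([1.0, 3.0], (36, 1))
        table = PheromoneTable(tau=tau, eta=np.ones((36, 2)))
        rng = np.random.default_rng(2)
        freq = np.mean([construct_subset(table, cfg, rng)
                        for _ in range(10_000)], axis=0)
        assert np.all(np.abs(freq - 0.75) < 0.02)


class TestBestCost:
    def test_perfect_predictions_cost_zero(self):
        assert best_cost([0.0, 0.0], [0.0]) == 0.0

    def test_hand_computed_weighting(self):
        assert best_cost([1.0, 1.0], [2.0]) == pytest.approx(1.25)

    def test_equal_deviations_make_weights_irrelevant(self):
        for tw in (0.5, 0.75, 0.9):
            assert best_cost([1.5, 1.5], [1.5, 1.5], tw, 1 - tw) == \
                pytest.approx(1.5)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            best_cost([], [1.0])


class TestDepositAndUpdate:
    def test_deposit_is_inverse_cost(self):
        assert deposit_amount(2.0, Q=1.0) == 0.5
        assert deposit_amount(1.0, Q=1.0) == 2 * deposit_amount(2.0, Q=1.0)

    def test_zero_cost_deposit_is_capped(self):
        assert deposit_amount(0.0, Q=1.0) == 1.0 / 1e-12

    def test_conventional_evaporation_rule(self):
        cfg = ACOConfig(seed=0, evaporation=0.05)
        table = PheromoneTable(tau=np.ones((2, 2)), eta=np.ones((2, 2)))
        sol = AntSolution(mask=np.array([True, False]), cost=2.0)
        update_pheromone(table, [sol], cfg)
        assert table.tau[0, aco.INCLUDE] == pytest.approx(1.45)
        assert table.tau[1, aco.EXCLUDE] == pytest.approx(1.45)
        assert table.tau[0, aco.EXCLUDE] == pytest.approx(0.95)

    def test_literal_rule_keeps_only_rho_fraction(self):
        cfg = ACOConfig(seed=0, evaporation=0.05,
                        evaporation_mode="literal")
        table = PheromoneTable(tau=np.ones((2, 2)), eta=np.ones((2, 2)))
        update_pheromone(table, [], cfg)
        assert np.allclose(table.tau, 0.05)

    def test_decay_without_deposits_reaches_floor(self):
        cfg = ACOConfig(seed=0, evaporation=0.5)
        table = PheromoneTable(tau=np.ones((2, 2)), eta=np.ones((2, 2)))
        prev = table.tau.copy()
        for _ in range(60):
            update_pheromone(table, [], cfg)
            assert np.all(table.tau <= prev)
            prev = table.tau.copy()
        assert np.allclose(table.tau, 1e-6)


class TestEvaluateSubset:
    def test_informative_mask_beats_noise_mask(self, two_component_split):
        wins = 0
        for seed in range(100):
            tc = TrainConfig(max_epochs=100, seed=seed)
            true_mask = np.zeros(36, bool)
            true_mask[[8, 23]] = True
            noise_mask = np.zeros(36, bool)
            noise_mask[[0, 1]] = True
            a = evaluate_subset(true_mask, two_component_split, tc)
            b = evaluate_subset(noise_mask, two_component_split, tc)
            wins += a.cost < b.cost
        assert wins >= 95

    def test_deterministic_given_seed(self, two_component_split):
        mask = np.zeros(36, bool)
        mask[[8, 23]] = True
        tc = TrainConfig(max_epochs=100, seed=3)
        a = evaluate_subset(mask, two_component_split, tc)
        b = evaluate_subset(mask, two_component_split, tc)
        assert a.cost == b.cost

    def test_noise_component_gains_at_most_noise_floor(self, two_component_split):
        deltas = []
        for seed in range(20):
            tc = TrainConfig(max_epochs=100, seed=seed)
            true_mask = np.zeros(36, bool)
            true_mask[[8, 23]] = True
            aug = true_mask.copy()
            aug[0] = True
            deltas.append(evaluate_subset(true_mask, two_component_split, tc).cost
                          - evaluate_subset(aug, two_component_split, tc).cost)
        assert np.median(deltas) <= 0.05

    def test_metrics_populated(self, two_component_split):
        mask = np.zeros(36, bool)
        mask[[8, 23]] = True
        sol = evaluate_subset(mask, two_component_split,
                              TrainConfig(max_epochs=100, seed=0))
        assert set(sol.metrics) == {"Rc2", "RMSECV", "Rp2", "RMSEP"}
        assert sol.cost >= 0

    def test_empty_mask_rejected(self, two_component_split):
        with pytest.raises(ValueError):
            evaluate_subset(np.zeros(36, bool), two_component_split)


def _table_cost_fn(costs):
    def fn(mask):
        return AntSolution(mask=mask.copy(),
                           cost=costs[tuple(np.flatnonzero(mask))])
    return fn


class TestRunOnCosts:
    def make_table(self):
        """Deterministic 4-component cost table with optimum {0, 2}."""
        rng = np.random.default_rng(99)
        costs = {}
        for r in range(1, 5):
            for sub in itertools.combinations(range(4), r):
                costs[sub] = float(rng.uniform(0.5, 2.0))
        costs[(0, 2)] = 0.1
        return costs

    def test_finds_enumerated_optimum(self):
        costs = self.make_table()
        optimum = min(costs, key=costs.get)
        hits = 0
        for seed in range(20):
            cfg = ACOConfig(n_ants=20, max_iterations=50, seed=seed,
                            visibility_mode="uniform")
            res = run_on_costs(_table_cost_fn(costs), 4, cfg)
            hits += tuple(np.flatnonzero(res.best_solution.mask)) == optimum
        assert hits >= 19

    def test_curve_is_non_increasing_and_deterministic(self):
        costs = self.make_table()
        cfg = ACOConfig(n_ants=5, max_iterations=20, seed=7,
                        visibility_mode="uniform")
        a = run_on_costs(_table_cost_fn(costs), 4, cfg)
        b = run_on_costs(_table_cost_fn(costs), 4, cfg)
        assert np.all(np.diff(a.convergence_curve) <= 0)
        assert np.array_equal(a.convergence_curve, b.convergence_curve)
        assert np.array_equal(a.best_solution.mask, b.best_solution.mask)
        assert len(a.convergence_curve) == 20
        assert 0 <= a.convergence_iteration < 20


class TestRunAndRepeat:
    def test_single_run_recovers_informative_pair(self, two_component_split):
        cfg = ACOConfig(n_ants=10, max_iterations=30, seed=5)
        res = run(two_component_split, cfg, TrainConfig(max_epochs=200))
        chosen = set(np.flatnonzero(res.best_solution.mask))
        assert {8, 23} <= chosen
        assert np.all(np.diff(res.convergence_curve) <= 0)

    def test_repeat_runs_frequency_bookkeeping(self, two_component_split):
        cfg = ACOConfig(n_ants=6, max_iterations=10)
        results, freq = repeat_runs(two_component_split, cfg,
                                    TrainConfig(max_epochs=100),
                                    n_runs=3, base_seed=40)
        assert freq.n_runs == 3
        assert np.all(freq.counts <= 3)
        tally = np.sum([r.best_solution.mask for r in results], axis=0)
        assert np.array_equal(freq.counts, tally)
        assert [r.seed for r in results] == [41, 42, 43]


class TestSelectByFrequency:
    def test_constructed_table(self):
        counts = np.zeros(36, int)
        counts[4], counts[11] = 30, 26
        counts[20] = 5
        freq = FrequencyTable(counts=counts, n_runs=50)
        assert select_by_frequency(freq, 25) == [4, 11]

    def test_zero_threshold_selects_all(self):
        freq = FrequencyTable(counts=np.zeros(36, int), n_runs=50)
        assert len(select_by_frequency(freq, 0)) == 36

    def test_ordering_by_count_then_index(self):
        counts = np.zeros(36, int)
        counts[[3, 7, 30]] = (20, 25, 20)
        freq = FrequencyTable(counts=counts, n_runs=50)
        assert select_by_frequency(freq, 20) == [7, 3, 30]

    def test_out_of_range_threshold_rejected(self):
        freq = FrequencyTable(counts=np.zeros(36, int), n_runs=50)
        with pytest.raises(ValueError):
            select_by_frequency(freq, 51)


class TestSelectorEstimator:
    def test_selector_transform_keeps_informative_columns(self, rng):
        n = 120
        od = rng.uniform(0.1, 9, n)
        X = rng.normal(0, 1, (n, 12))
        X[:, 3] = 6 * od / (od + 1.5) + rng.normal(0, 0.2, n)
        X[:, 7] = -5 * od / (od + 1.5) + rng.normal(0, 0.2, n)
        sel = ACOFeatureSelector(n_ants=8, max_iterations=15,
                                 bpnn_max_epochs=100, random_state=0)
        sel.fit(X, od)
        support = np.flatnonzero(sel.support_)
        assert {3, 7} <= set(support)
        assert sel.transform(X).shape == (n, len(support))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        sel = ACOFeatureSelector(random_state=3)
        assert clone(sel).get_params() == sel.get_params()
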