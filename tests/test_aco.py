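"""Attribute graphs, ant walks, pheromone dynamics, and the combined search."""

import numpy as np
import pytest

import antbayes as ab
from antbayes.aco import (
    AntPath,
    AttributeGraph,
    Edge,
    PHEROMONE_FLOOR,
    _PathEvaluator,
    build_attribute_graph,
    path_to_composition,
)

from conftest import make_comp, make_model


def manual_graph(tau_eta_per_interval):
    """Graph with explicit (pheromone, cond_probs) per edge for rule tests."""
    m = len(tau_eta_per_interval)
    edges = [
        [Edge(j, e, np.asarray(probs), tau) for e, (tau, probs) in enumerate(bundle)]
        for j, bundle in enumerate(tau_eta_per_interval)
    ]
    return AttributeGraph("x", np.arange(m + 1, dtype=float), edges, len(tau_eta_per_interval[0]))


def two_manual_experts():
    a = make_model([make_comp("x", [0, 5, 10], [0.6, 0.4], [0.2, 0.8])])
    b = make_model([make_comp("x", [0, 3, 5, 10], [0.3, 0.3, 0.4], [0.1, 0.1, 0.8])])
    return [a, b]


class TestGraphConstruction:
    def test_composite_boundary_union(self):
        graph = build_attribute_graph(two_manual_experts(), "x")
        assert graph.boundaries.tolist() == [0.0, 3.0, 5.0, 10.0]
        assert graph.m == 3
        assert sum(len(bundle) for bundle in graph.edges) == 6

    def test_projected_edge_probabilities(self):
        graph = build_attribute_graph(two_manual_experts(), "x")
        # expert 0's [0,5) mass 0.6 splits width-proportionally: 3/5 and 2/5
        assert graph.edges[0][0].cond_probs == pytest.approx([0.36, 0.12])
        assert graph.edges[1][0].cond_probs == pytest.approx([0.24, 0.08])
        # expert 1's own intervals project onto themselves unchanged
        assert graph.edges[0][1].cond_probs == pytest.approx([0.3, 0.1])

    def test_identical_experts_give_identical_edges(self):
        e = make_model([make_comp("x", [0, 4, 8], [0.5, 0.5], [0.3, 0.7])])
        graph = build_attribute_graph([e, ab.assemble(e, {})], "x")
        for bundle in graph.edges:
            assert bundle[0].cond_probs == pytest.approx(bundle[1].cond_probs)

    def test_missing_attribute_rejected(self):
        experts = two_manual_experts()
        with pytest.raises(KeyError):
            build_attribute_graph(experts, "y")

    def test_near_duplicate_boundaries_merged(self):
        a = make_model([make_comp("x", [0, 5, 10], [0.6, 0.4], [0.2, 0.8])])
        b = make_model([make_comp("x", [0, 5 + 1e-12, 10], [0.5, 0.5], [0.5, 0.5])])
        graph = build_attribute_graph([a, b], "x")
        assert graph.m == 2


class TestProjection:
    comp = make_comp("x", [0, 10], [0.4], [1.0])

    def test_half_of_an_interval_gets_half_its_mass(self):
        out = ab.project_probabilities(self.comp, ab.Interval(0, 5, 0))
        assert out == pytest.approx([0.2, 0.5])

    def test_full_interval_is_identity(self):
        out = ab.project_probabilities(self.comp, ab.Interval(0, 10, 0))
        assert out == pytest.approx([0.4, 1.0])

    def test_sub_intervals_telescope_back(self):
        cuts = [0, 1.5, 4.0, 7.25, 10]
        parts = [
            ab.project_probabilities(self.comp, ab.Interval(cuts[i], cuts[i + 1], i))
            for i in range(4)
        ]
        assert np.sum(parts, axis=0) == pytest.approx([0.4, 1.0], abs=1e-12)

    def test_inherit_projection_copies_enclosing_interval(self):
        comp = make_comp("x", [0, 5, 10], [0.6, 0.4], [0.2, 0.8])
        out = ab.project_probabilities(comp, ab.Interval(0, 2, 0), projection="inherit")
        assert out == pytest.approx([0.6, 0.2])


class TestTransitionRule:
    def test_symmetric_edges_uniform(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        assert ab.transition_probabilities(g, 0, 2.0, 1.0) == pytest.approx([1 / 3] * 3)

    def test_pheromone_only_limit(self):
        g = manual_graph([[(2.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        assert ab.transition_probabilities(g, 0, 1.0, 0.0) == pytest.approx([2 / 3, 1 / 3])

    def test_visibility_only_limit(self):
        g = manual_graph([[(1.0, (0.5, 0.3)), (1.0, (0.1, 0.1))]])
        assert ab.transition_probabilities(g, 0, 0.0, 1.0) == pytest.approx([0.8, 0.2])

    def test_zero_weights_fall_back_to_uniform(self):
        g = manual_graph([[(1.0, (0.0, 0.0)), (1.0, (0.0, 0.0))]])
        assert ab.transition_probabilities(g, 0, 0.0, 1.0) == pytest.approx([0.5, 0.5])


class TestRouletteSelect:
    def test_degenerate_wheel_always_picks_the_mass(self):
        rng = np.random.default_rng(0)
        assert all(ab.roulette_select([1.0, 0.0, 0.0], rng) == 0 for _ in range(20))

    def test_uniform_wheel_frequencies(self):
        rng = np.random.default_rng(1)
        draws = np.asarray([ab.roulette_select([1, 1, 1, 1], rng) for _ in range(100_000)])
        freqs = np.bincount(draws, minlength=4) / len(draws)
        assert freqs == pytest.approx([0.25] * 4, abs=0.01)

    def test_seeded_reproducibility(self):
        a = [ab.roulette_select([0.2, 0.3, 0.5], np.random.default_rng(7)) for _ in range(5)]
        b = [ab.roulette_select([0.2, 0.3, 0.5], np.random.default_rng(7)) for _ in range(5)]
        assert a == b


class TestSolutionConstruction:
    def test_path_length_matches_intervals(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        path = ab.construct_solution(g, ab.ACOConfig(), np.random.default_rng(0))
        assert len(path) == 1

    def test_zero_exponents_give_uniform_expert_choice(self):
        g = manual_graph(
            [[(5.0, (0.9, 0.9)), (1.0, (0.1, 0.1))], [(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]]
        )
        cfg = ab.ACOConfig(alpha=0.0, beta=0.0)
        rng = np.random.default_rng(3)
        picks = np.asarray([ab.construct_solution(g, cfg, rng).choices for _ in range(4000)])
        assert picks.mean(axis=0) == pytest.approx([0.5, 0.5], abs=0.05)

    def test_heavy_pheromone_dominates(self):
        g = manual_graph(
            [[(1e6, (0.5, 0.5)), (1.0, (0.5, 0.5))], [(1.0, (0.5, 0.5)), (1e6, (0.5, 0.5))]]
        )
        cfg = ab.ACOConfig(alpha=1.0, beta=0.0)
        rng = np.random.default_rng(5)
        paths = [ab.construct_solution(g, cfg, rng).choices for _ in range(200)]
        assert np.mean([p == (0, 1) for p in paths]) > 0.99

    def test_path_to_composition_counts_and_normalization(self):
        graph = build_attribute_graph(two_manual_experts(), "x")
        mixed = AntPath((0, 1, 0))
        raw = path_to_composition(graph, mixed, renormalize=False)
        assert raw.n_chunks == 3
        norm = path_to_composition(graph, mixed, renormalize=True)
        assert norm.probs_matrix().sum(axis=0) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_single_expert_path_needs_no_renormalization(self):
        graph = build_attribute_graph(two_manual_experts(), "x")
        for e in range(2):
            comp = path_to_composition(graph, AntPath((e, e, e)), renormalize=False)
            assert comp.probs_matrix().sum(axis=0) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_incomplete_path_rejected(self):
        graph = build_attribute_graph(two_manual_experts(), "x")
        with pytest.raises(ValueError, match="incomplete"):
            path_to_composition(graph, AntPath((0,)))


class TestPheromoneUpdate:
    def test_no_evaporation_no_quality_is_identity(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        ab.update_pheromone(g, AntPath((0,)), 0.0, ab.ACOConfig(rho=0.0))
        assert [e.pheromone for e in g.edges[0]] == [1.0, 1.0]

    def test_full_evaporation_leaves_only_deposit(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        cfg = ab.ACOConfig(rho=1.0, delta=2.0)
        ab.update_pheromone(g, AntPath((0,)), 0.5, cfg)
        assert g.edges[0][0].pheromone == pytest.approx(2.0 * 0.5)
        assert g.edges[0][1].pheromone == pytest.approx(PHEROMONE_FLOOR)

    def test_update_arithmetic(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        cfg = ab.ACOConfig(rho=0.02, delta=1.0)
        ab.update_pheromone(g, AntPath((0,)), 0.75, cfg)
        assert g.edges[0][0].pheromone == pytest.approx(0.98 + 0.75)
        assert g.edges[0][1].pheromone == pytest.approx(0.98)

    def test_pheromone_decays_to_floor_without_quality(self):
        g = manual_graph([[(1.0, (0.5, 0.5)), (1.0, (0.5, 0.5))]])
        cfg = ab.ACOConfig(rho=0.5, delta=1.0)
        for _ in range(100):
            ab.update_pheromone(g, AntPath((0,)), 0.0, cfg)
        assert all(e.pheromone >= PHEROMONE_FLOOR for e in g.edges[0])
        assert g.edges[0][1].pheromone == pytest.approx(PHEROMONE_FLOOR)


class TestEvaluation:
    def test_own_composition_reproduces_base_j(self, cohort, pool):
        base = pool[0]
        comp = base.composition("marker")
        j = ab.evaluate_solution(base, "marker", comp, cohort)
        assert j == pytest.approx(ab.j_score(base, cohort))

    def test_uninformative_attribute_equals_marginalized_model(self, cohort):
        informative = make_comp("marker", [-4, 0, 4], [0.8, 0.2], [0.2, 0.8])
        flat = make_comp("noise0", [-4, 0, 4], [0.5, 0.5], [0.5, 0.5])
        full = make_model([informative, flat])
        marginal = make_model([informative])
        j_full = ab.j_score(full, cohort)
        j_marginal = ab.j_score(
            marginal, ab.Dataset(cohort.X[["marker"]], cohort.y, [("marker", "continuous")])
        )
        assert j_full == pytest.approx(j_marginal)

    def test_fast_evaluator_matches_assemble_route(self, cohort, pool):
        graph = build_attribute_graph(pool, "marker")
        ev = _PathEvaluator(pool[0], graph, cohort, renormalize=True)
        rng = np.random.default_rng(2)
        for _ in range(10):
            choices = tuple(rng.integers(0, graph.n_experts, graph.m))
            comp = path_to_composition(graph, AntPath(choices), renormalize=True)
            assert ev.j_for_choices(choices) == pytest.approx(
                ab.evaluate_solution(pool[0], "marker", comp, cohort), abs=1e-12
            )


class TestOptimization:
    def test_single_iteration_single_ant_one_evaluation(self, cohort, pool):
        cfg = ab.ACOConfig(n_iterations=1, n_ants=1, seed=0)
        _, trace = ab.optimize_attribute(pool, pool[0], "marker", cohort, cfg)
        assert trace.evaluations_count == 1
        assert len(trace.best_so_far) == 1

    def test_best_so_far_never_decreases(self, cohort, pool):
        cfg = ab.ACOConfig(n_iterations=8, n_ants=4, seed=1)
        _, trace = ab.optimize_attribute(pool, pool[0], "marker", cohort, cfg)
        assert trace.best_so_far == sorted(trace.best_so_far)

    def test_oracle_bounds_and_budgeted_equivalence(self):
        # two coarse experts -> at most 6 composite intervals (<= 64 paths)
        data = ab.generate_dataset(
            ab.CohortConfig(
                160, 0.5,
                [ab.continuous_spec("x", separation=1.5), ab.continuous_spec("z")],
                seed=21,
            )
        )
        half = len(data) // 2
        e1 = ab.train_naive_bayes(data.subset_rows(range(half)), n_bins=2)
        e2 = ab.train_naive_bayes(data.subset_rows(range(half, len(data))), n_bins=3)
        context = ab.generate_dataset(
            ab.CohortConfig(
                150, 0.5,
                [ab.continuous_spec("x", separation=1.5), ab.continuous_spec("z")],
                seed=22,
            )
        )
        experts = [e1, e2]
        _, oracle_j = ab.exhaustive_oracle(experts, e1, "x", context)
        cfg = ab.ACOConfig(n_iterations=80, n_ants=40, seed=0)
        _, trace = ab.optimize_attribute(experts, e1, "x", context, cfg)
        assert trace.best_so_far[-1] <= oracle_j + 1e-12
        assert trace.best_so_far[-1] == pytest.approx(oracle_j, abs=1e-12)

    def test_oracle_cap(self, cohort, pool):
        with pytest.raises(ValueError, match="cap"):
            ab.exhaustive_oracle(pool, pool[0], "marker", cohort, cap=4)


class TestCombine:
    def test_identical_expert_pool_is_a_fixed_point(self, cohort):
        e = ab.train_naive_bayes(cohort, n_bins=3)
        twin = ab.NaiveBayesClassifier.from_json(e.to_json())
        cfg = ab.ACOConfig(n_iterations=2, n_ants=3, seed=0)
        composite, _ = ab.combine_classifiers([e, twin], cohort, cfg)
        assert ab.j_score(composite, cohort) == pytest.approx(ab.j_score(e, cohort))

    def test_composite_never_below_best_expert_on_context(self, cohort, pool):
        cfg = ab.ACOConfig(n_iterations=3, n_ants=4, seed=2)
        composite, traces = ab.combine_classifiers(pool, cohort, cfg)
        best = ab.best_expert(pool, cohort)
        assert ab.j_score(composite, cohort) >= ab.j_score(best, cohort) - 1e-12
        assert set(traces) == {c.attribute_name for c in composite.continuous_attrs}

    def test_fixed_seed_reproduces_composite_exactly(self, cohort, pool):
        cfg = ab.ACOConfig(n_iterations=3, n_ants=4, seed=5)
        a, _ = ab.combine_classifiers(pool, cohort, cfg)
        b, _ = ab.combine_classifiers(pool, cohort, cfg)
        assert a.to_json() == b.to_json()

    def test_mismatched_schemas_rejected(self, cohort, pool):
        lone = make_model([make_comp("other", [0, 1], [1.0], [1.0])])
        with pytest.raises(ValueError, match="schema"):
            ab.combine_classifiers([pool[0], lone], cohort, ab.ACOConfig())
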