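import numpy as np
import pytest

from conftest import make_discrete, random_discrete
from oracles import best_dag_by_enumeration
from pacobn.cbn import CBN
from pacobn.colony import (ColonyConfig, candidate_arcs,
                           construct_cbn, global_pheromone_update,
                           init_pheromone, local_pheromone_update,
                           local_search, run_colony, select_arc)
from pacobn.scoring import K2Scorer


def cfg_with(**kw):
    return ColonyConfig(**kw)


class TestPheromoneUpdates:
    def test_local_update_arithmetic(self):
        p = init_pheromone(3, 0.1)
        p[0, 1] = 1.0
        local_pheromone_update(p, (0, 1), cfg_with(rho=0.35, tau0=0.1))
        assert p[0, 1] == pytest.approx(0.685)

    def test_local_update_fixed_point_at_tau0(self):
        p = init_pheromone(3, 0.1)
        local_pheromone_update(p, (1, 2), cfg_with(rho=0.35, tau0=0.1))
        assert p[1, 2] == pytest.approx(0.1)

    def test_local_update_touches_only_selected_arc(self):
        p = init_pheromone(3, 0.2)
        p[:] = 0.7
        before = p.copy()
        local_pheromone_update(p, (2, 0), cfg_with(rho=0.5, tau0=0.2))
        changed = p != before
        assert changed.sum() == 1 and changed[2, 0]

    def test_repeated_local_updates_contract_to_tau0(self):
        p = init_pheromone(2, 0.1)
        p[0, 1] = 5.0
        gaps = []
        for _ in range(10):
            local_pheromone_update(p, (0, 1), cfg_with(rho=0.35, tau0=0.1))
            gaps.append(abs(p[0, 1] - 0.1))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_global_update_arithmetic_and_no_op(self):
        p = init_pheromone(3, 0.1)
        g = CBN.from_edges([(0, 1)], 3)
        before = p.copy()
        global_pheromone_update(p, g, -100.0, cfg_with(rho=0.35, tau0=0.1))
        assert p[0, 1] == pytest.approx(0.65 * 0.1 + 0.35 * 0.01)
        mask = np.ones_like(p, dtype=bool)
        mask[0, 1] = False
        assert (p[mask] == before[mask]).all()

    def test_better_score_deposits_more(self):
        g = CBN.from_edges([(0, 1)], 3)
        p1 = init_pheromone(3, 0.1)
        p2 = init_pheromone(3, 0.1)
        global_pheromone_update(p1, g, -50.0, cfg_with())
        global_pheromone_update(p2, g, -500.0, cfg_with())
        assert p1[0, 1] > p2[0, 1]

    def test_pheromone_stays_positive(self):
        p = init_pheromone(3, 1e-6)
        g = CBN.from_edges([(0, 1), (1, 2)], 3)
        cfg = cfg_with(rho=1.0, tau0=1e-6)
        for _ in range(5):
            local_pheromone_update(p, (0, 2), cfg)
            global_pheromone_update(p, g, -10.0, cfg)
        assert (p > 0).all()


class TestSelectArc:
    def test_single_candidate_forced(self, rng):
        p = init_pheromone(3, 0.1)
        arc = select_arc([(0, 1, 2.5)], p, cfg_with(), rng)
        assert arc == (0, 1)

    def test_exploitation_takes_argmax_of_tau_eta_beta(self):
        p = init_pheromone(3, 0.1)
        p[0, 1], p[0, 2], p[1, 2] = 0.3, 0.2, 0.1
        cands = [(0, 1, 1.0), (0, 2, 2.0), (1, 2, 3.0)]
        cfg = cfg_with(q0=0.999, beta=2.0)
        rng = np.random.default_rng(0)
        products = {(u, c): p[u, c] * e**cfg.beta for u, c, e in cands}
        expected = max(products, key=products.get)
        for _ in range(20):
            assert select_arc(cands, p, cfg, rng) == expected

    def test_exploration_frequencies_match_closed_form(self):
        p = init_pheromone(3, 0.1)
        p[0, 1], p[0, 2], p[1, 2] = 0.4, 0.2, 0.1
        cands = [(0, 1, 1.0), (0, 2, 2.0), (1, 2, 3.0)]
        cfg = cfg_with(q0=0.0, alpha=1.2, beta=2.0)
        w = np.array([p[u, c]**cfg.alpha * e**cfg.beta for u, c, e in cands])
        probs = w / w.sum()
        rng = np.random.default_rng(42)
        n = 20_000
        counts = np.zeros(3)
        index = {(u, c): k for k, (u, c, _) in enumerate(cands)}
        for _ in range(n):
            counts[index[select_arc(cands, p, cfg, rng)]] += 1
        for k in range(3):
            se = np.sqrt(n * probs[k] * (1 - probs[k]))
            assert abs(counts[k] - n * probs[k]) < 3 * se

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_arc([], init_pheromone(2, 0.1), cfg_with(), rng)


class TestCandidateArcs:
    def test_strong_dependence_offers_both_orientations(self, rng):
        x = rng.integers(0, 2, 500)
        noise = rng.random(500) < 0.05
        y = np.where(noise, 1 - x, x)
        data = make_discrete(np.column_stack([x, y]))
        scorer = K2Scorer(data)
        cands = {(u, c) for u, c, _ in candidate_arcs(CBN(2), scorer)}
        assert cands == {(0, 1), (1, 0)}

    def test_cycle_closing_arcs_never_appear(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        g = CBN.from_edges([(0, 1), (1, 2)], 3)
        for u, c, _ in candidate_arcs(g, scorer):
            g2 = g.copy()
            g2.add_arc(u, c)
            assert g2.is_acyclic()
        assert (2, 0) not in {(u, c) for u, c, _ in candidate_arcs(g, scorer)}

    def test_all_heuristics_positive(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        assert all(h > 0 for _, _, h in candidate_arcs(CBN(3), scorer))


class TestConstruction:
    def test_independent_columns_yield_sparse_graph(self, independent_dataset):
        scorer = K2Scorer(independent_dataset)
        p = init_pheromone(3, 0.1)
        g, _ = construct_cbn(scorer, p, cfg_with(), np.random.default_rng(0))
        assert g.n_arcs <= 1  # at most a spurious arc on 300 samples

    def test_construction_result_is_acyclic_and_scored(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        p = init_pheromone(3, 0.1)
        g, s = construct_cbn(scorer, p, cfg_with(), np.random.default_rng(1))
        assert g.is_acyclic()
        assert s == pytest.approx(scorer.network_score(g))

    def test_greedy_limit_recovers_enumerated_optimum(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        _, best = best_dag_by_enumeration(
            chain3_dataset.levels, chain3_dataset.cardinalities,
            scorer.network_score)
        p = init_pheromone(3, 0.1)
        g, s = construct_cbn(scorer, p, cfg_with(q0=0.999),
                             np.random.default_rng(0))
        g, s = local_search(g, scorer, cfg_with())
        assert s == pytest.approx(best, rel=1e-9)

    def test_every_arc_addition_strictly_improves(self, chain3_dataset):
        # candidates have positive heuristic, so the final score exceeds
        # the empty-graph score whenever any arc was added
        scorer = K2Scorer(chain3_dataset)
        p = init_pheromone(3, 0.1)
        g, s = construct_cbn(scorer, p, cfg_with(), np.random.default_rng(3))
        if g.n_arcs:
            assert s > scorer.network_score(CBN(3))


class TestLocalSearch:
    def test_local_optimum_is_fixed_point(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        g, s = local_search(CBN(3), scorer, cfg_with())
        g2, s2 = local_search(g, scorer, cfg_with())
        assert s2 == s and g2 == g

    def test_reversal_fixes_backward_orientation(self, rng):
        # truth X -> Y with an asymmetric coding that makes X -> Y score
        # higher; start from Y -> X and expect the reversal applied
        x = rng.integers(0, 2, 400)
        y = (x + (rng.random(400) < 0.2).astype(int) +
             rng.integers(0, 2, 400))  # 4-level child
        data = make_discrete(np.column_stack([x, np.clip(y, 0, 3),
                                              rng.integers(0, 2, 400)]))
        scorer = K2Scorer(data)
        fwd = CBN.from_edges([(0, 1)], 3)
        bwd = CBN.from_edges([(1, 0)], 3)
        if scorer.network_score(fwd) > scorer.network_score(bwd):
            g, s = local_search(bwd, scorer, cfg_with())
            assert s >= scorer.network_score(fwd) - 1e-9

    def test_score_never_decreases(self, rng):
        data = random_discrete(rng, v=4, m=60)
        scorer = K2Scorer(data)
        g0 = CBN.from_edges([(0, 1), (2, 3)], 4)
        s0 = scorer.network_score(g0)
        g, s = local_search(g0, scorer, cfg_with())
        assert s >= s0
        assert g.is_acyclic()


class TestColonyRuns:
    def test_best_score_non_decreasing_and_consistent(self, chain3_dataset):
        res = run_colony(chain3_dataset, cfg_with(num_ants=5, n_iterations=4),
                         seed=0)
        trace = res.iteration_trace
        assert all(a <= b + 1e-12 for a, b in zip(trace, trace[1:]))
        scorer = K2Scorer(chain3_dataset)
        assert res.best_score == pytest.approx(
            scorer.network_score(res.best_graph))
        assert res.best_graph.is_acyclic()

    def test_identical_seeds_identical_trajectories(self, chain3_dataset):
        a = run_colony(chain3_dataset, cfg_with(num_ants=4, n_iterations=3),
                       seed=7)
        b = run_colony(chain3_dataset, cfg_with(num_ants=4, n_iterations=3),
                       seed=7)
        assert a.iteration_trace == b.iteration_trace
        assert a.best_graph == b.best_graph
        np.testing.assert_array_equal(a.pheromone, b.pheromone)

    def test_colony_reaches_enumerated_optimum_on_chain(self, chain3_dataset):
        scorer = K2Scorer(chain3_dataset)
        _, best = best_dag_by_enumeration(
            chain3_dataset.levels, chain3_dataset.cardinalities,
            scorer.network_score)
        res = run_colony(chain3_dataset, cfg_with(), seed=0)
        assert res.best_score == pytest.approx(best, rel=1e-9)


def test_colony_config_validation():
    with pytest.raises(ValueError):
        ColonyConfig(rho=0.0)
    with pytest.raises(ValueError):
        ColonyConfig(q0=1.0)
    with pytest.raises(ValueError):
        ColonyConfig(tau0=0.0)
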