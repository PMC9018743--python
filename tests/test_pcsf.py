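"""PCSF engine: prize adjustment, objective, heuristic vs exact oracle."""

import networkx as nx
import numpy as np
import pytest

from drugnetstrat.pcsf import (
    Forest,
    PCSFParams,
    adjust_prizes,
    brute_force_pcsf,
    default_grid,
    grid_reconstruct,
    pcsf_objective,
    solve_pcsf,
)
from drugnetstrat.terminals import InfeasibleCondition, TerminalSet
from tests.conftest import make_graph


def unit_cost_graph(edges):
    """Edges with weight 0 => solver cost 1 per edge."""
    return make_graph(edges, default_weight=0.0)


def path_instance():
    """t1 - s - t2 with unit edge costs and terminal prizes 5."""
    g = unit_cost_graph([("t1", "s"), ("s", "t2")])
    return g, {"t1": 5.0, "t2": 5.0}


class TestAdjustPrizes:
    def test_substitution(self):
        g = nx.star_graph(10)
        g = nx.relabel_nodes(g, {0: "v", **{i: f"n{i}" for i in range(1, 11)}})
        nx.set_edge_attributes(g, 0.5, "weight")
        adj = adjust_prizes({"v": 2.0}, g, PCSFParams(beta=3, mu=0.1))
        assert adj["v"] == pytest.approx(3 * 2.0 - 0.1 * 10)  # = 5.0

    def test_mu_zero_scales_by_beta_only(self):
        g = make_graph([("a", "b")])
        adj = adjust_prizes({"a": 1.5}, g, PCSFParams(beta=4, mu=0.0))
        assert adj["a"] == pytest.approx(6.0)
        assert adj["b"] == 0.0

    def test_non_terminal_hub_penalty(self):
        g = make_graph([("v", x) for x in "abcd"])
        adj = adjust_prizes({"a": 1.0}, g, PCSFParams(beta=1, mu=0.5))
        assert adj["v"] == pytest.approx(-2.0)

    def test_missing_terminal_warns_and_drops(self):
        g = make_graph([("a", "b")])
        with pytest.warns(UserWarning):
            adj = adjust_prizes({"zz": 1.0}, g, PCSFParams())
        assert "zz" not in adj


class TestObjective:
    def test_empty_forest_forfeits_positive_prizes(self):
        g, prizes = path_instance()
        obj = pcsf_objective(Forest(), g, prizes, PCSFParams(beta=1, omega=1))
        assert obj == pytest.approx(10.0)

    def test_connected_path_forest(self):
        g, prizes = path_instance()
        f = Forest(nodes={"t1", "s", "t2"}, edges={("t1", "s"), ("s", "t2")})
        obj = pcsf_objective(f, g, prizes, PCSFParams(beta=1, omega=1))
        assert obj == pytest.approx(0 + 2 + 1)

    def test_two_singletons_beat_connected_tree(self):
        g, prizes = path_instance()
        f = Forest(nodes={"t1", "t2"})
        obj = pcsf_objective(f, g, prizes, PCSFParams(beta=1, omega=1))
        assert obj == pytest.approx(2.0)

    def test_foreign_edge_rejected(self):
        g, prizes = path_instance()
        f = Forest(nodes={"t1", "t2"}, edges={("t1", "t2")})
        with pytest.raises(ValueError):
            pcsf_objective(f, g, prizes, PCSFParams())

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Forest(nodes={"a", "b", "c"}, edges={("a", "b"), ("b", "c"), ("a", "c")})


class TestBruteForce:
    def test_single_terminal_kept_as_singleton(self):
        g = make_graph([("t", "x")])
        f = brute_force_pcsf(g, {"t": 5.0}, PCSFParams(beta=1, omega=1))
        assert f.nodes == {"t"} and f.objective == pytest.approx(1.0)

    def test_all_zero_prizes_empty_forest(self):
        g, _ = path_instance()
        f = brute_force_pcsf(g, {}, PCSFParams())
        assert f.nodes == set() and f.objective == 0.0

    def test_triangle_of_terminals_one_tree_two_edges(self):
        g = unit_cost_graph([("a", "b"), ("b", "c"), ("a", "c")])
        prizes = {v: 10.0 for v in "abc"}
        f = brute_force_pcsf(g, prizes, PCSFParams(beta=1, omega=1))
        assert f.nodes == {"a", "b", "c"}
        assert len(f.edges) == 2 and f.kappa == 1
        assert f.objective == pytest.approx(3.0)

    def test_refuses_large_instances(self):
        g = nx.relabel_nodes(nx.path_graph(13), str)
        nx.set_edge_attributes(g, 0.5, "weight")
        with pytest.raises(ValueError):
            brute_force_pcsf(g, {"0": 1.0}, PCSFParams())


class TestSolve:
    def test_path_instance_matches_oracle(self):
        g, prizes = path_instance()
        params = PCSFParams(beta=1, omega=1)
        f = solve_pcsf(g, prizes, params)
        exact = brute_force_pcsf(g, prizes, params)
        assert exact.objective == pytest.approx(2.0)
        assert f.objective == pytest.approx(exact.objective)

    def test_isolated_terminal_worth_its_tree(self):
        g = make_graph([("a", "b")])
        g.add_node("t")
        f = solve_pcsf(g, {"t": 5.0}, PCSFParams(beta=1, omega=1))
        assert f.nodes == {"t"}

    def test_cheap_terminal_excluded(self):
        g = make_graph([("t", "x")])
        f = solve_pcsf(g, {"t": 0.5}, PCSFParams(beta=1, omega=1))
        assert f.nodes == set()
        assert f.objective == pytest.approx(0.5)  # forfeited prize

    def test_no_positive_prize_raises(self):
        g = make_graph([("a", "b")])
        with pytest.raises(InfeasibleCondition):
            solve_pcsf(g, {}, PCSFParams())

    def test_deterministic(self, default_cohort):
        b = default_cohort
        ts = TerminalSet({p: (1.0, "tf") for p in sorted(b.gene_sets["module_00"])[:8]})
        params = PCSFParams(beta=2, omega=1)
        f1 = solve_pcsf(b.interactome, ts, params)
        f2 = solve_pcsf(b.interactome, ts, params)
        assert f1.nodes == f2.nodes and f1.edges == f2.edges


def random_instance(rng, n=8):
    g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, lambda i: f"n{i}")
    for u, v in g.edges():
        g.edges[u, v]["weight"] = float(rng.uniform(0.05, 0.95))
    k = int(rng.integers(2, 5))
    terms = rng.choice(sorted(g.nodes()), size=min(k, n), replace=False)
    prizes = {str(t): float(rng.uniform(0.2, 3.0)) for t in terms}
    params = PCSFParams(
        beta=float(rng.choice([1, 2, 5])),
        mu=float(rng.choice([0.0, 0.05, 0.2])),
        omega=float(rng.choice([0.5, 1.0, 2.0])),
    )
    return g, prizes, params


class TestHeuristicQuality:
    def test_admissible_and_mostly_optimal(self, rng):
        """Heuristic never beats the oracle, never loses to the empty forest,
        and matches the optimum on most small random instances."""
        n_eq = n_tot = 0
        for _ in range(40):
            g, prizes, params = random_instance(rng)
            try:
                f = solve_pcsf(g, prizes, params)
            except InfeasibleCondition:
                continue
            exact = brute_force_pcsf(g, prizes, params)
            adjusted = adjust_prizes(prizes, g, params)
            empty_obj = sum(p for p in adjusted.values() if p > 0)
            assert f.objective >= exact.objective - 1e-9
            assert f.objective <= empty_obj + 1e-9
            n_tot += 1
            n_eq += f.objective <= exact.objective + 1e-9
        assert n_tot > 30
        assert n_eq / n_tot >= 0.8

    def test_forests_acyclic_with_terminal_per_tree(self, rng):
        for _ in range(20):
            g, prizes, params = random_instance(rng)
            try:
                f = solve_pcsf(g, prizes, params)
            except InfeasibleCondition:
                continue
            if not f.nodes:
                continue
            fg = f.graph()
            assert nx.is_forest(fg)
            for comp in nx.connected_components(fg):
                assert comp & set(prizes), "every tree must touch a terminal"

    def test_mu_monotonically_excludes_hubs(self):
        """Raising the hub penalty never adds high-degree nodes (oracle)."""
        g = make_graph(
            [("h", x, 0.8) for x in ("t1", "t2", "t3", "a", "b", "c")]
            + [("t1", "t2", 0.2), ("t2", "t3", 0.2)]
        )
        prizes = {"t1": 2.0, "t2": 2.0, "t3": 2.0}
        hub_counts = []
        for mu in (0.0, 0.1, 0.3, 0.6, 1.0):
            f = brute_force_pcsf(g, prizes, PCSFParams(beta=1, mu=mu, omega=1))
            hub_counts.append(sum(1 for v in f.nodes if g.degree(v) > 3))
        assert hub_counts == sorted(hub_counts, reverse=True)


class TestGridReconstruct:
    def test_single_point_grid_is_that_solution(self):
        g, prizes = path_instance()
        ts = TerminalSet({"t1": (5.0, "tf"), "t2": (5.0, "phospho")})
        params = PCSFParams(beta=1, omega=3)
        net = grid_reconstruct(g, ts, [params], condition="c")
        f = solve_pcsf(g, ts, params)
        assert net.node_set == f.nodes
        assert net.provenance == [params]

    def test_selection_prefers_more_terminals(self):
        # omega=3 connects both terminals through s; omega=0.9... use beta
        g, _ = path_instance()
        ts = TerminalSet({"t1": (5.0, "tf"), "t2": (0.8, "phospho")})
        grid = [PCSFParams(beta=0.5, omega=1), PCSFParams(beta=5, omega=1)]
        net = grid_reconstruct(g, ts, grid, condition="c")
        # beta=0.5 gives t2 prize 0.4 < omega: dropped; beta=5 keeps both
        assert {"t1", "t2"} <= net.node_set
        assert net.provenance == [grid[1]]

    def test_tied_solutions_are_merged(self):
        g = unit_cost_graph([("t1", "s1", 0.5), ("s1", "t2", 0.5)])
        g.add_edge("t1", "s2", weight=0.5, origin="reference")
        g.add_edge("s2", "t2", weight=0.5, origin="reference")
        ts = TerminalSet({"t1": (9.0, "tf"), "t2": (9.0, "tf")})
        grid = [PCSFParams(beta=1, omega=1), PCSFParams(beta=2, omega=1)]
        net = grid_reconstruct(g, ts, grid, condition="c")
        assert {"t1", "t2"} <= net.node_set

    def test_roles_annotated(self, default_cohort, pipeline_result):
        net = next(iter(pipeline_result.networks.values()))
        roles = set(net.nodes.values())
        assert roles <= {"terminal_tf", "terminal_phospho", "drug_target", "steiner"}
        ts = pipeline_result.terminals[net.condition]
        for v, role in net.nodes.items():
            if role == "steiner":
                assert v not in ts.entries
            else:
                assert v in ts.entries

    def test_empty_grid_rejected(self):
        g, prizes = path_instance()
        ts = TerminalSet({"t1": (5.0, "tf")})
        with pytest.raises(ValueError):
            grid_reconstruct(g, ts, [])


def test_default_grid_shape():
    grid = default_grid()
    assert len(grid) == 27
    assert all(p.depth == 10 for p in grid)
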