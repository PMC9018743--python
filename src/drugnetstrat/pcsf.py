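"""Prize-collecting Steiner forest (PCSF) solver for omics network inference.

Given a confidence-weighted interactome and a prized terminal set, the PCSF
problem asks for a subforest F minimizing

    f'(F) = sum of forfeited positive adjusted prizes (terminals left out)
          + sum of penalties |p'(v)| for included nodes with negative prize
          + sum of edge costs c(e) = 1 - weight(e) over included edges
          + omega * kappa            (kappa = number of trees)

where the adjusted prize is ``p'(v) = beta * p(v) - mu * degree(v)``:
``beta`` scales the pull of terminals, ``mu`` penalizes promiscuous hubs,
``omega`` prices each additional tree (conceptually the cost of an edge to a
virtual root), and ``depth`` bounds the hop distance of any node from that
root. This objective equals the classical "excluded prizes + edges + omega *
kappa" form up to an additive constant, so the two share their minimizers;
the form used here is zero for the empty forest on a prize-free instance and
makes the hub penalty explicit.

:func:`solve_pcsf` is a deterministic cheapest-path-attachment heuristic with
strong pruning; :func:`brute_force_pcsf` is an exact oracle for tiny
instances used to certify solution quality.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .terminals import InfeasibleCondition, TerminalSet

__all__ = [
    "PCSFParams",
    "Forest",
    "ReconstructedNetwork",
    "adjust_prizes",
    "pcsf_objective",
    "solve_pcsf",
    "brute_force_pcsf",
    "grid_reconstruct",
    "default_grid",
]


@dataclass(frozen=True)
class PCSFParams:
    """Solver parameters: terminal scale β, hub penalty μ, tree cost ω, depth D."""

    beta: float = 1.0
    mu: float = 0.0
    omega: float = 1.0
    depth: int = 10

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.mu >= 0 and self.omega > 0 and self.depth >= 1):
            raise ValueError("require beta>0, mu>=0, omega>0, depth>=1")


@dataclass
class Forest:
    """A subforest of the interactome: disjoint trees, each holding >=1 terminal."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    objective: float = 0.0

    def __post_init__(self) -> None:
        self.edges = {tuple(sorted(e)) for e in self.edges}
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError("forest edge outside forest nodes")
        if len(self.edges) > 0 and len(self.edges) > len(self.nodes) - self.kappa:
            raise ValueError("forest contains a cycle")

    @property
    def kappa(self) -> int:
        return nx.number_connected_components(self.graph())

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def _prize_map(terminals: TerminalSet | Mapping[str, float]) -> dict[str, float]:
    if isinstance(terminals, TerminalSet):
        return terminals.prizes()
    return dict(terminals)


def adjust_prizes(
    terminals: TerminalSet | Mapping[str, float],
    g: nx.Graph,
    params: PCSFParams,
) -> dict[str, float]:
    """Adjusted prize p'(v) = beta*p(v) - mu*degree(v) for every node of g.

    Non-terminals have p(v) = 0 and so receive the pure hub penalty
    ``-mu * degree(v)``. Terminals absent from the interactome are dropped
    with a warning (they cannot be connected).
    """
    prizes = _prize_map(terminals)
    missing = sorted(set(prizes) - set(g.nodes()))
    if missing:
        warnings.warn(f"{len(missing)} terminal(s) absent from interactome: {missing[:5]}")
    return {
        v: params.beta * prizes.get(v, 0.0) - params.mu * g.degree(v)
        for v in g.nodes()
    }


def pcsf_objective(
    forest: Forest,
    g: nx.Graph,
    terminals: TerminalSet | Mapping[str, float],
    params: PCSFParams,
) -> float:
    """Evaluate f'(F) for a candidate forest on interactome g."""
    adj = adjust_prizes(terminals, g, params)
    for u, v in forest.edges:
        if not g.has_edge(u, v):
            raise ValueError(f"forest edge {u}-{v} not in interactome")
    forfeited = sum(p for v, p in adj.items() if p > 0 and v not in forest.nodes)
    penalties = sum(-adj[v] for v in forest.nodes if adj[v] < 0)
    edge_costs = sum(1.0 - g.edges[u, v]["weight"] for u, v in forest.edges)
    return forfeited + penalties + edge_costs + params.omega * forest.kappa


def _empty_objective(adj: Mapping[str, float], omega: float) -> float:
    return sum(p for p in adj.values() if p > 0)


def solve_pcsf(
    g: nx.Graph,
    terminals: TerminalSet | Mapping[str, float],
    params: PCSFParams,
) -> Forest:
    """Deterministic PCSF heuristic: rooted cheapest-path growth + strong pruning.

    A virtual root offers every positive-prize terminal an attachment edge of
    cost ω (starting a new tree). Terminals are visited in descending
    adjusted-prize order (ties by id); each is connected either to the root or
    to the growing forest by the cheapest path (edge costs plus penalties of
    newly included negative-prize nodes), provided the connection cost does
    not exceed the terminal's prize and the depth bound D from the root is
    respected. Strong pruning then removes every subtree whose prize mass is
    below its connection cost, and whole trees not worth their ω. The result
    never scores worse than the empty forest.
    """
    adj = adjust_prizes(terminals, g, params)
    order = sorted(
        (v for v, p in adj.items() if p > 0), key=lambda v: (-adj[v], v)
    )
    if not order:
        raise InfeasibleCondition("no terminal with positive adjusted prize")

    in_tree: set[str] = set()
    tree_edges: set[tuple[str, str]] = set()
    depth: dict[str, int] = {}
    parent: dict[str, str | None] = {}  # None marks a tree root (root child)

    for t in order:
        if t in in_tree:
            continue
        # cheapest path from the current forest to t, depth-bounded
        dist: dict[str, float] = {}
        hops: dict[str, int] = {}
        prev: dict[str, str] = {}
        heap: list[tuple[float, str]] = []
        for u in in_tree:
            dist[u] = 0.0
            hops[u] = depth[u]
            heapq.heappush(heap, (0.0, u))
        while heap:
            d, x = heapq.heappop(heap)
            if d > dist.get(x, float("inf")):
                continue
            if x == t:
                break
            if hops[x] + 1 > params.depth:
                continue
            for y in g.neighbors(x):
                if y in in_tree:
                    continue
                step = 1.0 - g.edges[x, y]["weight"]
                if y != t and adj[y] < 0:
                    step += -adj[y]
                nd = d + step
                if nd < dist.get(y, float("inf")) - 1e-12:
                    dist[y] = nd
                    hops[y] = hops[x] + 1
                    prev[y] = x
                    heapq.heappush(heap, (nd, y))
        attach_cost = dist.get(t, float("inf"))
        if params.omega <= attach_cost:
            # cheaper (or equal) to open a new tree at the root
            if params.omega <= adj[t]:
                in_tree.add(t)
                depth[t] = 1
                parent[t] = None
            continue
        if attach_cost <= adj[t]:
            path = [t]
            while path[-1] not in in_tree:
                path.append(prev[path[-1]])
            path.reverse()  # tree node ... t
            for a, b in zip(path, path[1:]):
                if b not in in_tree:
                    in_tree.add(b)
                    depth[b] = depth[a] + 1
                    parent[b] = a
                tree_edges.add(tuple(sorted((a, b))))

    forest = _strong_prune(g, in_tree, parent, adj, params.omega)
    forest.objective = pcsf_objective(forest, g, terminals, params)
    empty = Forest(objective=_empty_objective(adj, params.omega))
    if empty.objective < forest.objective:
        return empty
    return forest


def _strong_prune(
    g: nx.Graph,
    nodes: set[str],
    parent: Mapping[str, str | None],
    adj: Mapping[str, float],
    omega: float,
) -> Forest:
    """Optimal pruning of each rooted tree: drop subtrees worth less than
    their connecting edge cost, then whole trees worth less than ω."""
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for v in nodes:
        p = parent.get(v)
        if p is not None:
            children[p].append(v)
    roots = sorted(v for v in nodes if parent.get(v) is None)

    worth: dict[str, float] = {}
    keep_child: dict[tuple[str, str], bool] = {}

    def eval_subtree(v: str) -> float:  # post-order via explicit stack
        stack = [(v, False)]
        while stack:
            x, done = stack.pop()
            if not done:
                stack.append((x, True))
                for c in children[x]:
                    stack.append((c, False))
            else:
                w = adj[x]
                for c in children[x]:
                    gain = worth[c] - (1.0 - g.edges[x, c]["weight"])
                    kept = gain >= 0
                    keep_child[(x, c)] = kept
                    if kept:
                        w += gain
                worth[x] = w
        return worth[v]

    kept_nodes: set[str] = set()
    kept_edges: set[tuple[str, str]] = set()
    for r in roots:
        if eval_subtree(r) >= omega:
            stack = [r]
            kept_nodes.add(r)
            while stack:
                x = stack.pop()
                for c in children[x]:
                    if keep_child[(x, c)]:
                        kept_nodes.add(c)
                        kept_edges.add(tuple(sorted((x, c))))
                        stack.append(c)
    return Forest(nodes=kept_nodes, edges=kept_edges)


_ORACLE_MAX_NODES = 12


def brute_force_pcsf(
    g: nx.Graph,
    terminals: TerminalSet | Mapping[str, float],
    params: PCSFParams,
) -> Forest:
    """Exact PCSF oracle by exhaustive enumeration (instances of <=12 nodes).

    For every node subset, the cheapest covering forest is derived from
    per-component minimum spanning trees: splitting a component's MST into k
    trees optimally removes its k-1 heaviest edges, so only the split count
    needs searching. Ties between optimal forests break toward fewer edges,
    then the lexicographically smallest node set.
    """
    if g.number_of_nodes() > _ORACLE_MAX_NODES:
        raise ValueError(
            f"oracle refuses instances with more than {_ORACLE_MAX_NODES} nodes"
        )
    adj = adjust_prizes(terminals, g, params)
    all_nodes = sorted(g.nodes())
    total_pos = _empty_objective(adj, params.omega)

    best: tuple[float, int, tuple[str, ...]] | None = None
    best_forest = Forest(objective=total_pos)

    for r in range(len(all_nodes) + 1):
        for subset in itertools.combinations(all_nodes, r):
            s = set(subset)
            node_term = (
                total_pos
                - sum(adj[v] for v in s if adj[v] > 0)
                + sum(-adj[v] for v in s if adj[v] < 0)
            )
            edges: set[tuple[str, str]] = set()
            edge_cost_sum = 0.0
            kappa = 0
            sub = g.subgraph(s)
            for comp in nx.connected_components(sub):
                costs = sorted(
                    ((1.0 - sub.edges[u, v]["weight"], tuple(sorted((u, v))))
                     for u, v in _mst_edges(sub.subgraph(comp))),
                    reverse=True,
                )
                mst_total = sum(c for c, _ in costs)
                best_k, best_k_cost = 1, mst_total + params.omega
                for k in range(2, len(costs) + 2):
                    cost_k = (
                        mst_total
                        - sum(c for c, _ in costs[: k - 1])
                        + params.omega * k
                    )
                    if cost_k < best_k_cost - 1e-12:
                        best_k, best_k_cost = k, cost_k
                kept = [e for _, e in costs[best_k - 1 :]]
                edges.update(kept)
                edge_cost_sum += sum(c for c, _ in costs[best_k - 1 :])
                kappa += best_k
            obj = node_term + edge_cost_sum + params.omega * kappa if s else total_pos
            key = (obj, len(edges), subset)
            if best is None or _better(key, best):
                best = key
                best_forest = Forest(nodes=s, edges=edges, objective=obj)
    return best_forest


def _mst_edges(sub: nx.Graph) -> list[tuple[str, str]]:
    h = nx.Graph()
    h.add_nodes_from(sub.nodes())
    for u, v, data in sub.edges(data=True):
        h.add_edge(u, v, cost=1.0 - data["weight"])
    return list(nx.minimum_spanning_edges(h, weight="cost", data=False))


def _better(a: tuple[float, int, tuple], b: tuple[float, int, tuple]) -> bool:
    if a[0] < b[0] - 1e-12:
        return True
    if a[0] > b[0] + 1e-12:
        return False
    return (a[1], a[2]) < (b[1], b[2])


@dataclass
class ReconstructedNetwork:
    """Merged PCSF output for one condition, with node roles and provenance."""

    condition: str
    nodes: dict[str, str]  # protein -> role in {terminal_tf, terminal_phospho, drug_target, steiner}
    edges: list[tuple[str, str, float, str]]  # (u, v, weight, origin)
    provenance: list[PCSFParams] = field(default_factory=list)

    @property
    def node_set(self) -> set[str]:
        return set(self.nodes)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for v, role in self.nodes.items():
            g.add_node(v, role=role)
        for u, v, w, origin in self.edges:
            g.add_edge(u, v, weight=w, origin=origin)
        return g


_ROLE_OF_SOURCE = {
    "tf": "terminal_tf",
    "phospho": "terminal_phospho",
    "drug_target": "drug_target",
}


def grid_reconstruct(
    g: nx.Graph,
    terminals: TerminalSet,
    grid: Sequence[PCSFParams],
    hub_degree: int = 100,
    condition: str | None = None,
) -> ReconstructedNetwork:
    """Run the parameter grid, select the best solutions, merge them.

    Each grid point is solved independently. Solutions are ranked
    lexicographically by (number of terminals included, minus the count of
    included interactome hubs with degree > ``hub_degree``); every solution
    tied at the maximum is merged by node/edge union into the final
    condition network.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    terminal_ids = set(terminals.prizes())
    scored: list[tuple[tuple[int, int], PCSFParams, Forest]] = []
    for params in grid:
        try:
            forest = solve_pcsf(g, terminals, params)
        except InfeasibleCondition:
            continue
        n_term = len(forest.nodes & terminal_ids)
        n_hub = sum(1 for v in forest.nodes if g.degree(v) > hub_degree)
        scored.append(((n_term, -n_hub), params, forest))
    if not scored:
        raise InfeasibleCondition("all grid points infeasible")
    top = max(s for s, _, _ in scored)
    merged_nodes: set[str] = set()
    merged_edges: set[tuple[str, str]] = set()
    provenance = []
    for s, params, forest in scored:
        if s == top:
            merged_nodes |= forest.nodes
            merged_edges |= forest.edges
            provenance.append(params)
    sources = terminals.sources()
    roles = {
        v: _ROLE_OF_SOURCE.get(sources.get(v, ""), "steiner")
        for v in sorted(merged_nodes)
    }
    edges = [
        (u, v, float(g.edges[u, v]["weight"]), g.edges[u, v].get("origin", "reference"))
        for u, v in sorted(merged_edges)
    ]
    return ReconstructedNetwork(
        condition=condition or terminals.condition,
        nodes=roles,
        edges=edges,
        provenance=provenance,
    )


def default_grid(
    depth: int = 10,
    mus: Iterable[float] = (0.0, 0.01, 0.1),
    betas: Iterable[float] = (2.0, 5.0, 10.0),
    omegas: Iterable[float] = (1.0, 2.0, 3.0),
) -> list[PCSFParams]:
    """Reduced desk-scale parameter grid (full-resolution μ grid by config)."""
    return [
        PCSFParams(beta=b, mu=m, omega=w, depth=depth)
        for m in mus
        for b in betas
        for w in omegas
    ]
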