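"""Topology-based comparison of reconstructed drug networks.

The central quantity is the network-medicine separation score

    s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2

where distances are unweighted shortest-path hop counts on the reference
interactome: <d_AB> averages, over every protein of A and of B, the distance
to the nearest protein of the *other* set (0 for shared proteins), while
<d_AA> averages each protein's distance to its nearest same-set neighbor.
Negative s_AB means the two networks interleave in the interactome
(topological overlap); positive s_AB means they occupy separated
neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "SeparationScore",
    "SeparationMatrix",
    "OverlapTest",
    "TopologySummary",
    "DistanceCache",
    "separation_score",
    "separation_matrix",
    "overlap_significance",
    "topology_summary",
    "cluster_matrix",
    "ClusterResult",
]


class DistanceCache:
    """Memoized BFS shortest-path lengths on one reference graph.

    Results are independent of caching; this only avoids repeating BFS runs
    when scoring many network pairs against the same interactome.
    """

    def __init__(self, g: nx.Graph):
        self.g = g
        self._dists: dict[str, dict[str, int]] = {}

    def from_node(self, v: str) -> dict[str, int]:
        if v not in self._dists:
            self._dists[v] = dict(nx.single_source_shortest_path_length(self.g, v))
        return self._dists[v]


@dataclass(frozen=True)
class SeparationScore:
    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float
    n_common: int


def _nearest_other(
    src: set[str], dst: set[str], cache: DistanceCache
) -> list[float]:
    """Distance from each node of src to its nearest node of dst (0 if shared)."""
    out: list[float] = []
    dropped = 0
    for a in sorted(src):
        if a in dst:
            out.append(0.0)
            continue
        if a not in cache.g:
            dropped += 1
            continue
        d = cache.from_node(a)
        reach = [d[b] for b in dst if b in d]
        if reach:
            out.append(float(min(reach)))
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} node(s) unreachable from the other set; dropped from mean")
    return out


def _within(nodes: set[str], cache: DistanceCache) -> float:
    if len(nodes) <= 1:
        return 0.0
    vals: list[float] = []
    dropped = 0
    for a in sorted(nodes):
        if a not in cache.g:
            dropped += 1
            continue
        d = cache.from_node(a)
        reach = [d[b] for b in nodes if b != a and b in d]
        if reach:
            vals.append(float(min(reach)))
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} node(s) unreachable within their own set; dropped")
    if not vals:
        raise ValueError("no within-set distances could be computed")
    return float(np.mean(vals))


def separation_score(
    set_a: Iterable[str],
    set_b: Iterable[str],
    ref: nx.Graph | DistanceCache,
) -> SeparationScore:
    """Menche-style topological separation of two protein sets on ``ref``."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both protein sets must be nonempty")
    cache = ref if isinstance(ref, DistanceCache) else DistanceCache(ref)
    cross = _nearest_other(a, b, cache) + _nearest_other(b, a, cache)
    if not cross:
        raise ValueError("no cross-set distances could be computed")
    d_ab = float(np.mean(cross))
    d_aa = _within(a, cache)
    d_bb = _within(b, cache)
    return SeparationScore(
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        d_ab=d_ab,
        d_aa=d_aa,
        d_bb=d_bb,
        n_common=len(a & b),
    )


@dataclass
class SeparationMatrix:
    """Symmetric all-pairs separation scores with condition metadata.

    ``meta`` is indexed by condition id with columns ``cell_line``, ``drug``
    and optionally ``moa``; ``classes`` annotates each pair as T1 (same cell
    line, same MoA), T2 (same cell line, different MoA), T3 (different cell
    line, same MoA) or T4 (different everything).
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must be square with matching labels")

    @property
    def conditions(self) -> list[str]:
        return list(self.scores.index)

    @property
    def classes(self) -> pd.DataFrame:
        cl = self.meta["cell_line"]
        moa = self.meta.get("moa")
        labels = self.conditions
        out = pd.DataFrame("", index=labels, columns=labels)
        for i, ci in enumerate(labels):
            for cj in labels[i + 1 :]:
                same_cl = cl[ci] == cl[cj]
                same_moa = moa is not None and moa[ci] == moa[cj]
                t = {(True, True): "T1", (True, False): "T2",
                     (False, True): "T3", (False, False): "T4"}[(same_cl, same_moa)]
                out.loc[ci, cj] = t
                out.loc[cj, ci] = t
        return out

    def pairs(self) -> pd.DataFrame:
        """Long-form table of unordered pairs with scores and class labels."""
        rows = []
        labels = self.conditions
        classes = self.classes
        for i, ci in enumerate(labels):
            for cj in labels[i + 1 :]:
                rows.append(
                    {
                        "a": ci,
                        "b": cj,
                        "s_ab": self.scores.loc[ci, cj],
                        "class": classes.loc[ci, cj],
                    }
                )
        return pd.DataFrame(rows)


def separation_matrix(
    networks: Mapping[str, Iterable[str]],
    ref: nx.Graph,
    meta: pd.DataFrame,
) -> SeparationMatrix:
    """Score all unordered pairs of condition networks.

    ``networks`` maps condition id -> protein set; ``meta`` is indexed by the
    same ids. Pair failures (e.g. mutually unreachable sets) are recorded as
    missing entries rather than aborting the matrix.
    """
    ids = sorted(networks)
    if len(ids) < 2:
        raise ValueError("need >=2 networks")
    cache = DistanceCache(ref)
    m = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        sa = set(networks[a])
        try:
            m.loc[a, a] = -_within(sa, cache)  # s_AA = 0 - (d_AA + d_AA)/2
        except ValueError:
            pass
        for b in ids[i + 1 :]:
            try:
                s = separation_score(sa, set(networks[b]), cache)
                m.loc[a, b] = m.loc[b, a] = s.s_ab
            except ValueError as exc:
                warnings.warn(f"pair ({a}, {b}) not scored: {exc}")
    return SeparationMatrix(scores=m, meta=meta.loc[ids])


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric significance of the node overlap of two networks."""

    x: int  # common nodes
    M: int  # larger network size
    n: int  # smaller network size
    N: int  # interactome size
    p_value: float


def overlap_significance(
    nodes_a: Iterable[str], nodes_b: Iterable[str], ref: nx.Graph
) -> OverlapTest:
    """Upper-tail P(X >= x) for the observed node overlap."""
    a, b = set(nodes_a), set(nodes_b)
    if not (a <= set(ref.nodes()) and b <= set(ref.nodes())):
        raise ValueError("network nodes must lie in the reference interactome")
    x = len(a & b)
    big, small = (a, b) if len(a) >= len(b) else (b, a)
    M, n, N = len(big), len(small), ref.number_of_nodes()
    if x > n:
        raise ValueError("overlap exceeds the smaller network")
    p = float(stats.hypergeom.sf(x - 1, N, M, n))
    return OverlapTest(x=x, M=M, n=n, N=N, p_value=p)


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_shortest_path: float
    density: float
    diameter: int
    connected: bool


def topology_summary(net) -> TopologySummary:
    """Standard topology descriptors of a reconstructed network.

    Path-based metrics (average shortest path, diameter) fall back to the
    largest connected component for disconnected networks, flagged via
    ``connected=False``.
    """
    g = net if isinstance(net, nx.Graph) else net.graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    connected = nx.is_connected(g)
    core = g if connected else g.subgraph(max(nx.connected_components(g), key=len))
    if core.number_of_nodes() > 1:
        aspl = float(nx.average_shortest_path_length(core))
        diam = int(nx.diameter(core))
    else:
        aspl, diam = 0.0, 0
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        avg_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        avg_shortest_path=aspl,
        density=float(nx.density(g)),
        diameter=diam,
        connected=connected,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]  # input order (sorted)
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick-like string."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = render(node.left), render(node.right)
            return f"({left},{right}):{node.dist:.6g}"

        return render(tree) + ";"


def cluster_matrix(m: SeparationMatrix | pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering of score-matrix rows.

    Rows are compared by Euclidean distance. Labels are sorted before
    clustering so that tied merges resolve deterministically; missing
    entries are imputed with the matrix maximum (with a warning).
    """
    scores = m.scores if isinstance(m, SeparationMatrix) else m
    if len(scores) < 2:
        raise ValueError("need >=2 items to cluster")
    scores = scores.sort_index(axis=0).sort_index(axis=1)
    values = scores.to_numpy(dtype=float)
    if np.isnan(values).any():
        warnings.warn("missing separation entries imputed with matrix maximum")
        values = np.where(np.isnan(values), np.nanmax(values), values)
    z = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    labels = list(scores.index)
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(linkage=z, labels=labels, leaf_order=order)
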