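"""Condition-specific interactome refinement and link-prediction augmentation.

The reference interactome is a :class:`networkx.Graph` whose edges carry

``weight``
    interaction confidence in ``(0, 1]`` (predicted edges may go down to 0),
``origin``
    ``"reference"`` for curated interactions, ``"predicted"`` for edges added
    by Adamic/Adar link prediction.

The solver cost of an edge is ``c(e) = 1 - weight``, so high-confidence
interactions are cheap to include and link-predicted edges (scaled into
``[0, 0.5]``) are always expensive (cost in ``[0.5, 1]``).

The refinement pipeline runs in a fixed order:

1. :func:`remove_hubs` — strip promiscuous hub proteins,
2. :func:`expression_filter` — drop edges touching unexpressed proteins,
3. :func:`adamic_adar_scores` — score candidate missing interactions,
4. :func:`localization_filter` — keep only co-localizable predictions,
5. :func:`augment_interactome` — append surviving predictions.

:func:`prepare_condition_interactome` wires the five steps together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "PredictedEdge",
    "edge_cost",
    "remove_hubs",
    "expression_filter",
    "adamic_adar_scores",
    "localization_filter",
    "augment_interactome",
    "prepare_condition_interactome",
]

REFERENCE = "reference"
PREDICTED = "predicted"


@dataclass(frozen=True)
class PredictedEdge:
    """A candidate protein interaction proposed by link prediction.

    ``pair`` is stored sorted so that an unordered pair has one canonical
    form; ``scaled_weight`` is filled in by :func:`augment_interactome`.
    """

    pair: tuple[str, str]
    aa_score: float
    scaled_weight: float | None = None

    def __post_init__(self) -> None:
        if self.pair[0] > self.pair[1]:
            object.__setattr__(self, "pair", (self.pair[1], self.pair[0]))
        if self.aa_score < 0:
            raise ValueError("Adamic/Adar scores are non-negative")


def edge_cost(g: nx.Graph, u: str, v: str) -> float:
    """Solver cost of an edge: one minus its confidence weight."""
    return 1.0 - g.edges[u, v]["weight"]


def remove_hubs(
    g: nx.Graph, deg_thresh: int = 900, sd_mult: float = 10.0
) -> tuple[nx.Graph, list[str]]:
    """Remove edges incident to promiscuous hub proteins.

    A node is a hub when its degree exceeds ``deg_thresh`` AND lies more than
    ``sd_mult`` standard deviations above the mean degree (both clauses must
    hold; mean/SD are taken over all node degrees of ``g``). All edges
    touching a hub are dropped; the hub nodes themselves remain as isolates.
    Self-loops are removed unconditionally.

    Returns the filtered copy and the list of hub nodes removed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    out = g.copy()
    out.remove_edges_from(list(nx.selfloop_edges(out)))
    degrees = np.array([d for _, d in out.degree()], dtype=float)
    cutoff = degrees.mean() + sd_mult * degrees.std()
    hubs = sorted(
        n for n, d in out.degree() if d > deg_thresh and d > cutoff
    )
    for h in hubs:
        out.remove_edges_from(list(out.edges(h)))
    return out, hubs


def expression_filter(
    g: nx.Graph, expr: Mapping[str, float], thresh: float = 2.0
) -> nx.Graph:
    """Drop edges with an endpoint whose expression is below ``thresh``.

    Proteins absent from ``expr`` are treated as unmeasured and their edges
    are kept: absence of evidence is not evidence of silence.
    """
    out = g.copy()
    low = {p for p, v in expr.items() if v < thresh}
    out.remove_edges_from(
        [(u, v) for u, v in out.edges() if u in low or v in low]
    )
    return out


def adamic_adar_scores(g: nx.Graph, top_k: int | None = None) -> list[PredictedEdge]:
    """Score non-adjacent protein pairs by the Adamic/Adar index.

    ``Score(x, y) = sum over common neighbors w of 1 / ln(degree(w))``.

    Only pairs with at least one common neighbor can score above zero, so the
    scan walks each node's neighborhood instead of all ``O(n^2)`` pairs. A
    shared neighbor necessarily has degree >= 2, hence ``ln(degree) >= ln 2``
    and no division by zero can occur.

    Returns the ``top_k`` best-scoring pairs (default: as many as the graph
    has edges), sorted by descending score with lexicographic pair
    tie-breaking.
    """
    if top_k is None:
        top_k = g.number_of_edges()
    scores: dict[tuple[str, str], float] = {}
    for w in g.nodes():
        nbrs = sorted(g.neighbors(w))
        if len(nbrs) < 2:
            continue
        contrib = 1.0 / math.log(len(nbrs))
        for i, x in enumerate(nbrs):
            for y in nbrs[i + 1 :]:
                if not g.has_edge(x, y):
                    scores[(x, y)] = scores.get((x, y), 0.0) + contrib
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [PredictedEdge(pair, s) for pair, s in ranked[:top_k]]


def localization_filter(
    preds: Iterable[PredictedEdge],
    loc: Mapping[str, set[str]],
) -> list[PredictedEdge]:
    """Keep predictions whose proteins could share a subcellular compartment.

    A prediction survives when the two proteins share at least one annotated
    location, or when at least one of them has no localization record at all
    (its compartment is unknown, so co-localization cannot be excluded).
    """
    kept = []
    for p in preds:
        a, b = p.pair
        loc_a, loc_b = loc.get(a), loc.get(b)
        if not loc_a or not loc_b or (set(loc_a) & set(loc_b)):
            kept.append(p)
    return kept


def augment_interactome(g: nx.Graph, preds: Iterable[PredictedEdge]) -> nx.Graph:
    """Append link-predicted edges with scores min–max scaled onto [0, 0.5].

    The cap at 0.5 keeps every predicted edge less trustworthy than any
    curated interaction of middling confidence. Degenerate scaling (a single
    prediction, or all scores equal) maps everything to 0.5. Predictions that
    duplicate an existing edge or would introduce a new node are skipped with
    a warning.
    """
    preds = list(preds)
    out = g.copy()
    if not preds:
        return out
    raw = np.array([p.aa_score for p in preds], dtype=float)
    span = raw.max() - raw.min()
    if span == 0:
        scaled = np.full_like(raw, 0.5)
    else:
        scaled = 0.5 * (raw - raw.min()) / span
    for p, w in zip(preds, scaled):
        a, b = p.pair
        if out.has_edge(a, b):
            warnings.warn(f"predicted edge {a}-{b} duplicates an existing edge; skipped")
            continue
        if a not in out or b not in out:
            warnings.warn(f"predicted edge {a}-{b} references unknown protein; skipped")
            continue
        out.add_edge(a, b, weight=float(w), origin=PREDICTED)
    return out


def prepare_condition_interactome(
    g: nx.Graph,
    expr: Mapping[str, float],
    loc: Mapping[str, set[str]],
    *,
    deg_thresh: int = 900,
    sd_mult: float = 10.0,
    expr_thresh: float = 2.0,
    top_k: int | None = None,
) -> nx.Graph:
    """Full refinement pipeline for one (cell line, drug) condition."""
    filtered, _ = remove_hubs(g, deg_thresh=deg_thresh, sd_mult=sd_mult)
    filtered = expression_filter(filtered, expr, thresh=expr_thresh)
    preds = adamic_adar_scores(filtered, top_k=top_k)
    preds = localization_filter(preds, loc)
    return augment_interactome(filtered, preds)
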