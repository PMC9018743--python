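"""Hypergeometric pathway enrichment of network node sets.

A network's proteins are tested against each gene set of a collection with a
one-sided (upper-tail) hypergeometric test on the overlap, given a background
universe (by default the interactome node set). Pathways with raw p < 0.05
count as enriched; for network-to-network comparison only pathways whose
names mark them as signaling pathways are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "enrich",
    "shared_pathways",
    "default_signaling_filter",
]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets over a background universe.

    Members outside the universe are dropped on construction; sets emptied
    by the restriction are removed with a warning.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            inside = set(members) & self.universe
            if inside:
                restricted[name] = inside
            else:
                warnings.warn(f"gene set {name!r} has no members in the universe; dropped")
        self.sets = restricted


@dataclass(frozen=True)
class EnrichmentRecord:
    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    significant: bool


def enrich(
    query: Iterable[str],
    gsc: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of ``query`` in every gene set.

    Out-of-universe query members are dropped (counted in a warning).
    Records are sorted by ascending p-value, ties by name.
    """
    q = set(query)
    inside = q & gsc.universe
    if len(inside) < len(q):
        warnings.warn(f"{len(q) - len(inside)} query protein(s) outside the universe; dropped")
    if not inside:
        warnings.warn("empty query after universe restriction")
        return []
    N, n = len(gsc.universe), len(inside)
    records = []
    for name in sorted(gsc.sets):
        members = gsc.sets[name]
        x = len(members & inside)
        p = float(stats.hypergeom.sf(x - 1, N, len(members), n))
        records.append(
            EnrichmentRecord(
                name=name,
                overlap=x,
                set_size=len(members),
                query_size=n,
                universe_size=N,
                p_value=p,
                significant=p < alpha,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.name))
    return records


def default_signaling_filter(name: str) -> bool:
    return "signaling" in name.lower()


def shared_pathways(
    records_a: Iterable[EnrichmentRecord],
    records_b: Iterable[EnrichmentRecord],
    signaling_filter: Callable[[str], bool] = default_signaling_filter,
) -> list[str]:
    """Signaling pathways significantly enriched in both networks."""
    sig_a = {r.name for r in records_a if r.significant and signaling_filter(r.name)}
    sig_b = {r.name for r in records_b if r.significant and signaling_filter(r.name)}
    return sorted(sig_a & sig_b)
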