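"""Directed TSS similarity networks and their component structure.

The network for a TSS=k dataset has an edge u -> v whenever v is among u's
top-k qualifying subjects.  Strong components (mutual reachability on the
directed graph) are the conservative paralog-cluster proxy; weak components
(connectivity of the undirected shadow) additionally absorb epaktologs
attached through one-directional best-hit edges.  Profiling component
counts and the largest-connected-component size across k shows where a
query crosses from its paralog cluster into the network's giant component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .similarity import DEFAULT_CUTOFF, TSSDataset, build_tss_dataset

STRONG = "STRONG"
WEAK = "WEAK"


@dataclass(frozen=True)
class ComponentPartition:
    """Disjoint, exhaustive decomposition of the network vertices."""

    mode: str
    k: int
    components: tuple[frozenset[str], ...]

    @property
    def n_vertices(self) -> int:
        return sum(len(c) for c in self.components)

    @property
    def n_components_ge2(self) -> int:
        return sum(1 for c in self.components if len(c) >= 2)

    @property
    def lcc_size(self) -> int:
        return max((len(c) for c in self.components), default=0)

    def component_of(self, vertex: str) -> frozenset[str]:
        for comp in self.components:
            if vertex in comp:
                return comp
        raise KeyError(vertex)

    def refines(self, coarser: "ComponentPartition") -> bool:
        """True if every component here is inside one component of ``coarser``."""
        location = {}
        for idx, comp in enumerate(coarser.components):
            for v in comp:
                location[v] = idx
        for comp in self.components:
            targets = {location.get(v) for v in comp}
            if len(targets) != 1 or None in targets:
                return False
        return True


def build_graph(tss: TSSDataset) -> nx.DiGraph:
    """Directed graph of a TSS dataset: u -> v iff v is in u's top-k list."""
    graph = nx.DiGraph()
    graph.add_nodes_from(tss.vertices())
    for query, subjects in tss.lists.items():
        for subject in subjects:
            if subject != query:
                graph.add_edge(query, subject)
    return graph


def _sorted_components(raw, mode: str, k: int) -> ComponentPartition:
    comps = sorted(
        (frozenset(c) for c in raw), key=lambda c: (-len(c), min(c))
    )
    return ComponentPartition(mode=mode, k=k, components=tuple(comps))


def strong_components(graph: nx.DiGraph, k: int = 0) -> ComponentPartition:
    """Maximal mutually reachable vertex sets of the directed network.

    A singleton component means no paralog was identified for that protein
    at this k.
    """
    return _sorted_components(nx.strongly_connected_components(graph), STRONG, k)


def weak_components(graph: nx.DiGraph, k: int = 0) -> ComponentPartition:
    """Connected components of the underlying undirected graph."""
    return _sorted_components(nx.weakly_connected_components(graph), WEAK, k)


def component_partition(graph: nx.DiGraph, mode: str, k: int = 0) -> ComponentPartition:
    if mode == STRONG:
        return strong_components(graph, k)
    if mode == WEAK:
        return weak_components(graph, k)
    raise ValueError(f"unknown component mode {mode!r}")


def component_profile(
    hits,
    k_range: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-k component statistics in both modes.

    One row per (k, mode): number of network vertices, number of components
    with at least two members (the cluster-like "families") and the size of
    the largest component.  The vertex count is constant across k.
    """
    if len(k_range) == 0:
        raise ValueError("k_range must be non-empty")
    rows = []
    for k in k_range:
        graph = build_graph(build_tss_dataset(hits, k, cutoff))
        for mode in (STRONG, WEAK):
            part = component_partition(graph, mode, k)
            rows.append(
                {
                    "k": k,
                    "mode": mode,
                    "n_vertices": part.n_vertices,
                    "n_components_ge2": part.n_components_ge2,
                    "lcc_size": part.lcc_size,
                }
            )
    return pd.DataFrame(rows)


def trace_query(
    hits,
    query_id: str,
    k_range: Sequence[int],
    mode: str = STRONG,
    cutoff: float = DEFAULT_CUTOFF,
    giant_fraction: float = 0.2,
) -> pd.DataFrame:
    """Membership of one query's component for each k.

    Flags the k at which the component exceeds ``giant_fraction`` of the
    vertices -- the point where the query is absorbed into the network's
    largest connected component.
    """
    rows = []
    seen = False
    for k in k_range:
        tss = build_tss_dataset(hits, k, cutoff)
        graph = build_graph(tss)
        if query_id not in graph:
            raise KeyError(
                f"query {query_id!r} has no qualifying hit at cutoff {cutoff}"
            )
        seen = True
        part = component_partition(graph, mode, k)
        comp = part.component_of(query_id)
        absorbed = len(comp) >= giant_fraction * part.n_vertices
        rows.append(
            {
                "k": k,
                "mode": mode,
                "component_size": len(comp),
                "members": ",".join(sorted(comp)),
                "absorbed_in_lcc": bool(absorbed),
            }
        )
    if not seen:
        raise ValueError("k_range must be non-empty")
    return pd.DataFrame(rows)


def partition_to_frame(part: ComponentPartition) -> pd.DataFrame:
    rows = [
        {"protein_id": v, "mode": part.mode, "k": part.k, "component_id": idx}
        for idx, comp in enumerate(part.components)
        for v in sorted(comp)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "mode", "k", "component_id"])
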