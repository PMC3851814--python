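"""Link-prediction similarities on the PPI network.

Three common-neighbor statistics over an undirected simple graph of
proteins: Jaccard (overlap of neighborhoods), Adamic-Adar (common
neighbors down-weighted by log degree) and Resource Allocation (down
weighted by degree).  Proteins absent from the network receive the
missing-value sentinel when features are built in bulk; direct calls on
unknown nodes raise.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import networkx as nx

from .errors import MalformedTableError, UnknownProteinError
from .missing import MISSING

logger = logging.getLogger(__name__)


class PPINetwork:
    """Undirected simple graph of proteins (no self-loops, no duplicate
    edges), thinly wrapping :class:`networkx.Graph`."""

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        self.graph = nx.Graph()
        self.graph.add_nodes_from(nodes)
        dropped_self = 0
        for u, v in edges:
            if u == v:
                dropped_self += 1
                continue
            self.graph.add_edge(u, v)
        if dropped_self:
            logger.warning("dropped %d self-interaction(s)", dropped_self)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.graph:
            raise UnknownProteinError(f"protein {protein!r} not in network")
        return set(self.graph[protein])

    def degree(self, protein: str) -> int:
        return len(self.neighbors(protein))


def load_edge_list(path) -> PPINetwork:
    """Read a two-column TSV edge list (``#`` comments allowed).

    Self-loops and duplicate edges are dropped silently (with counts
    logged); an empty file yields an empty network.
    """
    edges = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise MalformedTableError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            edges.append((fields[0], fields[1]))
    net = PPINetwork(edges)
    n_dupes = len(edges) - net.n_edges
    if n_dupes:
        logger.debug("collapsed %d duplicate/self edge entries", n_dupes)
    return net


def _common_neighbors(net: PPINetwork, i: str, j: str) -> set[str]:
    return net.neighbors(i) & net.neighbors(j)


def jaccard_sim(net: PPINetwork, i: str, j: str) -> float:
    """|N(i) ∩ N(j)| / |N(i) ∪ N(j)|; 0 when both neighborhoods are empty."""
    ni, nj = net.neighbors(i), net.neighbors(j)
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def adamic_adar_sim(
    net: PPINetwork, i: str, j: str, log_base: float = math.e
) -> float:
    """Sum over common neighbors ``n`` of ``1 / log(degree(n))``.

    Common neighbors always have degree >= 2 (they adjoin both endpoints),
    so the sum is finite for the natural-log default; ``log_base`` is
    configurable.
    """
    return sum(
        1.0 / (math.log(net.degree(n)) / math.log(log_base))
        for n in _common_neighbors(net, i, j)
    )


def resource_allocation_sim(net: PPINetwork, i: str, j: str) -> float:
    """Sum over common neighbors ``n`` of ``1 / degree(n)``."""
    return sum(1.0 / net.degree(n) for n in _common_neighbors(net, i, j))


def topology_features(
    net: PPINetwork,
    pairs: Iterable[tuple[str, str]],
    mask_edge: bool = False,
) -> list[tuple[float, float, float]]:
    """Jaccard/AA/RA rows for a pair list; proteins absent from the
    network yield MISSING in all three columns.

    ``mask_edge=True`` enables the leave-one-out variant: when the pair is
    itself an edge, the edge is removed before computing neighborhoods.
    """
    rows = []
    for i, j in pairs:
        if i not in net or j not in net:
            rows.append((MISSING, MISSING, MISSING))
            continue
        removed = False
        if mask_edge and net.graph.has_edge(i, j):
            net.graph.remove_edge(i, j)
            removed = True
        try:
            rows.append(
                (
                    jaccard_sim(net, i, j),
                    adamic_adar_sim(net, i, j),
                    resource_allocation_sim(net, i, j),
                )
            )
        finally:
            if removed:
                net.graph.add_edge(i, j)
    return rows
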