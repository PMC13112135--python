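"""Clustering by co-occurrence: the core locus-clustering algorithm.

Transcripts are nodes; for an ordered pair (i, j) sharing at least one bin,
the co-occurrence proportion is |bins(i) & bins(j)| / |bins(i)| — the
fraction of i's bins that also contain j.  An undirected edge {i, j} is
formed when either directed proportion reaches the threshold.  Connected
components of the resulting graph, after fragment and chimera removal, are
the binned locus clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .binning import BinIndex
from .model import BINNED, CHIMERA, FRAGMENT, Cluster, Clustering, LoclustError

logger = logging.getLogger(__name__)

#: Default co-occurrence proportion threshold.
DEFAULT_THRESHOLD = 0.66


def cooccurrence(index: BinIndex, i: str, j: str) -> float:
    """Proportion of i's bins that also contain j.

    Defined as 1 for i == j.  Raises for a transcript with no bins.
    """
    bins_i = index.bins_of(i)
    if not bins_i:
        raise LoclustError(f"co-occurrence undefined: {i!r} occurs in no bin")
    if i == j:
        return 1.0
    bins_j = index.bins_of(j)
    return len(bins_i & bins_j) / len(bins_i)


@dataclass
class CooccurrenceGraph:
    """Undirected edge graph plus the directed proportions behind it."""

    graph: nx.Graph
    prop: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def subgraph_without(self, removed: set[str]) -> "CooccurrenceGraph":
        kept = self.graph.subgraph(n for n in self.graph.nodes if n not in removed)
        return CooccurrenceGraph(
            graph=nx.Graph(kept), prop=self.prop, threshold=self.threshold
        )


def build_graph(index: BinIndex, threshold: float = DEFAULT_THRESHOLD) -> CooccurrenceGraph:
    """Build the co-occurrence graph over all binned transcripts.

    Only pairs sharing at least one bin are evaluated (never all pairs).
    """
    if not (0.0 < threshold <= 1.0):
        raise LoclustError(f"threshold must be in (0, 1], got {threshold}")

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(index.by_transcript)

    candidates: set[tuple[str, str]] = set()
    for b in index.bins.values():
        for i, j in itertools.combinations(sorted(b.members), 2):
            candidates.add((i, j))

    prop: dict[tuple[str, str], float] = {}
    for i, j in candidates:
        bins_i, bins_j = index.bins_of(i), index.bins_of(j)
        shared = len(bins_i & bins_j)
        p_ij = shared / len(bins_i)
        p_ji = shared / len(bins_j)
        prop[(i, j)] = p_ij
        prop[(j, i)] = p_ji
        if p_ij >= threshold or p_ji >= threshold:
            graph.add_edge(i, j)
    return CooccurrenceGraph(graph=graph, prop=prop, threshold=threshold)


def detect_fragments(cg: CooccurrenceGraph) -> frozenset[str]:
    """Probable fragments: nodes whose relationships are one-sided against
    them in >= 50% of cases.

    An edge {i, j} is one-sided against i when prop(i->j) >= t but
    prop(j->i) < t: every bin of i contains j but not vice versa, the
    signature of a truncated transcript.  Nodes with no relationships are
    never fragments.  The tie at exactly 50% removes the node.
    """
    t = cg.threshold
    fragments = set()
    for node in cg.graph.nodes:
        neighbours = list(cg.graph.neighbors(node))
        if not neighbours:
            continue
        one_sided = sum(
            1
            for other in neighbours
            if cg.prop[(node, other)] >= t and cg.prop[(other, node)] < t
        )
        if one_sided / len(neighbours) >= 0.5:
            fragments.add(node)
    return frozenset(fragments)


def detect_chimeras(cg: CooccurrenceGraph) -> frozenset[str]:
    """Probable chimeras: articulation points of each connected component.

    Computed in a single pass (simultaneous removal, no iterative
    re-detection).  Components of size <= 2 yield none.  Callers must remove
    fragments and rebuild the graph before calling.
    """
    chimeras: set[str] = set()
    for component in nx.connected_components(cg.graph):
        if len(component) <= 2:
            continue
        chimeras.update(nx.articulation_points(cg.graph.subgraph(component)))
    return frozenset(chimeras)


def extract_binned_clusters(
    cg: CooccurrenceGraph,
    fragments: frozenset[str],
    chimeras: frozenset[str],
) -> Clustering:
    """Connected components of the filter-surviving graph, as binned
    clusters; isolated survivors become singletons.

    Cluster ids are assigned deterministically by each component's smallest
    member id.
    """
    overlap = fragments & chimeras
    if overlap:
        raise LoclustError(f"transcripts flagged as both fragment and chimera: {sorted(overlap)}")
    removed = fragments | chimeras
    surviving = cg.subgraph_without(set(removed))
    components = sorted(
        (sorted(component) for component in nx.connected_components(surviving.graph)),
        key=lambda members: members[0],
    )
    clusters = tuple(
        Cluster(f"cluster-{i:06d}", frozenset(members), BINNED)
        for i, members in enumerate(components, 1)
    )
    filtered = {t: FRAGMENT for t in fragments}
    filtered.update({t: CHIMERA for t in chimeras})
    return Clustering(clusters=clusters, filtered=filtered)


def cluster_binned(
    index: BinIndex, threshold: float = DEFAULT_THRESHOLD
) -> Clustering:
    """Full binned-clustering pipeline: graph, fragment filter, chimera
    filter (on the fragment-free graph), components."""
    cg = build_graph(index, threshold)
    fragments = detect_fragments(cg)
    if fragments:
        logger.info("removed %d probable fragment(s)", len(fragments))
    pruned = cg.subgraph_without(set(fragments))
    chimeras = detect_chimeras(pruned)
    if chimeras:
        logger.info("removed %d probable chimera(s)", len(chimeras))
    return extract_binned_clusters(cg, fragments, chimeras)


def write_graph_tsv(cg: CooccurrenceGraph, path) -> None:
    """Debug dump: one row per undirected edge with both directed
    proportions."""
    from pathlib import Path

    lines = ["node_a\tnode_b\tprop_a_to_b\tprop_b_to_a"]
    for a, b in sorted(tuple(sorted(e)) for e in cg.graph.edges):
        lines.append(f"{a}\t{b}\t{cg.prop[(a, b)]:.6g}\t{cg.prop[(b, a)]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
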