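"""The transcript forest: the simulated transcript phylogeny.

A directed forest over every transcript simulated at every guide-tree
node.  Edges are labeled ``conserved`` (vertical descent on a guide
branch) or by the AS event type that derived the child isoform; roots
are transcript gains (random selections from the isoform pool).  Lost
lineages carry loss markers referencing the branch on which they died.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

EDGE_LABELS = ("conserved", "a5", "a3", "es", "me", "ir")


class TranscriptForest:
    """Thin wrapper over a :class:`networkx.DiGraph` with forest invariants."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        #: transcript id -> (branch scope, reason) for terminated lineages
        self.losses: Dict[str, Tuple[str, str]] = {}

    # -- construction -------------------------------------------------------
    def add_transcript(self, tid: str, node_label: str) -> None:
        self.graph.add_node(tid, gene=node_label)

    def add_edge(self, source: str, sink: str, event: str) -> None:
        if event not in EDGE_LABELS:
            raise ValueError(f"unknown edge label {event!r}")
        if self.graph.in_degree(sink):
            raise ValueError(f"sink {sink} already has a parent")
        self.graph.add_edge(source, sink, event=event)

    def mark_lost(self, tid: str, branch: str, reason: str) -> None:
        self.losses[tid] = (branch, reason)

    # -- queries ------------------------------------------------------------
    def __contains__(self, tid: str) -> bool:
        return tid in self.graph

    def gene_of(self, tid: str) -> str:
        try:
            return self.graph.nodes[tid]["gene"]
        except KeyError:
            raise KeyError(f"unknown transcript id {tid!r}") from None

    def roots(self) -> List[str]:
        return [n for n in self.graph if self.graph.in_degree(n) == 0]

    def children(self, tid: str) -> List[str]:
        return sorted(self.graph.successors(tid))

    def edge_event(self, source: str, sink: str) -> str:
        return self.graph.edges[source, sink]["event"]

    def transcripts_at(self, node_labels: Iterable[str]) -> List[str]:
        labels = set(node_labels)
        return [n for n, d in self.graph.nodes(data=True) if d["gene"] in labels]

    def path_events(self, t1: str, t2: str) -> Optional[List[str]]:
        """Edge labels on the unique connecting path, or None if disconnected."""
        for tid in (t1, t2):
            self.gene_of(tid)  # raises on unknown id
        und = self.graph.to_undirected(as_view=True)
        try:
            path = nx.shortest_path(und, t1, t2)
        except nx.NetworkXNoPath:
            return None
        labels = []
        for a, b in zip(path, path[1:]):
            data = self.graph.get_edge_data(a, b) or self.graph.get_edge_data(b, a)
            labels.append(data["event"])
        return labels

    def conserved_components(self) -> List[Set[str]]:
        """Connected components of the conserved-edge subgraph (all nodes)."""
        sub = nx.Graph()
        sub.add_nodes_from(self.graph.nodes)
        sub.add_edges_from((a, b) for a, b, d in self.graph.edges(data=True)
                           if d["event"] == "conserved")
        return [set(c) for c in nx.connected_components(sub)]

    def validate(self) -> "TranscriptForest":
        if self.graph.number_of_nodes() \
                and not nx.is_forest(self.graph.to_undirected(as_view=True)):
            raise ValueError("transcript graph is not a forest")
        for n in self.graph:
            if self.graph.in_degree(n) > 1:
                raise ValueError(f"transcript {n} has more than one parent")
        return self
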