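"""Splicing orthology and transcript-conservation statistics.

Two transcripts are splicing orthologs when they belong to distinct
genes and the unique forest path connecting them carries only
``conserved`` edges — i.e. they descend from one ancestral isoform with
no AS event in between.  A group of orthologous transcripts is a set of
pairwise orthologs; groups are reported over the transcripts of the
guide tree's *leaf* genes (the extant isoforms), which is why an
ancestral transcript conserved in two leaves yields one group holding
the two leaf copies and not the ancestor itself.

The conservation ratio — conserved clusters / transcripts, in (0, 1]
— summarizes how much transcript conservation a simulation produced:
1 means every transcript sits alone, values near 0 mean heavy
clustering.  Clusters are taken either from the transcript phylogeny
(conserved components) or, as a history-free control, from identical
exon-composition signatures.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .forest import TranscriptForest
from .transcripts import Transcript


def are_orthologs(t1: str, t2: str, forest: TranscriptForest) -> bool:
    """True iff the two transcripts are splicing orthologs.

    Requires distinct genes, a connecting path in the forest, and only
    conserved edges on that path.  Raises ``KeyError`` on unknown ids.
    """
    g1, g2 = forest.gene_of(t1), forest.gene_of(t2)
    if t1 == t2 or g1 == g2:
        return False
    events = forest.path_events(t1, t2)
    if events is None:
        return False
    return all(e == "conserved" for e in events)


def ortholog_groups(forest: TranscriptForest,
                    leaf_labels: Iterable[str]) -> List[FrozenSet[str]]:
    """Maximal groups of pairwise-orthologous extant transcripts.

    Within one forest tree a conserved-edge component is geodesically
    convex, so its leaf-gene members are pairwise connected by conserved
    paths; maximality is then clique maximality in the pairwise-ortholog
    graph (components and cliques coincide on duplication-free guide
    trees, where one gene never contributes two members).
    """
    labels = set(leaf_labels)
    groups: List[FrozenSet[str]] = []
    for comp in forest.conserved_components():
        members = [t for t in comp if forest.gene_of(t) in labels]
        if len(members) < 2:
            continue
        pair_graph = nx.Graph()
        pair_graph.add_nodes_from(members)
        pair_graph.add_edges_from(
            (a, b) for a, b in combinations(members, 2)
            if forest.gene_of(a) != forest.gene_of(b))
        for clique in nx.find_cliques(pair_graph):
            if len(clique) >= 2:
                groups.append(frozenset(clique))
    return sorted(set(groups), key=lambda g: sorted(g))


def cluster_by_phylogeny(forest: TranscriptForest,
                         leaf_labels: Iterable[str]) -> List[Set[str]]:
    """Partition extant transcripts by conserved-edge connectivity.

    Two leaf transcripts share a cluster when a conserved path (possibly
    through ancestral transcripts) joins them; unclustered transcripts
    form singletons.
    """
    labels = set(leaf_labels)
    clusters = []
    for comp in forest.conserved_components():
        members = {t for t in comp if forest.gene_of(t) in labels}
        if members:
            clusters.append(members)
    return clusters


def cluster_by_exon_composition(transcripts: Sequence[Transcript]) -> List[Set[str]]:
    """Partition transcripts by identical splicing signature.

    The signature is the homologous exon-id composition including a5/a3
    offsets and retained introns; two transcripts cluster only when the
    signatures match exactly.
    """
    by_sig: Dict[Tuple, Set[str]] = {}
    for t in transcripts:
        by_sig.setdefault(t.signature(), set()).add(t.tid)
    return list(by_sig.values())


def conservation_ratio(clusters: Sequence[Set[str]],
                       transcripts: Iterable[str]) -> float:
    """Conserved clusters over transcripts; requires a true partition."""
    tids = set(transcripts)
    if not tids:
        raise ValueError("conservation ratio undefined for zero transcripts")
    covered: Set[str] = set()
    total = 0
    for c in clusters:
        total += len(c)
        covered |= set(c)
    if covered != tids or total != len(tids):
        raise ValueError("clusters must partition the transcript set")
    return len(clusters) / len(tids)


@dataclass
class ConservationReport:
    n_clusters: int
    n_transcripts: int
    ratio: float
    mode: str


def conservation_report(result, mode: str = "phylogeny") -> ConservationReport:
    """Compute the conservation ratio of a finished simulation."""
    leaf_labels = [l.label for l in result.tree.leaves]
    leaf_ts = result.leaf_transcripts()
    tids = [t.tid for t in leaf_ts]
    if mode == "phylogeny":
        clusters = cluster_by_phylogeny(result.forest, leaf_labels)
    elif mode == "composition":
        clusters = cluster_by_exon_composition(leaf_ts)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    ratio = conservation_ratio(clusters, tids)
    return ConservationReport(n_clusters=len(clusters),
                              n_transcripts=len(tids), ratio=ratio, mode=mode)
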