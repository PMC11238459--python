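"""The simulation driver: one preorder pass over the guide tree.

At the root a gene structure and its transcript set are generated; on
every branch the structure evolves (exon loss / gain / duplication),
every surviving exon and intron sequence evolves (codon-level /
nucleotide-level), and the transcript set is propagated through the
loss / gain / AS-stage pipeline.  All randomness flows through
per-node generator streams derived from ``(seed, preorder index)``, so
two runs with the same seed are byte-identical and a node's draws do
not depend on how its siblings were processed.

Two transcript modes are supported:

* ``linked`` — transcript sets evolve along branches (the full model);
* ``independent`` — a history-free control in which every node's
  transcript set is regenerated from its own structure with the root
  procedure, severing all cross-node transcript ancestry.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .alignment import ColumnSystem, apply_events_to_columns
from .config import SimulationConfig
from .forest import TranscriptForest
from .sequences import (SequenceEvent, evolve_exon_sequence,
                        evolve_intron_sequence)
from .structure import (GeneStructure, StructureEvent, evolve_structure,
                        simulate_root_structure)
from .transcripts import (IdAllocator, Stage, Transcript,
                          propagate_transcripts, simulate_root_transcripts)
from .tree import GuideTree, parse_guide_tree


@dataclass
class EventRecord:
    """One row of the unified event log."""

    category: str          # transcript | structure | sequence
    node: str              # gene node the event acts at (child of the branch)
    branch: str            # "parent->child" or "" at the root
    stage: int
    event_type: str
    source_id: str = ""
    sink_id: str = ""
    payload: str = ""


@dataclass
class SimulationResult:
    tree: GuideTree
    config: SimulationConfig
    mode: str
    structures: Dict[str, GeneStructure]
    transcripts: Dict[str, List[Transcript]]
    forest: TranscriptForest
    stages: List[Stage]
    structure_events: Dict[str, List[StructureEvent]]
    #: branch label -> list of (element label, parent seq, event log)
    sequence_logs: Dict[str, List[Tuple[str, str, List[SequenceEvent]]]]
    events: List[EventRecord]
    colsys: ColumnSystem

    def leaf_transcripts(self) -> List[Transcript]:
        out: List[Transcript] = []
        for leaf in self.tree.leaves:
            out.extend(self.transcripts[leaf.label])
        return out


def _node_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _evolve_sequences(child: GeneStructure, branch_length: float,
                      config: SimulationConfig, rng: np.random.Generator,
                      colsys: ColumnSystem, branch: str,
                      ) -> List[Tuple[str, str, List[SequenceEvent]]]:
    logs: List[Tuple[str, str, List[SequenceEvent]]] = []
    for exon in child.exons:
        old = exon.seq
        exon.seq, events = evolve_exon_sequence(old, branch_length, config, rng)
        exon.cols = apply_events_to_columns(colsys, exon.cols, events,
                                            origin=f"{branch}:ins")
        logs.append((f"exon:{exon.exon_id}", old, events))
    for idx, intron in enumerate(child.introns):
        old = intron.seq
        intron.seq, events = evolve_intron_sequence(old, branch_length, config, rng)
        intron.cols = apply_events_to_columns(colsys, intron.cols, events,
                                              origin=f"{branch}:ins")
        logs.append((f"intron:{idx}", old, events))
    return logs


def _log_stages(records: List[EventRecord], stages: List[Stage], node: str,
                branch: str) -> None:
    for st in stages:
        for etype, src, sink in st.events:
            records.append(EventRecord("transcript", node, branch, st.index,
                                       etype, src or "", sink or ""))
        if st.shortfall:
            records.append(EventRecord("transcript", node, branch, st.index,
                                       f"{st.kind}_shortfall",
                                       payload=str(st.shortfall)))


def _forest_add_stages(forest: TranscriptForest, stages: List[Stage],
                       node: str, branch: str) -> None:
    for st in stages:
        for etype, src, sink in st.events:
            if sink is not None and sink not in forest:
                forest.add_transcript(sink, node)
            if etype in ("structural_loss", "tl"):
                forest.mark_lost(src, branch, etype)
            elif src is None:
                continue  # rs gain: a new forest root
            else:
                forest.add_edge(src, sink, etype)


def simulate(tree: Union[GuideTree, str], config: Optional[SimulationConfig] = None,
             mode: str = "linked") -> SimulationResult:
    """Run a full simulation over the guide tree.

    ``tree`` may be a :class:`GuideTree` or a Newick/NHX string.
    Returns every simulated artifact: per-node structures and
    transcript sets, the transcript forest, stage and event logs, and
    the homology-column system backing the true alignment.
    """
    if isinstance(tree, str):
        tree = parse_guide_tree(tree)
    config = (config or SimulationConfig()).validate()
    if mode not in ("linked", "independent"):
        raise ValueError(f"unknown mode {mode!r}")

    colsys = ColumnSystem()
    exon_ids = itertools.count(1)
    structures: Dict[str, GeneStructure] = {}
    transcripts: Dict[str, List[Transcript]] = {}
    structure_events: Dict[str, List[StructureEvent]] = {}
    sequence_logs: Dict[str, List[Tuple[str, str, List[SequenceEvent]]]] = {}
    all_stages: List[Stage] = []
    records: List[EventRecord] = []
    forest = TranscriptForest()

    for node in tree.preorder():
        rng = _node_rng(config.seed, node.index)
        if node.is_root:
            st = simulate_root_structure(config, rng, colsys, exon_ids,
                                         node_label=node.label)
            structures[node.label] = st
            ts, stages = simulate_root_transcripts(
                st, config, rng, IdAllocator(node.label))
            transcripts[node.label] = ts
            _forest_add_stages(forest, stages, node.label, branch="")
            _log_stages(records, stages, node.label, branch="")
            all_stages.extend(stages)
            continue

        parent_label = node.parent.label
        branch = f"{parent_label}->{node.label}"
        child_st, sev = evolve_structure(structures[parent_label], node.length,
                                         config, rng, colsys, exon_ids,
                                         child_label=node.label)
        structure_events[branch] = sev
        for ev in sev:
            records.append(EventRecord("structure", node.label, branch, 0,
                                       ev.kind, source_id=ev.template_id,
                                       sink_id=ev.exon_id,
                                       payload=f"index={ev.index}"))
        slogs = _evolve_sequences(child_st, node.length, config, rng, colsys,
                                  branch)
        sequence_logs[branch] = slogs
        for label, _old, evs in slogs:
            for ev in evs:
                records.append(EventRecord(
                    "sequence", node.label, branch, 0, ev.kind,
                    source_id=label,
                    payload=f"pos={ev.pos};old={ev.old};new={ev.new}"))
        structures[node.label] = child_st

        if mode == "linked":
            ts, stages = propagate_transcripts(
                transcripts[parent_label], structures[parent_label], child_st,
                node.length, config, rng, IdAllocator(node.label))
        else:
            ts, stages = simulate_root_transcripts(
                child_st, config, rng, IdAllocator(node.label))
        transcripts[node.label] = ts
        _forest_add_stages(forest, stages, node.label, branch=branch)
        _log_stages(records, stages, node.label, branch=branch)
        all_stages.extend(stages)

    forest.validate()
    return SimulationResult(tree=tree, config=config, mode=mode,
                            structures=structures, transcripts=transcripts,
                            forest=forest, stages=all_stages,
                            structure_events=structure_events,
                            sequence_logs=sequence_logs, events=records,
                            colsys=colsys)
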