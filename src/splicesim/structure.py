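"""Exon-intron structure of a gene and its evolution along branches.

A gene at one guide-tree node is an ordered alternation of exons and
introns (always ``|introns| = |exons| - 1``).  Along a branch the
structure changes by three elementary events — exon loss, exon gain and
exon duplication — whose counts follow the same ceiling budget used for
transcripts, with structure-specific constants.  Exon identifiers are
stable across the tree and never reused after a loss, so the process
obeys Dollo parsimony by construction: a gained or duplicated exon
always receives a fresh id.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .alignment import ColumnSystem
from .config import SimulationConfig, event_budget
from .sequences import (MarkovChainParams, generate_exon_sequence,
                        generate_intron_sequence)


@dataclass
class Exon:
    exon_id: str
    seq: str
    cols: List[int] = field(default_factory=list)
    parent_exon_id: Optional[str] = None   # set for duplicated exons


@dataclass
class Intron:
    seq: str
    cols: List[int] = field(default_factory=list)


@dataclass
class GeneStructure:
    node_label: str
    exons: List[Exon]
    introns: List[Intron]

    def validate(self) -> "GeneStructure":
        if not self.exons:
            raise ValueError("a gene must keep at least one exon")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError("|introns| must equal |exons| - 1")
        for e in self.exons:
            if len(e.seq) % 3 or len(e.seq) < 3:
                raise ValueError(f"exon {e.exon_id} length not a positive multiple of 3")
        return self

    @property
    def exon_ids(self) -> List[str]:
        return [e.exon_id for e in self.exons]

    def exon_index(self, exon_id: str) -> int:
        for i, e in enumerate(self.exons):
            if e.exon_id == exon_id:
                return i
        raise KeyError(exon_id)

    def elements(self) -> Iterator[Tuple[str, object]]:
        """Alternating ('exon', Exon) / ('intron', Intron) in gene order."""
        for i, e in enumerate(self.exons):
            yield ("exon", e)
            if i < len(self.introns):
                yield ("intron", self.introns[i])

    def gene_sequence(self) -> str:
        return "".join(el.seq for _, el in self.elements())

    def gene_cols(self) -> List[int]:
        out: List[int] = []
        for _, el in self.elements():
            out.extend(el.cols)
        return out

    def copy_for(self, node_label: str) -> "GeneStructure":
        return GeneStructure(
            node_label=node_label,
            exons=[Exon(e.exon_id, e.seq, list(e.cols), e.parent_exon_id)
                   for e in self.exons],
            introns=[Intron(i.seq, list(i.cols)) for i in self.introns],
        )


@dataclass(frozen=True)
class StructureEvent:
    """One structure mutation; the log replays parent -> child exactly."""

    kind: str            # exon_loss | exon_gain | exon_duplication | exon_loss_skipped
    exon_id: str
    index: int           # exon index (loss/dup template) or insertion slot (gain)
    seq: str = ""        # gained/duplicated exon sequence at creation time
    intron_seq: str = "" # fresh intron accompanying a gain/duplication
    template_id: str = ""  # duplication template


# ---------------------------------------------------------------------------
# Dimension draws
# ---------------------------------------------------------------------------

def _draw_exon_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    raw = rng.normal(config.exon_length_mean, config.exon_length_sd)
    length = 3 * int(round(raw / 3.0))
    return max(config.min_exon_length, length)


def _draw_intron_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    raw = rng.normal(config.intron_length_mean, config.intron_length_sd)
    return max(config.min_intron_length, int(round(raw)))


def _draw_exon_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.exon_count is not None:
        return config.exon_count
    return max(1, int(round(rng.normal(config.exon_count_mean, config.exon_count_sd))))


# ---------------------------------------------------------------------------
# Root structure
# ---------------------------------------------------------------------------

def simulate_root_structure(config: SimulationConfig, rng: np.random.Generator,
                            colsys: Optional[ColumnSystem] = None,
                            exon_ids: Optional[Iterator[int]] = None,
                            node_label: str = "root") -> GeneStructure:
    """Generate the ancestral gene: m exons and m-1 introns."""
    colsys = colsys if colsys is not None else ColumnSystem()
    exon_ids = exon_ids if exon_ids is not None else itertools.count(1)
    exon_mc = config.exon_markov or MarkovChainParams.default_exon()
    intron_mc = config.intron_markov or MarkovChainParams.default_intron()
    m = _draw_exon_count(config, rng)
    exons: List[Exon] = []
    introns: List[Intron] = []
    for j in range(m):
        seq = generate_exon_sequence(_draw_exon_length(config, rng), exon_mc, rng)
        eid = f"exon{next(exon_ids)}"
        exons.append(Exon(eid, seq, colsys.append_block(len(seq), f"root:{eid}")))
        if j < m - 1:
            iseq = generate_intron_sequence(_draw_intron_length(config, rng),
                                            intron_mc, rng)
            introns.append(Intron(iseq, colsys.append_block(len(iseq),
                                                           f"root:intron{j}")))
    return GeneStructure(node_label, exons, introns).validate()


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------

def evolve_structure(parent: GeneStructure, branch_length: float,
                     config: SimulationConfig, rng: np.random.Generator,
                     colsys: Optional[ColumnSystem] = None,
                     exon_ids: Optional[Iterator[int]] = None,
                     child_label: str = "child",
                     ) -> Tuple[GeneStructure, List[StructureEvent]]:
    """Evolve an exon-intron structure along one branch.

    Event counts per kind follow ``ceil(k_structure * c_s_r * m * p_kind)``
    with ``m`` the parent's exon count.  Losses remove an exon and merge
    its flanking introns; a loss that would leave the gene exonless is
    skipped and logged.  Gains insert a freshly generated exon (new id)
    at a uniform slot; duplications insert a verbatim copy (new id,
    template-linked) immediately downstream of its template.
    """
    parent.validate()
    if colsys is None:
        colsys = ColumnSystem()
        colsys.adopt(parent.gene_cols())
    exon_ids = exon_ids if exon_ids is not None else itertools.count(10 ** 6)
    exon_mc = config.exon_markov or MarkovChainParams.default_exon()
    intron_mc = config.intron_markov or MarkovChainParams.default_intron()
    child = parent.copy_for(child_label)
    events: List[StructureEvent] = []
    m = len(parent.exons)
    n_loss = event_budget(m, config.p_exon_loss, config.k_structure, branch_length)
    n_gain = event_budget(m, config.p_exon_gain, config.k_structure, branch_length)
    n_dup = event_budget(m, config.p_exon_dup, config.k_structure, branch_length)

    for _ in range(n_loss):
        if len(child.exons) == 1:
            events.append(StructureEvent("exon_loss_skipped",
                                         child.exons[0].exon_id, 0))
            continue
        j = int(rng.integers(len(child.exons)))
        lost = child.exons.pop(j)
        if j == 0:
            child.introns.pop(0)
        elif j == len(child.exons):  # was the last exon
            child.introns.pop()
        else:
            left, right = child.introns[j - 1], child.introns[j]
            child.introns[j - 1] = Intron(left.seq + right.seq,
                                          left.cols + right.cols)
            child.introns.pop(j)
        events.append(StructureEvent("exon_loss", lost.exon_id, j))

    for _ in range(n_gain):
        j = int(rng.integers(len(child.exons) + 1))
        eid = f"exon{next(exon_ids)}"
        eseq = generate_exon_sequence(_draw_exon_length(config, rng), exon_mc, rng)
        iseq = generate_intron_sequence(_draw_intron_length(config, rng),
                                        intron_mc, rng)
        origin = f"{child_label}:gain:{eid}"
        _insert_exon(child, colsys, j, Exon(eid, eseq), iseq, origin)
        events.append(StructureEvent("exon_gain", eid, j, seq=eseq,
                                     intron_seq=iseq))

    for _ in range(n_dup):
        j = int(rng.integers(len(child.exons)))
        template = child.exons[j]
        eid = f"exon{next(exon_ids)}"
        iseq = generate_intron_sequence(_draw_intron_length(config, rng),
                                        intron_mc, rng)
        copy = Exon(eid, template.seq, parent_exon_id=template.exon_id)
        origin = f"{child_label}:dup:{eid}"
        icols = colsys.insert_after(template.cols[-1], len(iseq), origin)
        ecols = colsys.insert_after(icols[-1], len(template.seq), origin)
        copy.cols = ecols
        child.exons.insert(j + 1, copy)
        child.introns.insert(j, Intron(iseq, icols))
        events.append(StructureEvent("exon_duplication", eid, j + 1,
                                     seq=template.seq, intron_seq=iseq,
                                     template_id=template.exon_id))

    return child.validate(), events


def _insert_exon(child: GeneStructure, colsys: ColumnSystem, slot: int,
                 exon: Exon, intron_seq: str, origin: str) -> None:
    """Insert a fresh exon at ``slot`` (0..m), wiring a fresh intron."""
    m = len(child.exons)
    if slot == 0:
        anchor = child.exons[0].cols[0]
        ecols = colsys.insert_before(anchor, len(exon.seq), origin)
        icols = colsys.insert_after(ecols[-1], len(intron_seq), origin)
        exon.cols = ecols
        child.exons.insert(0, exon)
        child.introns.insert(0, Intron(intron_seq, icols))
    elif slot == m:
        anchor = child.exons[-1].cols[-1]
        icols = colsys.insert_after(anchor, len(intron_seq), origin)
        ecols = colsys.insert_after(icols[-1], len(exon.seq), origin)
        exon.cols = ecols
        child.exons.append(exon)
        child.introns.append(Intron(intron_seq, icols))
    else:
        # between exons slot-1 and slot: existing intron stays on the left
        anchor = child.introns[slot - 1].cols[-1]
        ecols = colsys.insert_after(anchor, len(exon.seq), origin)
        icols = colsys.insert_after(ecols[-1], len(intron_seq), origin)
        exon.cols = ecols
        child.exons.insert(slot, exon)
        child.introns.insert(slot, Intron(intron_seq, icols))


# ---------------------------------------------------------------------------
# Replay oracle
# ---------------------------------------------------------------------------

def replay_structure(parent: GeneStructure,
                     events: List[StructureEvent],
                     child_label: str = "replayed") -> GeneStructure:
    """Re-derive the child structure from the parent and the event log.

    Columns are not reconstructed (they require the live column system);
    the replay compares by exon ids, order and sequences.
    """
    child = GeneStructure(
        node_label=child_label,
        exons=[Exon(e.exon_id, e.seq, [], e.parent_exon_id) for e in parent.exons],
        introns=[Intron(i.seq, []) for i in parent.introns],
    )
    for ev in events:
        if ev.kind == "exon_loss_skipped":
            continue
        if ev.kind == "exon_loss":
            j = ev.index
            assert child.exons[j].exon_id == ev.exon_id
            child.exons.pop(j)
            if j == 0:
                child.introns.pop(0)
            elif j == len(child.exons):
                child.introns.pop()
            else:
                left, right = child.introns[j - 1], child.introns[j]
                child.introns[j - 1] = Intron(left.seq + right.seq, [])
                child.introns.pop(j)
        elif ev.kind == "exon_gain":
            j = ev.index
            m = len(child.exons)
            if j == 0:
                child.exons.insert(0, Exon(ev.exon_id, ev.seq))
                child.introns.insert(0, Intron(ev.intron_seq))
            elif j == m:
                child.exons.append(Exon(ev.exon_id, ev.seq))
                child.introns.append(Intron(ev.intron_seq))
            else:
                child.exons.insert(j, Exon(ev.exon_id, ev.seq))
                child.introns.insert(j, Intron(ev.intron_seq))
        elif ev.kind == "exon_duplication":
            j = ev.index
            child.exons.insert(j, Exon(ev.exon_id, ev.seq,
                                       parent_exon_id=ev.template_id))
            child.introns.insert(j - 1, Intron(ev.intron_seq))
        else:
            raise ValueError(f"unknown structure event {ev.kind!r}")
    return child.validate()


def structures_equal(a: GeneStructure, b: GeneStructure) -> bool:
    return ([(e.exon_id, e.seq) for e in a.exons]
            == [(e.exon_id, e.seq) for e in b.exons]
            and [i.seq for i in a.introns] == [i.seq for i in b.introns])
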