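"""Evolution of transcript sets along the guide tree — the core model.

A transcript is an ordered, non-empty subset of its gene's exons plus
splice modifiers: signed 5'/3' boundary offsets (from alternative
splice-site selection, always multiples of 3) and retained introns
(identified by their flanking exon pair).  Seven event types act on a
gene's transcript set: the five alternative-splicing events (a5, a3,
es, me, ir), transcript gain by random selection from the ``2^m - 1``
isoform pool (rs), and transcript loss (tl).

Evolution proceeds in *evolutionary stages*: a stage turns a set of
source transcripts into a sink set by applying a budgeted number of
events of one type; every sink links to at most one source.  At the
root the budget is ``ceil(n * tc_x)``; on a branch of length ``c_s_r``
it is ``ceil(k_tc * c_s_r * n * tc_x)``, with ``n`` recomputed from the
current source count at each stage.  One stage runs per AS type, in a
configurable order, which both terminates and lets a transcript undergo
several successive events (each stage's sinks are the next stage's
sources).  Losses never occur at the root.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import SimulationConfig, event_budget, root_event_budget
from .structure import GeneStructure


class Inapplicable(Exception):
    """The drawn (transcript, event-type) pair cannot produce a new isoform."""


# ---------------------------------------------------------------------------
# Transcript
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    tid: str
    node_label: str
    exon_ids: Tuple[str, ...]
    #: exon_id -> (acceptor-side offset, donor-side offset), nt, multiples of 3;
    #: positive trims into the exon, negative extends into the flanking intron
    offsets: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    #: retained introns as (left exon id, right exon id) junctions
    retained: FrozenSet[Tuple[str, str]] = frozenset()
    provenance: Optional[str] = None

    def signature(self) -> Tuple:
        """Splicing identity: exon composition, offsets and retentions."""
        offsets = tuple(sorted((k, v) for k, v in self.offsets.items()
                               if v != (0, 0)))
        return (self.exon_ids, offsets, tuple(sorted(self.retained)))

    def offset(self, exon_id: str) -> Tuple[int, int]:
        return self.offsets.get(exon_id, (0, 0))


def isoform_pool_size(m: int) -> int:
    """Number of possible isoforms of an m-exon gene: 2^m - 1."""
    if m < 1:
        raise ValueError(f"exon count must be >= 1, got {m}")
    return 2 ** m - 1


def raw_root_transcript_draws(rng: np.random.Generator, size: int,
                              mean: float = 1.45, sd: float = 1.08) -> np.ndarray:
    """Raw Normal(mean, sd) draws behind the root transcript count."""
    return rng.normal(mean, sd, size=size)


def sample_root_transcript_count(rng: np.random.Generator,
                                 mean: float = 1.45, sd: float = 1.08) -> int:
    """Root transcript count: Normal draw, rounded, clamped to >= 1."""
    return max(1, int(round(float(rng.normal(mean, sd)))))


def transcript_from_mask(structure: GeneStructure, mask: int, tid: str) -> Transcript:
    exon_ids = tuple(e.exon_id for j, e in enumerate(structure.exons)
                     if mask >> j & 1)
    if not exon_ids:
        raise ValueError("empty exon mask")
    return Transcript(tid=tid, node_label=structure.node_label, exon_ids=exon_ids)


def transcript_mask(structure: GeneStructure, t: Transcript) -> int:
    index = {e.exon_id: j for j, e in enumerate(structure.exons)}
    mask = 0
    for eid in t.exon_ids:
        mask |= 1 << index[eid]
    return mask


def sample_isoform_masks(m: int, n: int, rng: np.random.Generator,
                         exclude: Optional[Set[int]] = None) -> List[int]:
    """Draw n distinct non-empty exon subsets uniformly from the pool.

    ``exclude`` removes masks from the pool (already-present isoforms);
    n is clamped to the available pool size.
    """
    exclude = exclude or set()
    pool = isoform_pool_size(m)
    avail = pool - len(exclude)
    n = min(n, max(avail, 0))
    if n <= 0:
        return []
    if m <= 16:
        candidates = np.array([x for x in range(1, pool + 1) if x not in exclude])
        picked = rng.choice(candidates, size=n, replace=False)
        return [int(x) for x in picked]
    out: Set[int] = set()
    while len(out) < n:  # rejection sampling for very wide genes
        x = int(rng.integers(1, pool + 1))
        if x not in exclude and x not in out:
            out.add(x)
    return sorted(out)


class IdAllocator:
    """Sequential 'label#k' transcript ids for one gene node."""

    def __init__(self, node_label: str, start: int = 1):
        self.node_label = node_label
        self._k = start

    def next(self) -> str:
        tid = f"{self.node_label}#{self._k}"
        self._k += 1
        return tid


# ---------------------------------------------------------------------------
# AS events
# ---------------------------------------------------------------------------

def _order_by_structure(structure: GeneStructure, ids: Iterable[str]) -> Tuple[str, ...]:
    pos = {e.exon_id: j for j, e in enumerate(structure.exons)}
    return tuple(sorted(ids, key=pos.__getitem__))


def _retained_junctions(t: Transcript, structure: GeneStructure
                        ) -> List[Tuple[str, str]]:
    """Junctions of t eligible for intron retention (structure-adjacent)."""
    pos = {e.exon_id: j for j, e in enumerate(structure.exons)}
    out = []
    for a, b in zip(t.exon_ids, t.exon_ids[1:]):
        if pos[b] == pos[a] + 1 and (a, b) not in t.retained:
            out.append((a, b))
    return out


def apply_as_event(t: Transcript, kind: str, structure: GeneStructure,
                   rng: np.random.Generator, tid_factory: IdAllocator,
                   config: Optional[SimulationConfig] = None) -> Transcript:
    """Derive a new transcript from ``t`` by one AS event.

    Raises :class:`Inapplicable` when the event cannot change ``t``
    (es on a single-exon transcript, me with no absent exon, ir with no
    eligible junction, a5/a3 with no feasible boundary shift).
    """
    config = config or SimulationConfig()
    if kind == "es":
        if len(t.exon_ids) < 2:
            raise Inapplicable("es needs >= 2 exons")
        j = int(rng.integers(len(t.exon_ids)))
        removed = t.exon_ids[j]
        new_ids = t.exon_ids[:j] + t.exon_ids[j + 1:]
        return Transcript(
            tid=tid_factory.next(), node_label=t.node_label, exon_ids=new_ids,
            offsets={k: v for k, v in t.offsets.items() if k != removed},
            retained=frozenset(p for p in t.retained if removed not in p),
            provenance=t.tid)
    if kind == "me":
        absent = [e.exon_id for e in structure.exons if e.exon_id not in t.exon_ids]
        if not absent:
            raise Inapplicable("me needs an absent structure exon")
        out_id = t.exon_ids[int(rng.integers(len(t.exon_ids)))]
        in_id = absent[int(rng.integers(len(absent)))]
        new_ids = _order_by_structure(
            structure, [e for e in t.exon_ids if e != out_id] + [in_id])
        return Transcript(
            tid=tid_factory.next(), node_label=t.node_label, exon_ids=new_ids,
            offsets={k: v for k, v in t.offsets.items() if k != out_id},
            retained=frozenset(p for p in t.retained if out_id not in p),
            provenance=t.tid)
    if kind in ("a5", "a3"):
        return _apply_boundary_shift(t, kind, structure, rng, tid_factory, config)
    if kind == "ir":
        junctions = _retained_junctions(t, structure)
        if not junctions:
            raise Inapplicable("ir needs a structure-adjacent unretained junction")
        pair = junctions[int(rng.integers(len(junctions)))]
        return replace(t, tid=tid_factory.next(), offsets=dict(t.offsets),
                       retained=t.retained | {pair}, provenance=t.tid)
    raise KeyError(f"unknown AS event type {kind!r}")


def _apply_boundary_shift(t: Transcript, kind: str, structure: GeneStructure,
                          rng: np.random.Generator, tid_factory: IdAllocator,
                          config: SimulationConfig) -> Transcript:
    """a5 shifts an exon's donor (3') boundary, a3 its acceptor (5')."""
    side = 1 if kind == "a5" else 0
    pos = {e.exon_id: j for j, e in enumerate(structure.exons)}
    m = len(structure.exons)
    for _attempt in range(4 * len(t.exon_ids) + 4):
        eid = t.exon_ids[int(rng.integers(len(t.exon_ids)))]
        j = pos[eid]
        exon_len = len(structure.exons[j].seq)
        cur5, cur3 = t.offset(eid)
        cur = (cur5, cur3)[side]
        other = (cur5, cur3)[1 - side]
        mag = 3 * min(int(rng.geometric(1.0 / max(config.offset_mean_codons, 1.0))),
                      config.offset_max_codons)
        for sign in rng.permutation([1, -1]):
            new = cur + sign * mag
            if new == cur:
                continue
            if new > 0:
                # both positive trims must leave >= 3 nt of exon
                if new + max(other, 0) > exon_len - 3:
                    continue
            elif new < 0:
                # extension needs a flanking intron on that side
                if side == 1 and j >= m - 1:
                    continue
                if side == 0 and j == 0:
                    continue
            offsets = dict(t.offsets)
            offsets[eid] = (new, cur3) if side == 0 else (cur5, new)
            return replace(t, tid=tid_factory.next(), offsets=offsets,
                           retained=t.retained, provenance=t.tid)
    raise Inapplicable(f"{kind}: no feasible boundary shift")


# ---------------------------------------------------------------------------
# Spliced (CDS) sequence assembly
# ---------------------------------------------------------------------------

def spliced_segments(t: Transcript, structure: GeneStructure
                     ) -> List[Tuple[str, str, List[int]]]:
    """The transcript's CDS as ordered pieces of (label, seq, columns).

    Pieces are exon cores after effective boundary offsets, intron
    extensions from negative offsets, and retained-intron bodies (3'
    trimmed to a multiple of 3).  Offsets are clamped here, at build
    time, because exon and intron lengths drift along branches after
    the offset was drawn; every piece length is a multiple of 3.
    """
    pos = {e.exon_id: j for j, e in enumerate(structure.exons)}
    pieces: List[Tuple[str, str, List[int]]] = []
    for rank, eid in enumerate(t.exon_ids):
        j = pos[eid]
        exon = structure.exons[j]
        off5, off3 = t.offset(eid)
        L = len(exon.seq)
        t5 = min(off5, 3 * ((L - 3) // 3)) if off5 > 0 else 0
        t3 = min(off3, 3 * ((L - 3 - t5) // 3)) if off3 > 0 else 0

        left_retained = (rank > 0
                         and (t.exon_ids[rank - 1], eid) in t.retained
                         and pos[t.exon_ids[rank - 1]] == j - 1)
        right_retained = (rank < len(t.exon_ids) - 1
                          and (eid, t.exon_ids[rank + 1]) in t.retained
                          and pos[t.exon_ids[rank + 1]] == j + 1)

        if off5 < 0 and j > 0 and not left_retained:
            intr = structure.introns[j - 1]
            avail = 3 * ((len(intr.seq) // 2) // 3)
            e5 = min(-off5, avail)
            if e5:
                pieces.append((f"ext5:{eid}", intr.seq[-e5:], intr.cols[-e5:]))
        pieces.append((f"exon:{eid}", exon.seq[t5:L - t3], exon.cols[t5:L - t3]))
        if off3 < 0 and j < len(structure.exons) - 1 and not right_retained:
            intr = structure.introns[j]
            avail = 3 * ((len(intr.seq) // 2) // 3)
            e3 = min(-off3, avail)
            if e3:
                pieces.append((f"ext3:{eid}", intr.seq[:e3], intr.cols[:e3]))
        if right_retained:
            intr = structure.introns[j]
            inc = 3 * (len(intr.seq) // 3)
            if inc:
                pieces.append((f"intron:{eid}-{t.exon_ids[rank + 1]}",
                               intr.seq[:inc], intr.cols[:inc]))
    return pieces


def spliced_sequence(t: Transcript, structure: GeneStructure
                     ) -> Tuple[str, List[int]]:
    """The transcript's CDS and its homology columns."""
    seq_parts: List[str] = []
    cols: List[int] = []
    for _, s, c in spliced_segments(t, structure):
        seq_parts.append(s)
        cols.extend(c)
    return "".join(seq_parts), cols


# ---------------------------------------------------------------------------
# Evolutionary stages
# ---------------------------------------------------------------------------

@dataclass
class Stage:
    """One evolutionary stage: source set -> sink set under one event type."""

    scope: str                  # node label or "parent->child"
    index: int
    kind: str                   # selection | structural | tl | conserved | rs | AS type
    budget: Optional[int]
    sources: List[str]
    events: List[Tuple[str, Optional[str], Optional[str]]] = field(default_factory=list)
    shortfall: int = 0

    @property
    def sinks(self) -> List[str]:
        return [s for _, _, s in self.events if s is not None]


def run_as_stage(transcripts: List[Transcript], kind: str, budget: int,
                 structure: GeneStructure, config: SimulationConfig,
                 rng: np.random.Generator, alloc: IdAllocator,
                 scope: str, index: int) -> Stage:
    """Apply ``budget`` events of one AS type to a source snapshot.

    Sources are the transcripts present when the stage opens; each
    event draws a source uniformly (a transcript may be drawn more than
    once) and appends the derived sink to ``transcripts``.  When a draw
    is inapplicable, the source is redrawn up to n times, then the
    event is skipped and counted as shortfall.
    """
    snapshot = list(transcripts)
    stage = Stage(scope=scope, index=index, kind=kind, budget=budget,
                  sources=[t.tid for t in snapshot])
    if not snapshot:
        stage.shortfall = budget
        return stage
    for _ in range(budget):
        created = None
        for _try in range(max(1, len(snapshot))):
            src = snapshot[int(rng.integers(len(snapshot)))]
            try:
                created = apply_as_event(src, kind, structure, rng, alloc, config)
            except Inapplicable:
                continue
            break
        if created is None:
            stage.shortfall += 1
            continue
        transcripts.append(created)
        stage.events.append((kind, src.tid, created.tid))
    return stage


# ---------------------------------------------------------------------------
# Root simulation
# ---------------------------------------------------------------------------

def simulate_root_transcripts(structure: GeneStructure, config: SimulationConfig,
                              rng: np.random.Generator,
                              alloc: Optional[IdAllocator] = None,
                              use_branch_budget: bool = False,
                              branch_length: float = 0.0,
                              ) -> Tuple[List[Transcript], List[Stage]]:
    """Two-step root procedure: random isoform selection, then AS stages.

    If ``tc_rs`` is 0, a single transcript holding every exon is
    selected; otherwise Normal(1.45, 1.08) (rounded, clamped to >= 1,
    clamped to the pool size) transcripts are drawn uniformly without
    replacement from the ``2^m - 1`` pool.  No transcripts are lost at
    the root.  With ``use_branch_budget`` the same procedure serves the
    history-free per-node mode of branch nodes.
    """
    alloc = alloc or IdAllocator(structure.node_label)
    m = len(structure.exons)
    stages: List[Stage] = []
    transcripts: List[Transcript] = []

    selection = Stage(scope=structure.node_label, index=0, kind="selection",
                      budget=None, sources=[])
    if config.tc_rs == 0:
        t = Transcript(tid=alloc.next(), node_label=structure.node_label,
                       exon_ids=tuple(structure.exon_ids))
        transcripts.append(t)
        selection.events.append(("rs", None, t.tid))
    else:
        n = (config.root_transcript_count
             if config.root_transcript_count is not None
             else sample_root_transcript_count(rng, config.root_count_mean,
                                               config.root_count_sd))
        masks = sample_isoform_masks(m, n, rng)
        for mask in masks:
            t = transcript_from_mask(structure, mask, alloc.next())
            transcripts.append(t)
            selection.events.append(("rs", None, t.tid))
    stages.append(selection)

    for i, kind in enumerate(config.stage_order, start=1):
        p = config.proportion(kind)
        if use_branch_budget:
            budget = event_budget(len(transcripts), p, config.k_tc, branch_length)
        else:
            budget = root_event_budget(len(transcripts), p)
        stages.append(run_as_stage(transcripts, kind, budget, structure, config,
                                   rng, alloc, scope=structure.node_label, index=i))
    return transcripts, stages


# ---------------------------------------------------------------------------
# Branch propagation
# ---------------------------------------------------------------------------

def propagate_transcripts(parent_transcripts: Sequence[Transcript],
                          parent_structure: GeneStructure,
                          child_structure: GeneStructure,
                          branch_length: float,
                          config: SimulationConfig,
                          rng: np.random.Generator,
                          alloc: Optional[IdAllocator] = None,
                          ) -> Tuple[List[Transcript], List[Stage]]:
    """Propagate a transcript set from a parent gene to its child.

    Pipeline: (1) structural losses — every parent transcript whose
    exon set or retained-intron junctions were disrupted by structure
    events is lost; survivors are the conserved transcripts; (2)
    regulated losses drawn with the ``tc_tl`` budget among survivors;
    (3) conserved copies instantiated at the child (conserved edges);
    (4) gains from the child's isoform pool with the ``tc_rs`` budget
    (new forest roots; exact duplicates of existing isoforms excluded);
    (5) one AS stage per event type with branch budgets.
    """
    alloc = alloc or IdAllocator(child_structure.node_label)
    scope = f"{parent_structure.node_label}->{child_structure.node_label}"
    child_ids = set(child_structure.exon_ids)
    succ = {a.exon_id: b.exon_id
            for a, b in zip(child_structure.exons, child_structure.exons[1:])}
    stages: List[Stage] = []

    structural = Stage(scope=scope, index=0, kind="structural", budget=None,
                       sources=[t.tid for t in parent_transcripts])
    survivors: List[Transcript] = []
    for t in parent_transcripts:
        intact = (all(e in child_ids for e in t.exon_ids)
                  and all(succ.get(a) == b for a, b in t.retained))
        if intact:
            survivors.append(t)
        else:
            structural.events.append(("structural_loss", t.tid, None))
    stages.append(structural)

    n_tl = min(event_budget(len(survivors), config.tc_tl, config.k_tc,
                            branch_length), len(survivors))
    tl_stage = Stage(scope=scope, index=1, kind="tl", budget=n_tl,
                     sources=[t.tid for t in survivors])
    if n_tl:
        victims = rng.choice(len(survivors), size=n_tl, replace=False)
        victim_set = {survivors[int(i)].tid for i in victims}
        tl_stage.events = [("tl", tid, None) for tid in sorted(victim_set)]
        survivors = [t for t in survivors if t.tid not in victim_set]
    stages.append(tl_stage)

    conserved_stage = Stage(scope=scope, index=2, kind="conserved", budget=None,
                            sources=[t.tid for t in survivors])
    transcripts: List[Transcript] = []
    for t in survivors:
        child_t = Transcript(tid=alloc.next(),
                             node_label=child_structure.node_label,
                             exon_ids=t.exon_ids, offsets=dict(t.offsets),
                             retained=t.retained, provenance=t.tid)
        transcripts.append(child_t)
        conserved_stage.events.append(("conserved", t.tid, child_t.tid))
    stages.append(conserved_stage)

    m = len(child_structure.exons)
    n_rs = event_budget(len(transcripts), config.tc_rs, config.k_tc, branch_length)
    rs_stage = Stage(scope=scope, index=3, kind="rs", budget=n_rs,
                     sources=[t.tid for t in transcripts])
    if n_rs:
        plain = {transcript_mask(child_structure, t) for t in transcripts
                 if not any(v != (0, 0) for v in t.offsets.values())
                 and not t.retained}
        masks = sample_isoform_masks(m, n_rs, rng, exclude=plain)
        rs_stage.shortfall = n_rs - len(masks)
        for mask in masks:
            t = transcript_from_mask(child_structure, mask, alloc.next())
            transcripts.append(t)
            rs_stage.events.append(("rs", None, t.tid))
    stages.append(rs_stage)

    for i, kind in enumerate(config.stage_order, start=4):
        budget = event_budget(len(transcripts), config.proportion(kind),
                              config.k_tc, branch_length)
        stages.append(run_as_stage(transcripts, kind, budget, child_structure,
                                   config, rng, alloc, scope=scope, index=i))
    return transcripts, stages
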