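"""Homology columns and the true multiple sequence alignment.

Every nucleotide position ever simulated is assigned a globally unique
*column token* when it first appears (root gene, insertion, exon gain or
duplication).  Tokens are kept in one master order; descendants inherit
their parent's tokens, deletions simply drop tokens from the child (the
master keeps them for the other rows), and new tokens are spliced into
the master between their neighbours.  A row of the true alignment is
then just a sequence scattered over the master columns it owns — the
alignment is exact by construction, not estimated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .sequences import SequenceEvent


class AlignmentIntegrityError(ValueError):
    """Sequences and column records disagree (corrupt event threading)."""


class ColumnSystem:
    """Allocator and global ordering of homology-column tokens."""

    def __init__(self) -> None:
        self.order: List[int] = []
        self.origin: Dict[int, str] = {}
        self._next = 0

    def __len__(self) -> int:
        return len(self.order)

    def _fresh(self, k: int, origin: str) -> List[int]:
        toks = list(range(self._next, self._next + k))
        self._next += k
        for t in toks:
            self.origin[t] = origin
        return toks

    def append_block(self, k: int, origin: str) -> List[int]:
        toks = self._fresh(k, origin)
        self.order.extend(toks)
        return toks

    def adopt(self, cols: Iterable[int], origin: str = "adopted") -> None:
        """Register tokens allocated elsewhere (in their given order)."""
        cols = list(cols)
        for t in cols:
            if t not in self.origin:
                self.origin[t] = origin
        self.order.extend(t for t in cols if t not in set(self.order))
        if cols:
            self._next = max(self._next, max(cols) + 1)

    def insert_before(self, anchor: int, k: int, origin: str) -> List[int]:
        toks = self._fresh(k, origin)
        i = self.order.index(anchor)
        self.order[i:i] = toks
        return toks

    def insert_after(self, anchor: int, k: int, origin: str) -> List[int]:
        toks = self._fresh(k, origin)
        i = self.order.index(anchor) + 1
        self.order[i:i] = toks
        return toks

    def insert_into(self, cols: Sequence[int], pos: int, k: int,
                    origin: str) -> List[int]:
        """New tokens between ``cols[pos-1]`` and ``cols[pos]`` in the master."""
        if not cols:
            return self.append_block(k, origin)
        if pos == 0:
            return self.insert_before(cols[0], k, origin)
        return self.insert_after(cols[pos - 1], k, origin)

    def rank(self) -> Dict[int, int]:
        return {tok: i for i, tok in enumerate(self.order)}


def apply_events_to_columns(colsys: ColumnSystem, cols: List[int],
                            events: Sequence[SequenceEvent],
                            origin: str) -> List[int]:
    """Mirror a sequence event log onto a parallel column-token list."""
    cols = list(cols)
    for ev in events:
        if ev.kind == "sub":
            continue
        if ev.kind == "del":
            del cols[ev.pos:ev.pos + len(ev.old)]
        elif ev.kind == "ins":
            fresh = colsys.insert_into(cols, ev.pos, len(ev.new), origin)
            cols[ev.pos:ev.pos] = fresh
    return cols


@dataclass
class TrueAlignment:
    """The exact alignment implied by the simulation's event history."""

    ids: List[str]
    rows: List[str]
    columns: List[int]                 # master tokens, one per column
    origins: List[str]                 # provenance of each column

    def row(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def __len__(self) -> int:
        return len(self.columns)


def build_true_alignment(result, include_genes: bool = True,
                         include_transcripts: bool = True) -> TrueAlignment:
    """Assemble the true MSA of all gene and transcript sequences.

    Raises :class:`AlignmentIntegrityError` if any row's recorded
    columns are out of master order or disagree in length with its
    sequence — the signature of a corrupted event log.
    """
    from .transcripts import spliced_sequence  # local import avoids a cycle

    entries: List[Tuple[str, str, List[int]]] = []
    if include_genes:
        for label, st in result.structures.items():
            entries.append((f"gene|{label}", st.gene_sequence(), st.gene_cols()))
    if include_transcripts:
        for label, transcripts in result.transcripts.items():
            st = result.structures[label]
            for t in transcripts:
                seq, cols = spliced_sequence(t, st)
                entries.append((t.tid, seq, cols))

    rank = result.colsys.rank()
    used = set()
    for rid, seq, cols in entries:
        if len(seq) != len(cols):
            raise AlignmentIntegrityError(
                f"row {rid}: sequence length {len(seq)} != {len(cols)} columns")
        if any(rank[a] >= rank[b] for a, b in zip(cols, cols[1:])):
            raise AlignmentIntegrityError(f"row {rid}: columns out of master order")
        used.update(cols)

    columns = [tok for tok in result.colsys.order if tok in used]
    index = {tok: i for i, tok in enumerate(columns)}
    rows: List[str] = []
    for rid, seq, cols in entries:
        row = ["-"] * len(columns)
        for nt, tok in zip(seq, cols):
            row[index[tok]] = nt
        rows.append("".join(row))

    aln = TrueAlignment(
        ids=[e[0] for e in entries],
        rows=rows,
        columns=columns,
        origins=[result.colsys.origin[tok] for tok in columns],
    )
    for (rid, seq, _), row in zip(entries, aln.rows):
        if row.replace("-", "") != seq:
            raise AlignmentIntegrityError(f"row {rid}: ungapped row != sequence")
    return aln
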