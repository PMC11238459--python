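"""Serialization of every simulated artifact.

Files written by :func:`write_outputs` (all plain text):

========================================  =====================================
file                                      content
========================================  =====================================
``gene_sequences_leaves.fasta``           unspliced gene sequences of the
                                          guide tree's leaf genes
``transcript_sequences.fasta``            transcript CDS at every node
``exon_coordinates_genes.tsv``            exon locations on each gene
``transcript_segments.tsv``               CDS pieces of each transcript on its
                                          gene and on the transcript itself
``transcript_forest.nhx``                 one Newick tree per line; edges
                                          carry ``[&&NHX:event=...]`` labels
``true_alignment.fasta``                  the exact MSA of all gene and
                                          transcript sequences
``events.tsv``                            unified event log
``ortholog_groups.tsv``                   one group per line, tab-separated
========================================  =====================================

All coordinates are 0-based, half-open, as stated in each header line.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import dendropy
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .alignment import build_true_alignment
from .forest import TranscriptForest
from .orthology import ortholog_groups
from .simulate import SimulationResult
from .transcripts import spliced_segments

_COORD_HEADER = "# coordinates are 0-based, half-open\n"


def _records(pairs: Sequence[Tuple[str, str]], description: str = ""):
    return [SeqRecord(Seq(s), id=i, description=description) for i, s in pairs]


# ---------------------------------------------------------------------------
# Forest <-> Newick/NHX
# ---------------------------------------------------------------------------

def forest_to_newick(forest: TranscriptForest) -> List[str]:
    """One Newick string per transcript tree, edges NHX-labeled."""

    def render(tid: str) -> str:
        label = f"'{tid}'"
        kids = forest.children(tid)
        if not kids:
            return label
        inner = ",".join(
            render(k) + f":1.0[&&NHX:event={forest.edge_event(tid, k)}]"
            for k in kids)
        return f"({inner}){label}"

    return [render(root) + ";" for root in sorted(forest.roots())]


_NHX_EDGE = re.compile(r"'([^']+)':[0-9.]+\[&&NHX:event=(\w+)\]")


def read_forest_newick(lines: Sequence[str]) -> TranscriptForest:
    """Re-parse forest Newick lines (topology via dendropy, NHX via tags).

    Gene labels are recovered from the ``gene#k`` id convention.
    """
    forest = TranscriptForest()
    for line in lines:
        line = line.strip()
        if not line:
            continue
        tree = dendropy.Tree.get(data=line, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        events = dict(_NHX_EDGE.findall(line))

        def walk(dnode, parent_tid):
            label = (dnode.taxon.label if dnode.taxon is not None
                     else dnode.label)
            forest.add_transcript(label, label.rsplit("#", 1)[0])
            if parent_tid is not None:
                forest.add_edge(parent_tid, label, events[label])
            for child in dnode.child_nodes():
                walk(child, label)

        walk(tree.seed_node, None)
    return forest


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def gene_exon_table(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for label, st in result.structures.items():
        pos = 0
        for kind, el in st.elements():
            if kind == "exon":
                rows.append({"node": label, "exon_id": el.exon_id,
                             "start": pos, "end": pos + len(el.seq),
                             "strand": "+"})
            pos += len(el.seq)
    return pd.DataFrame(rows)


def transcript_segment_table(result: SimulationResult) -> pd.DataFrame:
    """Each CDS piece located on the gene and on the transcript."""
    rows = []
    for label, transcripts in result.transcripts.items():
        st = result.structures[label]
        gene_pos = {tok: i for i, tok in enumerate(st.gene_cols())}
        for t in transcripts:
            tx_pos = 0
            for seg_label, seq, cols in spliced_segments(t, st):
                rows.append({
                    "transcript_id": t.tid, "node": label, "segment": seg_label,
                    "gene_start": gene_pos[cols[0]],
                    "gene_end": gene_pos[cols[-1]] + 1,
                    "tx_start": tx_pos, "tx_end": tx_pos + len(seq),
                })
                tx_pos += len(seq)
    return pd.DataFrame(rows)


def events_table(result: SimulationResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": e.category, "node": e.node, "branch": e.branch,
        "stage": e.stage, "event_type": e.event_type,
        "source_id": e.source_id, "sink_id": e.sink_id, "payload": e.payload,
    } for e in result.events])


# ---------------------------------------------------------------------------
# Main writer
# ---------------------------------------------------------------------------

def write_outputs(result: SimulationResult, outdir: str,
                  alignment: bool = True) -> Dict[str, Path]:
    """Write every output file; returns name -> path."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir!r} is not writable: {exc}")

    paths: Dict[str, Path] = {}

    leaf_labels = [l.label for l in result.tree.leaves]
    p = out / "gene_sequences_leaves.fasta"
    seqio_write(_records([(f"gene|{l}", result.structures[l].gene_sequence())
                          for l in leaf_labels]), str(p), "fasta")
    paths["genes"] = p

    pairs = []
    for label in result.structures:
        st = result.structures[label]
        for t in result.transcripts[label]:
            from .transcripts import spliced_sequence
            pairs.append((t.tid, spliced_sequence(t, st)[0]))
    p = out / "transcript_sequences.fasta"
    seqio_write(_records(pairs), str(p), "fasta")
    paths["transcripts"] = p

    p = out / "exon_coordinates_genes.tsv"
    with open(p, "w") as fh:
        fh.write(_COORD_HEADER)
        gene_exon_table(result).to_csv(fh, sep="\t", index=False)
    paths["gene_coords"] = p

    p = out / "transcript_segments.tsv"
    with open(p, "w") as fh:
        fh.write(_COORD_HEADER)
        transcript_segment_table(result).to_csv(fh, sep="\t", index=False)
    paths["transcript_coords"] = p

    p = out / "transcript_forest.nhx"
    p.write_text("\n".join(forest_to_newick(result.forest)) + "\n")
    paths["forest"] = p

    if alignment:
        aln = build_true_alignment(result)
        p = out / "true_alignment.fasta"
        seqio_write(_records(list(zip(aln.ids, aln.rows))), str(p), "fasta")
        paths["alignment"] = p

    p = out / "events.tsv"
    events_table(result).to_csv(p, sep="\t", index=False)
    paths["events"] = p

    p = out / "ortholog_groups.tsv"
    groups = ortholog_groups(result.forest, leaf_labels)
    with open(p, "w") as fh:
        for g in groups:
            fh.write("\t".join(sorted(g)) + "\n")
    paths["orthologs"] = p

    return paths
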