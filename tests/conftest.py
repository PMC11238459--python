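"""Shared fixtures: compact configurations and a hand-built ancestral
gene scenario (four exons, seven transcripts) used across test modules."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from splicesim import (ColumnSystem, Exon, GeneStructure, Intron,
                      SimulationConfig, Transcript, TranscriptForest)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small gene dimensions so simulations stay fast in tests."""
    return SimulationConfig(
        seed=0, k_tc=1.5, tc_rs=0.4,
        exon_count_mean=4, exon_count_sd=1,
        exon_length_mean=30, exon_length_sd=9,
        intron_length_mean=16, intron_length_sd=5,
    )


def make_structure(label, n_exons, exon_len=6, intron_len=6, ids=None):
    """Hand-built structure with deterministic sequences and fresh columns."""
    colsys = ColumnSystem()
    ids = ids or [f"exon{i + 1}" for i in range(n_exons)]
    exons, introns = [], []
    for j in range(n_exons):
        seq = ("ATGGCCAAGGCC" * ((exon_len // 12) + 1))[:exon_len]
        exons.append(Exon(ids[j], seq, colsys.append_block(exon_len, f"{label}:e{j}")))
        if j < n_exons - 1:
            iseq = "GT" + "T" * (intron_len - 4) + "AG"
            introns.append(Intron(iseq, colsys.append_block(intron_len,
                                                           f"{label}:i{j}")))
    return GeneStructure(label, exons, introns).validate()


@pytest.fixture
def ancestral_scenario():
    """An ancestral gene with exons 1-4 and seven transcripts.

    Transcripts 2-6 contain exon4; 1 and 7 do not.  Losing exon4 on a
    branch must therefore kill exactly five transcripts and conserve
    two — the worked example of a structural-loss cascade.
    """
    parent = make_structure("Gene1", 4)
    child = make_structure("Gene2", 3, ids=["exon1", "exon2", "exon3"])
    mk = lambda k, ids, **kw: Transcript(tid=f"Gene1#{k}", node_label="Gene1",
                                         exon_ids=tuple(ids), **kw)
    transcripts = [
        mk(1, ["exon1", "exon2", "exon3"]),
        mk(2, ["exon1", "exon2", "exon3", "exon4"]),
        mk(3, ["exon1", "exon2", "exon4"]),
        mk(4, ["exon2", "exon4"]),
        mk(5, ["exon1", "exon4"]),
        mk(6, ["exon1", "exon2", "exon4"], offsets={"exon4": (3, 0)}),
        mk(7, ["exon2", "exon3"]),
    ]
    return parent, child, transcripts


@pytest.fixture
def ancestral_forest(ancestral_scenario):
    """The transcript phylogeny implied by the ancestral-gene scenario.

    Roots Gene1#1 and Gene1#2 were gained; the rest derive by AS events;
    Gene1#1 alone is conserved into both extant genes (as Gene2#1 and
    Gene3#1), Gene1#7 is conserved then regulatorily lost, and every
    exon4-carrying transcript dies with the exon on the Gene1->Gene2
    branch.
    """
    _, _, transcripts = ancestral_scenario
    forest = TranscriptForest()
    for t in transcripts:
        forest.add_transcript(t.tid, "Gene1")
    forest.add_edge("Gene1#2", "Gene1#3", "es")
    forest.add_edge("Gene1#3", "Gene1#6", "a3")
    forest.add_edge("Gene1#1", "Gene1#4", "me")
    forest.add_edge("Gene1#1", "Gene1#5", "ir")
    forest.add_edge("Gene1#1", "Gene1#7", "es")
    for leaf, tid in (("Gene2", "Gene2#1"), ("Gene3", "Gene3#1")):
        forest.add_transcript(tid, leaf)
        forest.add_edge("Gene1#1", tid, "conserved")
    for lost in ("Gene1#2", "Gene1#3", "Gene1#4", "Gene1#5", "Gene1#6"):
        forest.mark_lost(lost, "Gene1->Gene2", "structural_loss")
    forest.mark_lost("Gene1#7", "Gene1->Gene2", "tl")
    # an extra AS-derived isoform at each leaf: not orthologous to anything
    forest.add_transcript("Gene2#2", "Gene2")
    forest.add_edge("Gene2#1", "Gene2#2", "es")
    forest.add_transcript("Gene3#2", "Gene3")
    forest.add_edge("Gene3#1", "Gene3#2", "a5")
    return forest.validate()
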