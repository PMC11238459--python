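"""True alignment assembly and output-file serialization."""
import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from splicesim import (SimulationConfig, build_true_alignment, simulate,
                      spliced_sequence)
from splicesim.outputs import (forest_to_newick, read_forest_newick,
                               write_outputs)


@pytest.fixture(scope="module")
def result():
    cfg = SimulationConfig(seed=8, k_tc=1.5, tc_rs=0.4, exon_count=4,
                           exon_length_mean=30, exon_length_sd=9,
                           intron_length_mean=16, intron_length_sd=5)
    return simulate("((A:0.2,B:0.3)AB:0.15,C:0.25);", cfg)


@pytest.fixture(scope="module")
def outdir(result, tmp_path_factory):
    path = tmp_path_factory.mktemp("sim_out")
    write_outputs(result, str(path))
    return path


class TestTrueAlignment:
    def test_zero_branch_alignment_is_gapless_copy(self):
        cfg = SimulationConfig(seed=1, exon_count=3, tc_rs=0, tc_tl=0,
                               tc_es=0, tc_me=0, tc_a5=0, tc_a3=0, tc_ir=0,
                               exon_length_mean=30, intron_length_mean=16)
        r = simulate("(A:0.0);", cfg)
        aln = build_true_alignment(r, include_transcripts=False)
        assert len(set(aln.rows)) == 1 and "-" not in aln.rows[0]

    def test_skipped_exon_is_an_all_gap_block(self):
        """An es event leaves the skipped exon's columns fully gapped."""
        cfg = SimulationConfig(seed=3, exon_count=3, tc_rs=0, tc_tl=0,
                               tc_es=1.0, tc_me=0, tc_a5=0, tc_a3=0, tc_ir=0,
                               stage_order=("es",), exon_length_mean=30,
                               intron_length_mean=16)
        r = simulate("(A:0.0);", cfg)
        root = r.tree.root.label
        full = next(t for t in r.transcripts[root] if len(t.exon_ids) == 3)
        skipped = next(t for t in r.transcripts[root] if len(t.exon_ids) == 2)
        missing = (set(full.exon_ids) - set(skipped.exon_ids)).pop()
        aln = build_true_alignment(r)
        exon = next(e for e in r.structures[root].exons
                    if e.exon_id == missing)
        col_of = {tok: i for i, tok in enumerate(aln.columns)}
        row = aln.row(skipped.tid)
        block = [row[col_of[tok]] for tok in exon.cols]
        assert set(block) == {"-"}
        full_row = aln.row(full.tid)
        assert all(full_row[col_of[tok]] != "-" for tok in exon.cols)

    def test_every_row_ungaps_to_its_sequence(self, result):
        aln = build_true_alignment(result)
        for label, st in result.structures.items():
            assert aln.ungapped(f"gene|{label}") == st.gene_sequence()
        for label, ts in result.transcripts.items():
            st = result.structures[label]
            for t in ts:
                assert aln.ungapped(t.tid) == spliced_sequence(t, st)[0]

    def test_column_origins_recorded(self, result):
        aln = build_true_alignment(result)
        assert len(aln.origins) == len(aln.columns)
        assert any(o.startswith("root") for o in aln.origins)


class TestOutputFiles:
    def test_all_files_written(self, outdir):
        names = {p.name for p in outdir.iterdir()}
        assert names >= {"gene_sequences_leaves.fasta",
                         "transcript_sequences.fasta",
                         "exon_coordinates_genes.tsv",
                         "transcript_segments.tsv", "transcript_forest.nhx",
                         "true_alignment.fasta", "events.tsv",
                         "ortholog_groups.tsv"}

    def test_leaf_gene_fasta_roundtrip(self, result, outdir):
        recs = {r.id: str(r.seq) for r in
                SeqIO.parse(outdir / "gene_sequences_leaves.fasta", "fasta")}
        assert set(recs) == {"gene|A", "gene|B", "gene|C"}
        for leaf in ("A", "B", "C"):
            assert recs[f"gene|{leaf}"] \
                == result.structures[leaf].gene_sequence()

    def test_transcript_fasta_lengths_multiple_of_three(self, outdir):
        recs = list(SeqIO.parse(outdir / "transcript_sequences.fasta", "fasta"))
        assert recs and all(len(r.seq) % 3 == 0 for r in recs)

    def test_forest_newick_roundtrip(self, result, outdir):
        lines = (outdir / "transcript_forest.nhx").read_text().splitlines()
        forest = read_forest_newick(lines)
        assert set(forest.graph.nodes) == set(result.forest.graph.nodes)
        assert {(a, b, d["event"]) for a, b, d in
                forest.graph.edges(data=True)} \
            == {(a, b, d["event"]) for a, b, d in
                result.forest.graph.edges(data=True)}

    def test_coordinate_slicing_rebuilds_cds(self, result, outdir):
        """Gene-coordinate segments re-concatenate to each transcript CDS."""
        # skiprows, not comment='#': transcript ids contain '#'
        seg = pd.read_csv(outdir / "transcript_segments.tsv", sep="\t",
                          skiprows=1)
        genes = {label: st.gene_sequence()
                 for label, st in result.structures.items()}
        for label, ts in result.transcripts.items():
            for t in ts:
                rows = seg[seg.transcript_id == t.tid]
                rebuilt = "".join(genes[label][r.gene_start:r.gene_end]
                                  for r in rows.itertuples())
                assert rebuilt == spliced_sequence(
                    t, result.structures[label])[0]

    def test_event_log_and_groups_consistent_ids(self, result, outdir):
        ev = pd.read_csv(outdir / "events.tsv", sep="\t",
                         keep_default_na=False)
        known = set(result.forest.graph.nodes)
        tx = ev[ev.category == "transcript"]
        sinks = {s for s in tx.sink_id if s}
        assert sinks <= known
        for line in (outdir / "ortholog_groups.tsv").read_text().splitlines():
            for tid in line.split("\t"):
                assert tid in known

    def test_alignment_fasta_rows_equal_width(self, outdir):
        recs = list(SeqIO.parse(outdir / "true_alignment.fasta", "fasta"))
        widths = {len(r.seq) for r in recs}
        assert len(widths) == 1

    def test_forest_leaves_are_extant_transcripts(self, result):
        leaf_genes = {l.label for l in result.tree.leaves}
        at_leaves = {t for t in result.forest.graph.nodes
                     if result.forest.gene_of(t) in leaf_genes}
        assert at_leaves == {t.tid for t in result.leaf_transcripts()}
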