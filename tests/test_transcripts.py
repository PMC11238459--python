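"""Transcript-set evolution: pools, AS events, stages, propagation."""
import numpy as np
import pytest
from scipy import stats

from splicesim import (IdAllocator, Inapplicable, SimulationConfig, Transcript,
                      apply_as_event, isoform_pool_size, propagate_transcripts,
                      raw_root_transcript_draws, root_event_budget,
                      sample_isoform_masks, sample_root_transcript_count,
                      simulate, simulate_root_transcripts, spliced_sequence,
                      transcript_from_mask)
from conftest import make_structure


@pytest.fixture
def alloc():
    return IdAllocator("G", start=10)


class TestPool:
    @pytest.mark.parametrize("m,expected", [(1, 1), (3, 7), (10, 1023)])
    def test_isoform_pool_size(self, m, expected):
        assert isoform_pool_size(m) == expected
        if m <= 10:  # brute-force enumeration oracle
            assert expected == sum(
                1 for mask in range(1, 2 ** m) if mask)

    def test_pool_size_rejects_zero(self):
        with pytest.raises(ValueError):
            isoform_pool_size(0)

    def test_uniform_sampling_chi_square(self):
        """Single draws from the m=3 pool are uniform over all 7 isoforms."""
        rng = np.random.default_rng(11)
        counts = np.zeros(7)
        for _ in range(10_000):
            counts[sample_isoform_masks(3, 1, rng)[0] - 1] += 1
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_sampling_without_replacement_and_clamp(self, rng):
        masks = sample_isoform_masks(3, 50, rng)
        assert sorted(masks) == list(range(1, 8))
        assert sample_isoform_masks(3, 3, rng, exclude={1, 2, 3, 4, 5, 6}) == [7]

    def test_root_count_clamped_to_one(self):
        rng = np.random.default_rng(0)
        assert all(sample_root_transcript_count(rng) >= 1 for _ in range(2000))

    def test_raw_draw_law(self):
        draws = raw_root_transcript_draws(np.random.default_rng(3), 100_000)
        assert abs(draws.mean() - 1.45) < 0.02
        assert abs(draws.std(ddof=1) - 1.08) < 0.02


class TestASEvents:
    def setup_method(self):
        self.structure = make_structure("G", 4, exon_len=12, intron_len=12)
        self.t = Transcript("G#1", "G", ("exon1", "exon2", "exon3", "exon4"))

    def test_es_removes_one_exon(self, rng, alloc):
        out = apply_as_event(self.t, "es", self.structure, rng, alloc)
        assert len(out.exon_ids) == 3
        assert set(out.exon_ids) < set(self.t.exon_ids)
        assert out.provenance == "G#1" and out.tid == "G#10"

    def test_es_single_exon_inapplicable(self, rng, alloc):
        t = Transcript("G#1", "G", ("exon2",))
        with pytest.raises(Inapplicable):
            apply_as_event(t, "es", self.structure, rng, alloc)

    def test_me_swaps_absent_exon(self, rng, alloc):
        t = Transcript("G#1", "G", ("exon1", "exon3"))
        out = apply_as_event(t, "me", self.structure, rng, alloc)
        assert len(out.exon_ids) == 2
        assert set(out.exon_ids) != {"exon1", "exon3"}
        assert len(set(out.exon_ids) & {"exon2", "exon4"}) == 1
        # structure order preserved
        order = [e.exon_id for e in self.structure.exons]
        assert list(out.exon_ids) == [e for e in order if e in out.exon_ids]

    def test_me_full_transcript_inapplicable(self, rng, alloc):
        with pytest.raises(Inapplicable):
            apply_as_event(self.t, "me", self.structure, rng, alloc)

    @pytest.mark.parametrize("kind,side", [("a5", 1), ("a3", 0)])
    def test_boundary_shift_offsets(self, kind, side, rng, alloc):
        out = apply_as_event(self.t, kind, self.structure, rng, alloc)
        assert out.exon_ids == self.t.exon_ids
        changed = [(e, o) for e, o in out.offsets.items() if o != (0, 0)]
        assert len(changed) == 1
        off = changed[0][1][side]
        assert off != 0 and off % 3 == 0
        seq, _ = spliced_sequence(out, self.structure)
        assert len(seq) % 3 == 0

    def test_ir_retains_adjacent_junction(self, rng, alloc):
        out = apply_as_event(self.t, "ir", self.structure, rng, alloc)
        assert len(out.retained) == 1
        (a, b), = out.retained
        ia = self.structure.exon_index(a)
        assert self.structure.exons[ia + 1].exon_id == b
        seq, _ = spliced_sequence(out, self.structure)
        base, _ = spliced_sequence(self.t, self.structure)
        assert len(seq) > len(base) and len(seq) % 3 == 0

    def test_ir_without_adjacent_junction_inapplicable(self, rng, alloc):
        t = Transcript("G#1", "G", ("exon1", "exon3"))  # non-adjacent
        with pytest.raises(Inapplicable):
            apply_as_event(t, "ir", self.structure, rng, alloc)

    def test_chained_events_accumulate(self, rng, alloc):
        """es then a3 produces a transcript differing by both records."""
        t4 = Transcript("G#2", "G", ("exon1", "exon2", "exon3", "exon4"))
        after_es = apply_as_event(t4, "es", self.structure, rng, alloc)
        after_a3 = apply_as_event(after_es, "a3", self.structure, rng, alloc)
        assert after_a3.exon_ids == after_es.exon_ids
        assert after_a3.provenance == after_es.tid
        assert any(o != (0, 0) for o in after_a3.offsets.values())


class TestRootSimulation:
    def test_null_tc_rs_selects_full_transcript(self, rng):
        st = make_structure("R", 3)
        cfg = SimulationConfig(tc_rs=0, tc_es=0, tc_me=0, tc_a5=0, tc_a3=0,
                               tc_ir=0, tc_tl=0)
        ts, stages = simulate_root_transcripts(st, cfg, rng)
        assert len(ts) == 1
        assert ts[0].exon_ids == ("exon1", "exon2", "exon3")
        assert all(not s.events for s in stages[1:])

    def test_es_stage_grows_two_sources_to_three(self, rng):
        """ceil(2 * 0.3) = 1 es event; the next stage sees 3 sources."""
        st = make_structure("R", 4)
        cfg = SimulationConfig(tc_rs=1.0, root_transcript_count=2,
                               tc_es=0.3, tc_me=0, tc_a5=0, tc_a3=0, tc_ir=0,
                               tc_tl=0, stage_order=("es", "me"))
        for seed in range(10):
            ts, stages = simulate_root_transcripts(
                st, cfg, np.random.default_rng(seed))
            es_stage = next(s for s in stages if s.kind == "es")
            if es_stage.shortfall:     # both drawn isoforms single-exon
                continue
            assert es_stage.budget == root_event_budget(2, 0.3) == 1
            assert len(es_stage.sources) == 2
            me_stage = next(s for s in stages if s.kind == "me")
            assert len(me_stage.sources) == 3
            assert len(ts) >= 3
            return
        pytest.fail("es stage never applicable across seeds")

    def test_budgets_recorded_per_stage(self, rng):
        st = make_structure("R", 5)
        cfg = SimulationConfig(root_transcript_count=3)
        ts, stages = simulate_root_transcripts(st, cfg, rng)
        for s in stages[1:]:
            assert s.budget == root_event_budget(len(s.sources),
                                                 cfg.proportion(s.kind))
            assert len(s.events) + s.shortfall == s.budget


class TestPropagation:
    def test_structural_loss_cascade(self, ancestral_scenario, rng):
        """Losing exon4 kills the five exon4 transcripts, conserves two."""
        parent, child, transcripts = ancestral_scenario
        cfg = SimulationConfig(tc_rs=0, tc_tl=0, tc_es=0, tc_me=0, tc_a5=0,
                               tc_a3=0, tc_ir=0)
        out, stages = propagate_transcripts(transcripts, parent, child, 1.0,
                                            cfg, rng)
        structural = next(s for s in stages if s.kind == "structural")
        lost = {src for _, src, _ in structural.events}
        assert lost == {"Gene1#2", "Gene1#3", "Gene1#4", "Gene1#5", "Gene1#6"}
        conserved = next(s for s in stages if s.kind == "conserved")
        assert {src for _, src, _ in conserved.events} == {"Gene1#1", "Gene1#7"}
        assert [t.provenance for t in out] == ["Gene1#1", "Gene1#7"]

    def test_regulated_loss_removes_conserved_transcript(self,
                                                         ancestral_scenario,
                                                         rng):
        parent, child, transcripts = ancestral_scenario
        cfg = SimulationConfig(tc_rs=0, tc_tl=0.1, k_tc=1.0, tc_es=0, tc_me=0,
                               tc_a5=0, tc_a3=0, tc_ir=0)
        # tl budget = ceil(1 * 1.0 * 2 * 0.1) = 1 of the two survivors
        out, stages = propagate_transcripts(transcripts, parent, child, 1.0,
                                            cfg, rng)
        tl = next(s for s in stages if s.kind == "tl")
        assert len(tl.events) == 1
        assert tl.events[0][1] in {"Gene1#1", "Gene1#7"}
        assert len(out) == 1

    def test_disrupted_retention_is_structural_loss(self, rng):
        """A retained intron whose junction gains an exon dies structurally."""
        parent = make_structure("P", 3)
        child = make_structure("C", 4, ids=["exon1", "exon9", "exon2", "exon3"])
        t = Transcript("P#1", "P", ("exon1", "exon2"),
                       retained=frozenset({("exon1", "exon2")}))
        cfg = SimulationConfig(tc_rs=0, tc_tl=0, tc_es=0, tc_me=0, tc_a5=0,
                               tc_a3=0, tc_ir=0)
        out, stages = propagate_transcripts([t], parent, child, 0.5, cfg, rng)
        structural = next(s for s in stages if s.kind == "structural")
        assert [e[1] for e in structural.events] == ["P#1"]
        assert out == []

    def test_gains_become_new_roots(self, rng):
        parent = make_structure("P", 3)
        child = make_structure("C", 3)
        t = Transcript("P#1", "P", ("exon1", "exon2", "exon3"))
        cfg = SimulationConfig(tc_rs=1.0, k_tc=2.0, tc_tl=0, tc_es=0, tc_me=0,
                               tc_a5=0, tc_a3=0, tc_ir=0)
        out, stages = propagate_transcripts([t], parent, child, 1.0, cfg, rng)
        rs = next(s for s in stages if s.kind == "rs")
        assert rs.budget == 2 and len(rs.events) == 2
        assert all(src is None for _, src, _ in rs.events)
        # the full-exon isoform is already present: gains must differ
        sigs = {tuple(x.exon_ids) for x in out}
        assert len(sigs) == len(out)


class TestSimulateDriver:
    def test_single_leaf_zero_branch_identity(self):
        cfg = SimulationConfig(seed=4, exon_count=3, tc_rs=0, tc_tl=0, tc_es=0,
                               tc_me=0, tc_a5=0, tc_a3=0, tc_ir=0,
                               exon_length_mean=30, intron_length_mean=16)
        result = simulate("(A:0.0);", cfg)
        root_label = result.tree.root.label
        assert len(result.transcripts[root_label]) == 1
        assert len(result.transcripts["A"]) == 1
        root_t = result.transcripts[root_label][0]
        leaf_t = result.transcripts["A"][0]
        assert leaf_t.exon_ids == root_t.exon_ids
        assert result.forest.edge_event(root_t.tid, leaf_t.tid) == "conserved"
        rs, cs = result.structures[root_label], result.structures["A"]
        assert rs.gene_sequence() == cs.gene_sequence()

    def test_same_seed_byte_identical(self, small_config):
        tree = "((A:0.2,B:0.3):0.1,C:0.25);"
        r1 = simulate(tree, small_config)
        r2 = simulate(tree, small_config)
        assert [(e.category, e.event_type, e.source_id, e.sink_id, e.payload)
                for e in r1.events] \
            == [(e.category, e.event_type, e.source_id, e.sink_id, e.payload)
                for e in r2.events]
        for label in r1.structures:
            assert r1.structures[label].gene_sequence() \
                == r2.structures[label].gene_sequence()
            assert [t.signature() for t in r1.transcripts[label]] \
                == [t.signature() for t in r2.transcripts[label]]

    def test_transcript_ids_follow_gene_labels(self, small_config):
        result = simulate("((A:0.2,B:0.3):0.1,C:0.25);", small_config)
        for label, ts in result.transcripts.items():
            assert all(t.tid.startswith(f"{label}#") for t in ts)
            assert len({t.tid for t in ts}) == len(ts)
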