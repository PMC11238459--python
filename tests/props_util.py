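"""Shared invariant checks run on full simulations (the property suite).

Each helper asserts one model invariant on a finished simulation:
Dollo parsimony of exon presence, forest shape, budget bookkeeping,
mod-3 coding constraints, replay oracles for structure and sequence
logs, alignment consistency and forest Newick round-trips.
"""
from __future__ import annotations

from typing import List

import numpy as np

from splicesim import (SimulationConfig, build_true_alignment, event_budget,
                      replay_sequence, replay_structure, root_event_budget,
                      simulate, spliced_sequence, structures_equal)
from splicesim.outputs import forest_to_newick, read_forest_newick


def random_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary tree with U(0.05, 0.35) branch lengths."""
    labels = [f"L{i + 1}" for i in range(n_leaves)]

    def build(names: List[str]) -> str:
        if len(names) == 1:
            return names[0]
        cut = int(rng.integers(1, len(names)))
        bl = lambda: rng.uniform(0.05, 0.35)
        return (f"({build(names[:cut])}:{bl():.3f},"
                f"{build(names[cut:])}:{bl():.3f})")

    if n_leaves == 1:
        return f"({labels[0]}:{rng.uniform(0.05, 0.35):.3f});"
    return build(labels) + ";"


def property_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, k_tc=1.5, tc_rs=0.4,
        exon_count_mean=4, exon_count_sd=1,
        exon_length_mean=30, exon_length_sd=9,
        intron_length_mean=16, intron_length_sd=5,
    )


def run_simulation(seed: int):
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(3, 9))
    return simulate(random_tree(rng, n_leaves), property_config(seed))


# ---------------------------------------------------------------------------
# Individual invariants
# ---------------------------------------------------------------------------

def check_dollo(result) -> None:
    """Exon presence on every root-to-leaf path is one contiguous interval."""
    def paths(node, prefix):
        prefix = prefix + [node.label]
        if node.is_leaf:
            yield prefix
        for c in node.children:
            yield from paths(c, prefix)

    for path in paths(result.tree.root, []):
        presence = [set(result.structures[l].exon_ids) for l in path]
        all_ids = set().union(*presence)
        for eid in all_ids:
            flags = [eid in s for s in presence]
            first, last = flags.index(True), len(flags) - 1 - flags[::-1].index(True)
            assert all(flags[first:last + 1]), \
                f"exon {eid} regained on path {path}"


def check_forest_shape(result) -> None:
    """In-degree <= 1, acyclic, roots are gains, stage sinks are unique."""
    result.forest.validate()
    gained = {sink for st in result.stages for etype, src, sink in st.events
              if etype == "rs"}
    assert set(result.forest.roots()) == gained
    for st in result.stages:
        sinks = [s for _, _, s in st.events if s is not None]
        assert len(sinks) == len(set(sinks)), "a stage produced a sink twice"


def check_no_root_losses(result) -> None:
    root = result.tree.root.label
    for st in result.stages:
        if st.scope == root:
            assert not any(e in ("tl", "structural_loss")
                           for e, _, _ in st.events)


def check_budgets(result) -> None:
    """Recorded per-stage AS event counts match the recomputed budgets."""
    lengths = {f"{n.parent.label}->{n.label}": n.length
               for n in result.tree.nodes if not n.is_root}
    cfg = result.config
    for st in result.stages:
        if st.kind not in ("es", "me", "a5", "a3", "ir"):
            continue
        n = len(st.sources)
        p = cfg.proportion(st.kind)
        if st.scope in lengths:
            expected = event_budget(n, p, cfg.k_tc, lengths[st.scope])
        else:
            expected = root_event_budget(n, p)
        assert st.budget == expected, (st.scope, st.kind, st.budget, expected)
        assert len(st.events) + st.shortfall == st.budget


def check_mod3(result) -> None:
    """Exon, offset and spliced-CDS lengths are all multiples of 3."""
    for label, st in result.structures.items():
        for e in st.exons:
            assert len(e.seq) % 3 == 0
        for t in result.transcripts[label]:
            assert t.exon_ids, "empty transcript"
            order = [e for e in st.exon_ids if e in t.exon_ids]
            assert list(t.exon_ids) == order, "exon order violates structure"
            assert set(t.exon_ids) <= set(st.exon_ids)
            for off5, off3 in t.offsets.values():
                assert off5 % 3 == 0 and off3 % 3 == 0
            seq, cols = spliced_sequence(t, st)
            assert len(seq) % 3 == 0 and len(seq) >= 3
            assert len(seq) == len(cols)


def check_replays(result) -> None:
    """Structure and sequence logs rebuild every child state exactly."""
    for node in result.tree.nodes:
        if node.is_root:
            continue
        branch = f"{node.parent.label}->{node.label}"
        replayed = replay_structure(result.structures[node.parent.label],
                                    result.structure_events[branch])
        exon_seq = {e.exon_id: e.seq for e in replayed.exons}
        stored = result.structures[node.label]
        for label, old, events in result.sequence_logs[branch]:
            kind, _, key = label.partition(":")
            if kind == "exon":
                assert exon_seq[key] == old, "structure replay mismatch"
                final = {e.exon_id: e.seq for e in stored.exons}[key]
            else:
                assert replayed.introns[int(key)].seq == old
                final = stored.introns[int(key)].seq
            assert replay_sequence(old, events) == final
        assert structures_equal(
            replayed,
            replay_structure(result.structures[node.parent.label],
                             result.structure_events[branch]))


def check_alignment(result) -> None:
    """Constructing the true alignment runs its internal ungap oracle."""
    aln = build_true_alignment(result)
    n_rows = (len(result.structures)
              + sum(len(v) for v in result.transcripts.values()))
    assert len(aln.ids) == n_rows
    assert all(len(r) == len(aln.columns) for r in aln.rows)


def check_forest_newick_roundtrip(result) -> None:
    lines = forest_to_newick(result.forest)
    re_read = read_forest_newick(lines)
    assert set(re_read.graph.nodes) == set(result.forest.graph.nodes)
    original = {(a, b, d["event"])
                for a, b, d in result.forest.graph.edges(data=True)}
    recovered = {(a, b, d["event"])
                 for a, b, d in re_read.graph.edges(data=True)}
    assert original == recovered


FAST_CHECKS = (check_dollo, check_forest_shape, check_no_root_losses,
               check_budgets, check_mod3, check_replays)
HEAVY_CHECKS = (check_alignment, check_forest_newick_roundtrip)


def run_all_checks(seed: int, heavy: bool = False) -> None:
    result = run_simulation(seed)
    for check in FAST_CHECKS:
        check(result)
    if heavy:
        for check in HEAVY_CHECKS:
            check(result)
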