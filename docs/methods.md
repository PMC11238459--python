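# Methods

## Model overview

`splicesim` simulates the evolution of one gene family along a rooted
guide tree whose branch lengths `c_s_r` are expected substitutions per
site. Three coupled layers evolve on every branch, in this order:

1. **exon–intron structure** — exon loss, gain and duplication;
2. **nucleotide sequences** — substitutions and indels on every
   surviving exon and intron;
3. **transcript sets** — structural and regulated transcript losses,
   transcript gains, and the five alternative-splicing event types.

All discrete event counts share one budget form,
`ceil(k × c_s_r × n × proportion)`, with `n` the number of source
objects when the stage opens (`ceil(n × proportion)` at the root,
where no branch exists). The ceiling guarantees at least one event
whenever the product is positive, so event counts never round to
nothing on short branches; it also means any positive proportion fires
at least once per branch (see *Lineage extinction* below).

## Evolutionary stages and termination

A stage converts a source transcript set into a sink set under one
event type; each sink links to at most one source, and sinks join the
source pool of the *next* stage, so chains of events (e.g. `es` then
`a3`) arise naturally. On every branch (and at the root) exactly one
stage runs per AS type, in the configurable order `es, me, a5, a3, ir`,
each with a budget recomputed from the current transcript count.

This one-stage-per-type rule is the package's termination choice.
Budgets use ceilings, so any rule of the form "iterate stages until
budgets vanish" never terminates with positive proportions, and a fixed
iteration cap makes transcript counts grow geometrically in the cap.
One pass per type keeps the process finite, reproduces the documented
stage arithmetic (a root `es` stage with 2 sources at `tc_es = 0.3`
yields 1 event and hands 3 sources to the next stage; a later branch
stage can open with 7 sources after earlier stages grew the set), and
still lets transcripts accumulate multiple events across stages.

Within a stage, each of the `budget` events draws a source uniformly
(with replacement — one transcript may head several events). When a
draw is inapplicable (`es` on a single-exon transcript, `me` with no
absent exon, `ir` with no eligible junction, `a5`/`a3` with no feasible
shift), the source is redrawn up to `n` times, after which the event is
skipped and logged as a shortfall; the invariant is
`events + shortfall = budget`.

## Transcript representation and AS-event semantics

A transcript stores its exon-id subset (structure-ordered), per-exon
acceptor/donor boundary offsets, and retained introns keyed by their
flanking exon pair.

* `es` removes one uniformly chosen exon (never the last one — the
  event is inapplicable on single-exon transcripts).
* `me` swaps one present exon for one absent structure exon, positions
  taken from structure order. The event generalizes classic mutually
  exclusive exon pairs, which are unordered in this model.
* `a5`/`a3` shift one exon's donor/acceptor boundary by
  `±3 × TruncGeom(offset_mean_codons, offset_max_codons)` nucleotides
  (sign uniform). Positive offsets trim into the exon (clamped so at
  least one codon remains), negative offsets extend into the flanking
  intron. Offsets are multiples of 3 by construction, so spliced
  lengths stay in frame.
* `ir` retains the intron between two transcript exons that are
  adjacent in the structure.

Offsets and retentions are *re-clamped at sequence-build time*: exon
and intron lengths drift by indels after the event was drawn, so the
effective trim is capped to leave ≥ 3 exon nt, intron extensions are
capped at half the intron (both neighbours may extend into the same
intron), and a retained intron contributes its first `3⌊L/3⌋` bases.
This keeps every transcript CDS a multiple of 3 at every node — the
model simulates coding sequence only; transcripts need not start with
ATG or end with a stop codon, but in-frame internal stops are excluded
as a modeling choice (offending substitutions are redrawn).

On a branch, a parent transcript survives structurally only if all its
exons exist in the child and every retained-intron junction is still a
single intact intron; a structural event that disrupts a retained
junction (an exon gained or duplicated into it) loses the transcript,
the same as losing one of its exons. Regulated (`tc_tl`) victims are
drawn before child copies are instantiated, so the loss record points
at the parent transcript and no orphan child node enters the forest.
Gains exclude exact duplicates of isoforms already present at the
child; two transcripts reaching the same splicing signature through
different histories remain distinct forest nodes, because the forest
records history, not a set of distinct isoforms.

## Sequence model

Fresh sequence comes from order-2 nucleotide Markov chains, one
parameter set for exons (mildly GC-rich, CpG-depleted) and one for
introns (AT-rich, strongly CpG-depleted), built from documented base
compositions with a same-base boost; users may substitute their own
chains via a TSV table (`context, pA, pC, pG, pT`). Chains are
programmatic defaults, not estimates from any genome database.

Evolution along a branch of length `c`:

* substitutions ~ `Poisson(rate × c × L)` per element, HKY-style with
  transition/transversion ratio `kappa` (default 2); exon substitutions
  creating an in-frame stop are redrawn;
* exon indels ~ `Poisson(exon_indel_rate × c × codons)`, length
  `3 × TruncGeom` placed at codon boundaries, deletions always leave
  ≥ 1 codon;
* intron indels operate on the interior only; `GT…AG` never mutates.

Every mutation is logged with its position in the coordinates current
at application time; replaying a log on the ancestral sequence
reproduces the descendant byte-for-byte, which the tests use as the
replay oracle and the alignment builder relies on.

## True alignment

Every nucleotide position ever created (root gene, insertion, exon
gain, duplication) receives a globally unique homology-column token;
descendants inherit tokens, deletions drop them from the child only,
and new tokens are spliced into one master order between their
neighbours. A row of the true MSA is a sequence scattered over its
tokens; a duplicated exon occupies fresh columns (its homology to the
template is recorded in the exon's `parent_exon_id`, not in the
alignment). Ungapping any row must reproduce its sequence exactly —
violated only by a corrupted event log, and checked on every build.

## Orthology and the conservation ratio

Two transcripts are splicing orthologs iff their genes differ and the
unique forest path between them carries only `conserved` edges.
Ortholog groups are reported over *extant* transcripts (guide-tree leaf
genes): a conserved component of the forest is geodesically convex, so
its leaf members are pairwise orthologous; maximality is clique
maximality in the pairwise graph, which coincides with components on
duplication-free guide trees (one gene cannot contribute two members
because a transcript maps to at most one conserved child per branch).

The conservation ratio is conserved clusters / transcripts over the
leaves, in (0, 1]; 1 means no conservation. Phylogeny-based clusters
are conserved components restricted to leaf transcripts. The
history-free control (`mode="independent"`) regenerates each node's
transcript set from its own structure with the root procedure and can
only cluster *identical* splicing signatures (exon ids + offsets +
retentions); with continuous-valued offsets and independent draws,
matching signatures across genes are rare, which is why the
phylogeny-based ratio sits below the composition-based one in the
paired experiment.

## Parameters

| key | meaning | unit | default |
|---|---|---|---|
| `k_tc` | branch factor for transcript-event budgets | – | 5 |
| `tc_rs, tc_tl` | gain / loss proportions | – | 1.0 / 0.05 |
| `tc_es, tc_me, tc_a5, tc_a3, tc_ir` | AS proportions | – | 0.25 / 0.15 / 0.15 / 0.15 / 0.15 |
| `root_count_mean, root_count_sd` | root transcript-count law | transcripts | 1.45, 1.08 |
| `k_structure` | branch factor for structure budgets | – | 1 |
| `p_exon_loss, p_exon_gain, p_exon_dup` | structure proportions | – | 0.2 / 0.1 / 0.05 |
| `exon_count_mean/sd` | root exon count (Normal, ≥ 1) | exons | 6, 2 |
| `exon_length_mean/sd` | exon length (Normal, ×3, ≥ 9) | nt | 150, 50 |
| `intron_length_mean/sd` | intron length (Normal, ≥ 4) | nt | 120, 40 |
| `exon/intron_substitution_rate` | substitutions per nt per unit branch | 1/nt | 1.0 / 1.5 |
| `exon_indel_rate` | indels per codon per unit branch | 1/codon | 0.02 |
| `intron_indel_rate` | indels per nt per unit branch | 1/nt | 0.03 |
| `offset_mean_codons/max` | a5/a3 shift law | codons | 2, 20 |
| `kappa` | transition/transversion ratio | – | 2 |
| `seed` | master seed | – | 0 |

The transcript-layer defaults are the tool's standard configuration;
structure- and sequence-layer constants are package choices in the
range typical for vertebrate coding genes, scaled so a unit branch is
one expected substitution per site. Tests and examples shrink gene
dimensions (e.g. 4–5 exons of ~30–60 nt, ~16–40 nt introns, `k_tc`
1.5–3) to keep simulated families small; every invariant is
dimension-free, so nothing about the checks depends on those sizes.

## Reproducibility

Each guide-tree node draws from `default_rng([seed, preorder_index])`,
so per-node results are independent of sibling processing and two runs
with identical inputs are byte-identical. The conservation experiment
derives per-iteration seeds from `SeedSequence(base_seed, (k_index,
iteration))`.

## Numerical choices and degenerate inputs

* Budget ceilings subtract `1e-9` before `ceil` so float fuzz
  (`30 × 0.1 = 3.0000000000000004`) cannot inflate a budget.
* A structure keeps ≥ 1 exon: a loss that would empty the gene is
  skipped and logged.
* Root transcript count is clamped to the isoform pool size; gains are
  clamped to the unused pool (clamps are logged as shortfalls).
* `GTAG` (no interior) is the smallest legal intron and is immutable.
* A root branch length, if present in the Newick, is ignored; unrooted
  trees (basal polytomy or `[&U]`) are rejected.

## Lineage extinction

Because ceilings force ≥ 1 `tl` loss per branch whenever
`tc_tl > 0`, and gains scale with the current transcript count, a gene
whose conserved set hits zero produces no further transcripts: the
lineage goes extinct and downstream nodes stay empty. This is a real
property of the budget arithmetic, common at small `k_tc` with few
transcripts and essentially absent at the default `k_tc = 5`. The
conservation experiment reports `NaN` ratios for extinct runs rather
than excluding them silently.

## What the generator does and does not emulate

Simulated data carries realistic *structure* — exon/intron layout,
frame-preserving AS events, branch-scaled divergence — but codon
content is context-chain noise with no selective constraint, splice
sites are fixed canonical dinucleotides, a5/a3 positions carry no
splice-site strength model, and introns undergo no gain, loss or
sliding. Passing tests therefore demonstrate correctness of the
evolutionary bookkeeping (budgets, Dollo parsimony, forests, replayable
logs, exact alignments), not biological realism of the sequences
themselves; methods benchmarked on these data see idealized, fully
resolved histories.
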