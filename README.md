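# splicesim

Simulation of eukaryotic gene-family evolution with alternative
splicing: given a guide gene tree, `splicesim` evolves a gene's
exon–intron structure, its nucleotide sequences and — centrally — the
*set of alternative transcripts* produced by each gene along every
branch. Because transcript sets at different nodes are connected by an
explicit evolutionary process, the simulator emits transcript
phylogenies (a forest), groups of splicing orthologs, exact ("true")
multiple sequence alignments and complete event logs. These are ground
truth for benchmarking spliced alignment, transcript-phylogeny
inference, multiple alignment and splicing-orthology methods, where no
real gold standard exists.

## The model

**Inputs.** A rooted guide gene tree in Newick or NHX format with a
branch length `c_s_r` (expected substitutions per site) on every
non-root edge, plus a configuration of rate constants and relative
event proportions.

**Gene structure.** Each gene is an ordered alternation of exons and
introns. Along a branch the structure changes by exon loss, gain and
duplication; exon identifiers are stable and never reused, so exon
presence obeys Dollo parsimony (an exon lost on a lineage is never
regained). Exon sequences evolve at the codon level (HKY-style
substitutions that never write an in-frame stop, whole-codon indels);
introns evolve at the nucleotide level with their `GT…AG` dinucleotides
pinned.

**Transcripts.** A transcript is a non-empty, order-preserving subset
of its gene's exons plus splice modifiers. Seven event types act on a
gene's transcript set: the five AS events — alternative 5'/3'
splice-site choice (`a5`/`a3`, boundary offsets that are always
multiples of 3), exon skipping (`es`), mutually exclusive exons (`me`)
and intron retention (`ir`) — plus transcript gain by random selection
(`rs`) from the pool of `2^m − 1` isoforms of an `m`-exon gene, and
transcript loss (`tl`).

**Evolutionary stages.** Evolution proceeds in stages: a stage turns a
set of *n* source transcripts into a sink set by applying

```
ceil(k_tc × c_s_r × n × tc_x)        on a branch
ceil(n × tc_x)                        at the root
```

events of type `x`, each sink linked to at most one source. At the
root, `Normal(1.45, 1.08)` (rounded, clamped ≥ 1) transcripts are first
drawn uniformly from the isoform pool (a single all-exon transcript if
`tc_rs = 0`); transcripts are never lost at the root. On a branch,
transcripts whose exons were structurally lost die, `tc_tl` prunes
survivors, `tc_rs` adds fresh pool picks (new forest roots), and one
stage per AS type follows. Across stages a transcript may accumulate
several events.

**Outputs.** The forest of transcript trees (edges labeled `conserved`
or by AS type), FASTA sequences, exon coordinates, the true MSA
(assembled from homology columns threaded through every event, never
estimated), event logs, and ortholog groups — two extant transcripts
are splicing orthologs when they belong to distinct genes and only
conserved edges lie on the forest path between them.

## Worked example

`python examples/simulate_family.py` prints:

```
gene nodes and transcript sets:
      n0: 5 exons, 426 nt gene, 4 transcripts
      HM: 6 exons, 583 nt gene, 7 transcripts
   human: 7 exons, 688 nt gene, 12 transcripts
   mouse: 7 exons, 708 nt gene, 12 transcripts
      FF: 6 exons, 527 nt gene, 7 transcripts
    frog: 7 exons, 613 nt gene, 18 transcripts
    fish: 7 exons, 667 nt gene, 15 transcripts

6 ortholog groups among extant transcripts:
  {fish#1, frog#1, mouse#2}
  {fish#2, frog#2, human#2, mouse#3}
  ...
```

The ancestral gene (`n0`) starts with 5 exons and 4 transcripts;
exon gains enlarge the structure toward the leaves, and AS-event
budgets scaled by branch lengths expand each transcript set. The group
`{fish#2, frog#2, human#2, mouse#3}` is one ancestral isoform conserved
without any AS event into all four extant genes. The other examples
show the budget arithmetic (`examples/event_budgets.py`) and the
conservation-ratio comparison between linked and history-free
transcript evolution (`examples/conservation_comparison.py`).

## Command line

```
splicesim --tree "((A:0.3,B:0.3):0.2,C:0.4);" --out results/ --seed 1
splicesim --tree-file family.nwk --out results/ \
    --mode conservation-experiment --iterations 100 --k-tc-values 100,200
```

All configuration keys can be given as flags (`--tc-es 0.25 …`) or in a
flat YAML file via `--config`; flags win. Defaults: `k_tc=5`,
`tc_rs=1`, `tc_es=0.25`, `tc_me=0.15`, `tc_a5=0.15`, `tc_a3=0.15`,
`tc_ir=0.15`, `tc_tl=0.05`. Same arguments + same seed give
byte-identical outputs. See `docs/methods.md` for every parameter, its
units and default.

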