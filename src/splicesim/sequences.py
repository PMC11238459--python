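"""Nucleotide sequence generation and branch-wise evolution.

Fresh exon and intron sequences are sampled from order-k nucleotide
Markov chains (bundled defaults, or user-supplied tables).  Along a
branch of length ``c_s_r`` (expected substitutions per site) sequences
accumulate substitutions and indels:

* exons evolve at the codon level — indels move whole codons at codon
  boundaries and substitutions that would write an in-frame stop codon
  (TAA/TAG/TGA in frame 0) are redrawn, so coding frame and length
  mod 3 are preserved;
* introns evolve at the nucleotide level in their interior only, with
  the canonical GT...AG dinucleotides pinned.

Every mutation is recorded as a :class:`SequenceEvent`; replaying the
event list on the ancestral sequence reproduces the descendant exactly,
which is the contract the true-alignment builder relies on.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
STOP_CODONS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ReplayError(ValueError):
    """An event log does not apply cleanly to the given sequence."""


# ---------------------------------------------------------------------------
# Markov chain parameters
# ---------------------------------------------------------------------------

@dataclass
class MarkovChainParams:
    """Order-k nucleotide Markov chain.

    ``probs`` maps contexts of length 0..order (the empty context seeds
    the first base) to probability vectors over A, C, G, T.  Every
    vector must sum to 1 within 1e-9.
    """

    order: int
    probs: Dict[str, np.ndarray]

    def validate(self) -> "MarkovChainParams":
        if self.order < 0:
            raise ValueError("order must be >= 0")
        for ctx, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"invalid probability vector for context {ctx!r}")
            self.probs[ctx] = p
        for k in range(self.order + 1):
            if not any(len(c) == k for c in self.probs):
                raise ValueError(f"no context of length {k} provided")
        return self

    def prob_vector(self, context: str) -> np.ndarray:
        """Probabilities for the next base after ``context`` (back-off)."""
        ctx = context[-self.order:] if self.order else ""
        while ctx not in self.probs:
            if not ctx:
                raise KeyError("chain lacks an empty-context vector")
            ctx = ctx[1:]
        return self.probs[ctx]

    # -- bundled defaults ---------------------------------------------------
    @classmethod
    def _build(cls, order: int, base: Dict[str, float],
               same_boost: float, cpg_factor: float) -> "MarkovChainParams":
        probs: Dict[str, np.ndarray] = {}
        contexts = [""]
        for _ in range(order):
            contexts += [c + n for c in contexts if len(c) == len(contexts[0])
                         for n in NUCLEOTIDES]
        # regenerate cleanly: all strings of length 0..order
        contexts = [""]
        frontier = [""]
        for _ in range(order):
            frontier = [c + n for c in frontier for n in NUCLEOTIDES]
            contexts += frontier
        for ctx in contexts:
            w = np.array([base[n] for n in NUCLEOTIDES], dtype=float)
            if ctx:
                last = ctx[-1]
                w[_NT_INDEX[last]] *= same_boost
                if last == "C":
                    w[_NT_INDEX["G"]] *= cpg_factor
            probs[ctx] = w / w.sum()
        return cls(order=order, probs=probs).validate()

    @classmethod
    def default_exon(cls) -> "MarkovChainParams":
        """Coding-like composition: mildly GC-rich, CpG-depleted."""
        return cls._build(2, {"A": 0.26, "C": 0.26, "G": 0.28, "T": 0.20},
                          same_boost=1.2, cpg_factor=0.8)

    @classmethod
    def default_intron(cls) -> "MarkovChainParams":
        """Intron-like composition: AT-rich, strongly CpG-depleted."""
        return cls._build(2, {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29},
                          same_boost=1.3, cpg_factor=0.4)

    # -- tabular interchange (context, pA, pC, pG, pT; "-" = empty context) --
    def to_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("context\tA\tC\tG\tT\n")
            for ctx in sorted(self.probs, key=lambda c: (len(c), c)):
                p = self.probs[ctx]
                fh.write((ctx or "-") + "\t" + "\t".join(f"{x:.6g}" for x in p) + "\n")

    @classmethod
    def from_table(cls, path: str) -> "MarkovChainParams":
        probs: Dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("context"):
                raise ValueError("Markov table must start with a 'context' header")
            for line in fh:
                if not line.strip():
                    continue
                ctx, *vals = line.rstrip("\n").split("\t")
                if len(vals) != 4:
                    raise ValueError(f"bad Markov table row: {line!r}")
                probs["" if ctx == "-" else ctx] = np.array(vals, dtype=float)
        order = max(len(c) for c in probs)
        return cls(order=order, probs=probs).validate()


def sample_chain(length: int, params: MarkovChainParams,
                 rng: np.random.Generator, context: str = "") -> str:
    """Sample ``length`` bases from the chain, continuing ``context``."""
    out: List[str] = []
    ctx = context
    for _ in range(length):
        p = params.prob_vector(ctx)
        nt = NUCLEOTIDES[rng.choice(4, p=p)]
        out.append(nt)
        ctx = (ctx + nt)[-params.order:] if params.order else ""
    return "".join(out)


# ---------------------------------------------------------------------------
# Fresh sequence generation
# ---------------------------------------------------------------------------

def generate_exon_sequence(length_nt: int,
                           params: Optional[MarkovChainParams] = None,
                           rng: Optional[np.random.Generator] = None,
                           context: str = "") -> str:
    """Sample a coding exon sequence free of in-frame stop codons.

    ``length_nt`` must be a positive multiple of 3.  Codons are drawn
    from the chain one at a time; a draw producing TAA/TAG/TGA in
    frame 0 is resampled.
    """
    if length_nt < 3 or length_nt % 3:
        raise ValueError(f"exon length must be a positive multiple of 3, got {length_nt}")
    params = params or MarkovChainParams.default_exon()
    rng = rng if rng is not None else np.random.default_rng()
    out: List[str] = []
    ctx = context
    for _ in range(length_nt // 3):
        for _attempt in range(200):
            codon = sample_chain(3, params, rng, ctx)
            if codon not in STOP_CODONS:
                break
        else:  # pragma: no cover - degenerate all-stop chains
            codon = codon[:2] + "C"
        out.append(codon)
        ctx = (ctx + codon)[-params.order:] if params.order else ""
    return "".join(out)


def generate_intron_sequence(length_nt: int,
                             params: Optional[MarkovChainParams] = None,
                             rng: Optional[np.random.Generator] = None) -> str:
    """Sample an intron sequence with canonical GT...AG splice sites."""
    if length_nt < 4:
        raise ValueError(f"intron length must be >= 4, got {length_nt}")
    params = params or MarkovChainParams.default_intron()
    rng = rng if rng is not None else np.random.default_rng()
    interior = sample_chain(length_nt - 4, params, rng, context="GT")
    return "GT" + interior + "AG"


# ---------------------------------------------------------------------------
# Mutation events and replay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceEvent:
    """One substitution / insertion / deletion, in current coordinates.

    ``pos`` indexes the sequence *at the time the event is applied*,
    so a log replays strictly in order.  ``old`` is the replaced
    segment (one base for substitutions, the removed run for
    deletions); ``new`` is the introduced segment.
    """

    kind: str  # 'sub' | 'ins' | 'del'
    pos: int
    old: str = ""
    new: str = ""


def replay_sequence(seq: str, events: Sequence[SequenceEvent]) -> str:
    """Apply an event log to ``seq``; raises :class:`ReplayError` on mismatch."""
    work = list(seq)
    for ev in events:
        if ev.kind == "sub":
            if work[ev.pos] != ev.old:
                raise ReplayError(f"substitution at {ev.pos}: expected {ev.old}, "
                                  f"found {work[ev.pos]}")
            work[ev.pos] = ev.new
        elif ev.kind == "del":
            seg = "".join(work[ev.pos:ev.pos + len(ev.old)])
            if seg != ev.old:
                raise ReplayError(f"deletion at {ev.pos}: expected {ev.old!r}, "
                                  f"found {seg!r}")
            del work[ev.pos:ev.pos + len(ev.old)]
        elif ev.kind == "ins":
            work[ev.pos:ev.pos] = list(ev.new)
        else:
            raise ReplayError(f"unknown event kind {ev.kind!r}")
    return "".join(work)


def _truncated_geometric(rng: np.random.Generator, mean: float, maximum: int) -> int:
    mean = max(mean, 1.0)
    k = int(rng.geometric(1.0 / mean))
    return min(k, max(1, maximum))


def _substitute_base(old: str, kappa: float, rng: np.random.Generator) -> str:
    """HKY-style draw of a base != old: transition weight kappa, transversions 1."""
    candidates = [n for n in NUCLEOTIDES if n != old]
    weights = np.array([kappa if _TRANSITION[old] == n else 1.0 for n in candidates])
    return candidates[rng.choice(3, p=weights / weights.sum())]


# ---------------------------------------------------------------------------
# Branch-wise evolution
# ---------------------------------------------------------------------------

def evolve_exon_sequence(seq: str, branch_length: float, config,
                         rng: np.random.Generator,
                         params: Optional[MarkovChainParams] = None,
                         ) -> Tuple[str, List[SequenceEvent]]:
    """Evolve a coding exon along a branch.

    Substitution count ~ Poisson(rate * c_s_r * L); indel count ~
    Poisson(rate * c_s_r * codons), each indel moving a whole number of
    codons at a codon boundary.  The output length stays a multiple of
    3 and no frame-0 stop codon is introduced.
    """
    if len(seq) % 3:
        raise ValueError("exon sequence length must be a multiple of 3")
    params = params or config.exon_markov or MarkovChainParams.default_exon()
    work = list(seq)
    events: List[SequenceEvent] = []

    n_sub = int(rng.poisson(config.exon_substitution_rate * branch_length * len(seq)))
    for _ in range(n_sub):
        for _attempt in range(100):
            pos = int(rng.integers(len(work)))
            old = work[pos]
            new = _substitute_base(old, config.kappa, rng)
            c0 = pos - pos % 3
            codon = "".join(work[c0:pos]) + new + "".join(work[pos + 1:c0 + 3])
            if codon not in STOP_CODONS:
                work[pos] = new
                events.append(SequenceEvent("sub", pos, old, new))
                break

    n_codons = len(work) // 3
    n_indel = int(rng.poisson(config.exon_indel_rate * branch_length * n_codons))
    for _ in range(n_indel):
        k = _truncated_geometric(rng, config.exon_indel_mean_codons,
                                 config.exon_indel_max_codons)
        cur_codons = len(work) // 3
        if rng.random() < 0.5:  # insertion of k whole codons
            pos = 3 * int(rng.integers(cur_codons + 1))
            frag = generate_exon_sequence(3 * k, params, rng)
            work[pos:pos] = list(frag)
            events.append(SequenceEvent("ins", pos, "", frag))
        else:  # deletion of k whole codons, keeping >= 1 codon
            k = min(k, cur_codons - 1)
            if k < 1:
                continue
            start = 3 * int(rng.integers(cur_codons - k + 1))
            old = "".join(work[start:start + 3 * k])
            del work[start:start + 3 * k]
            events.append(SequenceEvent("del", start, old, ""))
    return "".join(work), events


def evolve_intron_sequence(seq: str, branch_length: float, config,
                           rng: np.random.Generator,
                           params: Optional[MarkovChainParams] = None,
                           ) -> Tuple[str, List[SequenceEvent]]:
    """Evolve an intron along a branch, interior only; GT/AG preserved."""
    if len(seq) < 4 or not seq.startswith("GT") or not seq.endswith("AG"):
        raise ValueError("intron sequence must be GT...AG and >= 4 nt")
    params = params or config.intron_markov or MarkovChainParams.default_intron()
    interior = list(seq[2:-2])
    events: List[SequenceEvent] = []

    n_sub = int(rng.poisson(config.intron_substitution_rate * branch_length
                            * len(interior)))
    for _ in range(n_sub):
        if not interior:
            break
        pos = int(rng.integers(len(interior)))
        old = interior[pos]
        new = _substitute_base(old, config.kappa, rng)
        interior[pos] = new
        events.append(SequenceEvent("sub", pos + 2, old, new))

    n_indel = int(rng.poisson(config.intron_indel_rate * branch_length
                              * len(interior)))
    for _ in range(n_indel):
        k = _truncated_geometric(rng, config.intron_indel_mean_nt,
                                 config.intron_indel_max_nt)
        if rng.random() < 0.5 or not interior:
            pos = int(rng.integers(len(interior) + 1))
            ctx = "GT" + "".join(interior[:pos])
            frag = sample_chain(k, params, rng, context=ctx)
            interior[pos:pos] = list(frag)
            events.append(SequenceEvent("ins", pos + 2, "", frag))
        else:
            k = min(k, len(interior))
            start = int(rng.integers(len(interior) - k + 1))
            old = "".join(interior[start:start + k])
            del interior[start:start + k]
            events.append(SequenceEvent("del", start + 2, old, ""))
    return "GT" + "".join(interior) + "AG", events


def has_internal_stop(seq: str) -> bool:
    """True if any frame-0 codon except the final one is a stop codon."""
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3))
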