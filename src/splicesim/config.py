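"""Simulation configuration and the event-budget arithmetic.

Branch lengths of the guide tree are expected substitutions per site
(``c_s_r``).  The same lengths scale the *discrete* event counts drawn
for structure and transcript evolution through the ceiling formula

    budget = ceil(k * c_s_r * n * proportion)

where ``n`` is the number of source objects (transcripts or exons) at
the current evolutionary stage and ``proportion`` is the relative rate
of the event type.  At the root of the tree no branch exists and the
reduced form ``ceil(n * proportion)`` applies.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

import yaml

#: The five alternative-splicing event types, in the default stage order.
AS_EVENT_TYPES: Tuple[str, ...] = ("es", "me", "a5", "a3", "ir")

# Guard against float fuzz such as 0.1 * 30 = 3.0000000000000004; the
# budget must not jump to 4 in that case.
_CEIL_EPS = 1e-9


def _require_nonnegative(**values: float) -> None:
    bad = [k for k, v in values.items() if v < 0 or not math.isfinite(v)]
    if bad:
        raise ValueError(
            "arguments must be finite and >= 0: " + ", ".join(sorted(bad))
        )


def event_budget(n: int, proportion: float, k_tc: float, branch_length: float) -> int:
    """Number of events of one type on a branch: ceil(k * c * n * p).

    Returns 0 when the product is 0 and at least 1 whenever it is
    positive (the ceiling forces one event even for tiny products).
    """
    _require_nonnegative(n=n, proportion=proportion, k_tc=k_tc,
                         branch_length=branch_length)
    product = k_tc * branch_length * n * proportion
    if product <= 0:
        return 0
    return max(1, math.ceil(product - _CEIL_EPS))


def root_event_budget(n: int, proportion: float) -> int:
    """Root form of the budget: ceil(n * p); branch factors do not apply."""
    _require_nonnegative(n=n, proportion=proportion)
    product = n * proportion
    if product <= 0:
        return 0
    return max(1, math.ceil(product - _CEIL_EPS))


@dataclass
class SimulationConfig:
    """All tunable constants of a simulation run.

    Four broad parameter groups:

    1. constant factors scaling branch event counts (``k_tc``,
       ``k_structure``);
    2. sequence-evolution constants (substitution/indel rates, the
       Markov chains used to generate fresh exon/intron sequence, and
       the root gene's dimension distributions);
    3. structure-evolution proportions (exon loss / gain / duplication);
    4. transcript-evolution proportions (``tc_a5`` ... ``tc_rs``).

    All proportions and constants must be >= 0.  ``seed`` drives every
    stochastic draw; per-node generator streams are derived from
    ``(seed, preorder index)`` so results do not depend on traversal
    bookkeeping.
    """

    # -- category 4: transcript-set evolution ------------------------------
    k_tc: float = 5.0
    tc_rs: float = 1.0
    tc_tl: float = 0.05
    tc_es: float = 0.25
    tc_me: float = 0.15
    tc_a5: float = 0.15
    tc_a3: float = 0.15
    tc_ir: float = 0.15
    #: order in which the AS-event stages run on every branch / at the root
    stage_order: Tuple[str, ...] = AS_EVENT_TYPES
    #: override the Normal(root_count_mean, root_count_sd) draw (testing /
    #: scripted scenarios); None means draw.
    root_transcript_count: Optional[int] = None
    root_count_mean: float = 1.45
    root_count_sd: float = 1.08

    # -- category 3: exon-intron structure evolution -----------------------
    k_structure: float = 1.0
    p_exon_loss: float = 0.2
    p_exon_gain: float = 0.1
    p_exon_dup: float = 0.05

    # -- root gene dimensions ----------------------------------------------
    #: force an exact root exon count (None -> Normal draw below)
    exon_count: Optional[int] = None
    exon_count_mean: float = 6.0
    exon_count_sd: float = 2.0
    exon_length_mean: float = 150.0
    exon_length_sd: float = 50.0
    min_exon_length: int = 9
    intron_length_mean: float = 120.0
    intron_length_sd: float = 40.0
    min_intron_length: int = 4

    # -- category 2: sequence evolution ------------------------------------
    exon_substitution_rate: float = 1.0   # substitutions / nt / unit branch
    intron_substitution_rate: float = 1.5
    kappa: float = 2.0                    # transition/transversion ratio
    exon_indel_rate: float = 0.02         # indel events / codon / unit branch
    exon_indel_mean_codons: float = 1.5
    exon_indel_max_codons: int = 10
    intron_indel_rate: float = 0.03       # indel events / nt / unit branch
    intron_indel_mean_nt: float = 4.0
    intron_indel_max_nt: int = 30
    #: a5/a3 boundary offsets are 3 x truncated-geometric(mean, max) codons
    offset_mean_codons: float = 2.0
    offset_max_codons: int = 20
    #: Markov-chain parameters for fresh sequence; None -> bundled defaults
    exon_markov: Any = None
    intron_markov: Any = None

    # -- reproducibility ----------------------------------------------------
    seed: int = 0

    # ----------------------------------------------------------------------
    def proportion(self, kind: str) -> float:
        """Relative proportion for one of the seven transcript event types."""
        try:
            return getattr(self, f"tc_{kind}")
        except AttributeError:
            raise KeyError(f"unknown transcript event type: {kind!r}") from None

    def validate(self) -> "SimulationConfig":
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if isinstance(getattr(self, f.name), (int, float))
            and not isinstance(getattr(self, f.name), bool)
        }
        _require_nonnegative(**{k: float(v) for k, v in numeric.items()})
        if self.min_exon_length < 3 or self.min_exon_length % 3:
            raise ValueError("min_exon_length must be a positive multiple of 3")
        if self.min_intron_length < 4:
            raise ValueError("min_intron_length must be >= 4 (GT...AG)")
        unknown = [k for k in self.stage_order if k not in AS_EVENT_TYPES]
        if unknown:
            raise ValueError(f"unknown AS event types in stage_order: {unknown}")
        if self.root_transcript_count is not None and self.root_transcript_count < 1:
            raise ValueError("root_transcript_count must be >= 1")
        if self.exon_count is not None and self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")
        return self

    # -- construction -------------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Dict[str, Any]) -> "SimulationConfig":
        """Build a config from a flat mapping; unknown keys are an error."""
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - names)
        if unknown:
            raise ValueError(
                "unknown configuration keys: " + ", ".join(unknown)
            )
        kwargs = dict(mapping)
        if "stage_order" in kwargs and not isinstance(kwargs["stage_order"], tuple):
            kwargs["stage_order"] = tuple(kwargs["stage_order"])
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Load a flat ``key: value`` YAML configuration file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must hold a flat mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> Dict[str, Any]:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("exon_markov", "intron_markov"):
                continue
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
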