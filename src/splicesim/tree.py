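"""Guide gene tree: parsing, validation and serialization.

The guide tree carries the gene family's topology with gene labels at
the leaves and one branch length (``c_s_r``, expected substitutions per
site) on every non-root edge.  Newick and NHX input are accepted; NHX
comments are preserved by the reader but unused by the simulation.
Parsing is delegated to :mod:`dendropy`; this module wraps the result in
a small validated structure with stable preorder indices so every
simulated gene (internal nodes included) is addressable.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import dendropy


class TreeParseError(ValueError):
    """Raised when the Newick/NHX text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a syntactically valid tree violates guide-tree rules."""


@dataclass
class GuideNode:
    index: int                      # preorder index; root is 0
    label: str
    length: Optional[float]         # None only at the root
    parent: Optional["GuideNode"] = None
    children: List["GuideNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GuideNode({self.label!r}, length={self.length})"


class GuideTree:
    """A rooted guide gene tree with branch lengths on non-root edges."""

    def __init__(self, root: GuideNode):
        self.root = root
        self.nodes: List[GuideNode] = list(self._preorder(root))
        self.leaves: List[GuideNode] = [n for n in self.nodes if n.is_leaf]
        self._validate()

    @staticmethod
    def _preorder(node: GuideNode) -> Iterator[GuideNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def preorder(self) -> Iterator[GuideNode]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, label: str) -> GuideNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def _validate(self) -> None:
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate node labels: {dup}")
        for n in self.nodes:
            if n.is_root:
                continue
            if n.length is None:
                raise TreeValidationError(
                    f"non-root node {n.label!r} lacks a branch length"
                )
            if not math.isfinite(n.length) or n.length < 0:
                raise TreeValidationError(
                    f"branch length of {n.label!r} must be finite and >= 0, "
                    f"got {n.length}"
                )
        for leaf in self.leaves:
            if not leaf.label:
                raise TreeValidationError("leaf with empty label")

    # -- serialization ------------------------------------------------------
    def newick(self) -> str:
        def render(n: GuideNode) -> str:
            if n.children:
                inner = ",".join(render(c) for c in n.children)
                body = f"({inner}){n.label}"
            else:
                body = n.label
            if n.length is not None and not n.is_root:
                body += f":{n.length:g}"
            return body

        return render(self.root) + ";"


def parse_guide_tree(text: str) -> GuideTree:
    """Parse a Newick/NHX string into a validated :class:`GuideTree`.

    Every non-root edge must carry a branch length; explicitly unrooted
    trees (``[&U]`` token or a basal polytomy) are rejected.
    """
    if not text or not text.strip():
        raise TreeParseError("empty tree string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(
                f"duplicate leaf labels in guide tree: {exc}") from exc
        raise TreeParseError(f"malformed Newick/NHX input: {exc}") from exc

    if re.search(r"\[\s*&\s*U\s*\]", text, flags=re.IGNORECASE):
        raise TreeValidationError("unrooted trees ([&U]) are not supported")
    if len(dtree.seed_node.child_nodes()) > 2:
        raise TreeValidationError(
            "root has more than two children; unrooted trees are not supported"
        )

    counter = iter(range(10 ** 9))

    def convert(dnode, parent: Optional[GuideNode]) -> GuideNode:
        idx = next(counter)
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        else:
            label = f"n{idx}"
        node = GuideNode(index=idx, label=label,
                         length=dnode.edge.length, parent=parent)
        for child in dnode.child_nodes():
            node.children.append(convert(child, node))
        return node

    root = convert(dtree.seed_node, None)
    root.length = None  # a root branch length, if present, is ignored
    _uniquify_internal_labels(root)
    return GuideTree(root)


def _uniquify_internal_labels(root: GuideNode) -> None:
    seen = set()
    stack = [root]
    order: List[GuideNode] = []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(n.children))
    for n in order:
        if n.is_leaf:
            seen.add(n.label)
    for n in order:
        if n.is_leaf:
            continue
        label = n.label
        while label in seen:
            label = f"{label}_{n.index}"
        n.label = label
        seen.add(label)
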