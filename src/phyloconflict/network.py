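"""Rooted species trees and networks with inheritance probabilities.

A :class:`SpeciesNetwork` is a rooted DAG over species names.  Tree nodes
have one parent edge; reticulate nodes have two, each carrying an
inheritance probability ``gamma`` (the probability that a gene lineage
follows that edge backwards in time), with the pair summing to 1.  Branch
lengths are in coalescent units (time / 2N generations).

Input format is "rich newick": reticulate nodes are written twice with a
shared ``#H<k>`` tag, and each reticulation edge may carry
``:length:support:gamma`` fields, e.g.::

    ((A:1.0,(B:0.5)#H1:0.5::0.7):1.0,(#H1:0.5::0.3,C:1.0):1.0);

No installed library parses this dialect, so the reader here is hand
written (a small recursive-descent parser).
"""

from __future__ import annotations

import math
import re
from typing import Iterator

from .errors import NetworkError, NewickParseError
from .trees import GeneTree, TreeNode

__all__ = ["NetNode", "NetEdge", "SpeciesNetwork"]

_NAME_RE = re.compile(r"[^(),:;#\[\]\s]+")
_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


class NetEdge:
    """Directed edge parent -> child with a length and (optional) gamma."""

    __slots__ = ("parent", "child", "length", "gamma")

    def __init__(self, parent: "NetNode", child: "NetNode",
                 length: float = 0.0, gamma: float | None = None):
        self.parent = parent
        self.child = child
        self.length = length
        self.gamma = gamma

    def __repr__(self) -> str:  # pragma: no cover
        g = f", gamma={self.gamma}" if self.gamma is not None else ""
        return (f"NetEdge({self.parent.name or '·'}->"
                f"{self.child.name or '·'}, len={self.length}{g})")


class NetNode:
    __slots__ = ("name", "hybrid_id", "child_edges", "parent_edges")

    def __init__(self, name: str | None = None, hybrid_id: str | None = None):
        self.name = name
        self.hybrid_id = hybrid_id
        self.child_edges: list[NetEdge] = []
        self.parent_edges: list[NetEdge] = []

    @property
    def is_leaf(self) -> bool:
        return not self.child_edges

    @property
    def is_reticulate(self) -> bool:
        return len(self.parent_edges) > 1


class SpeciesNetwork:
    """Rooted species tree/network in coalescent units."""

    def __init__(self, root: NetNode):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesNetwork":
        root = _parse_rich_newick(text)
        return cls(root)

    # -- structure ----------------------------------------------------------

    def nodes(self) -> list[NetNode]:
        """All nodes in a child-before-parent (topological) order."""
        order: list[NetNode] = []
        seen: set[int] = set()
        remaining_children: dict[int, int] = {}

        def collect(node: NetNode):
            if id(node) in remaining_children:
                return
            remaining_children[id(node)] = len(node.child_edges)
            for e in node.child_edges:
                collect(e.child)
        collect(self.root)

        ready = [n for n in self._all_nodes() if not n.child_edges]
        # deterministic order: leaves sorted by name
        ready.sort(key=lambda n: n.name or "")
        while ready:
            node = ready.pop(0)
            if id(node) in seen:
                continue
            seen.add(id(node))
            order.append(node)
            for e in node.parent_edges:
                remaining_children[id(e.parent)] -= 1
                if remaining_children[id(e.parent)] == 0:
                    ready.append(e.parent)
        if len(order) != len(remaining_children):
            raise NetworkError("network contains a cycle")
        return order

    def _all_nodes(self) -> list[NetNode]:
        out, stack, seen = [], [self.root], set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            out.append(node)
            stack.extend(e.child for e in node.child_edges)
        return out

    def leaves(self) -> list[NetNode]:
        return sorted((n for n in self._all_nodes() if n.is_leaf),
                      key=lambda n: n.name or "")

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def reticulations(self) -> list[NetNode]:
        return [n for n in self.nodes() if n.is_reticulate]

    @property
    def is_tree(self) -> bool:
        return not self.reticulations()

    def heights(self) -> dict[int, float]:
        """Node heights above the leaves (leaves at 0), id(node) keyed.

        For slightly inconsistent input lengths the maximum over paths is
        used, so every edge has non-negative duration for simulation.
        """
        h: dict[int, float] = {}
        for node in self.nodes():
            if node.is_leaf:
                h[id(node)] = 0.0
            else:
                h[id(node)] = max(h[id(e.child)] + e.length
                                  for e in node.child_edges)
        return h

    # -- validation / conversion -------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise NetworkError("leaf labels are not unique")
        if not names:
            raise NetworkError("network has no leaves")
        for node in self.nodes():
            for e in node.child_edges:
                if e.length < 0:
                    raise NetworkError(f"negative branch length {e.length}")
            pes = node.parent_edges
            if len(pes) > 2:
                raise NetworkError("reticulate node with more than two parents")
            if len(pes) == 2:
                gammas = [e.gamma for e in pes]
                if any(g is None for g in gammas):
                    raise NetworkError(
                        "reticulation edges must carry inheritance probabilities")
                if not all(0 <= g <= 1 for g in gammas):
                    raise NetworkError(
                        f"inheritance probabilities {gammas} outside [0, 1]")
                if not math.isclose(sum(gammas), 1.0, abs_tol=1e-6):
                    raise NetworkError(
                        f"inheritance probabilities {gammas} do not sum to 1")
        # removing every minor parent edge must leave a tree
        self.major_tree()

    def major_tree(self) -> GeneTree:
        """The backbone tree obtained by dropping minor reticulation edges."""
        def build(node: NetNode, length: float) -> TreeNode:
            clone = TreeNode(node.name, length)
            for e in node.child_edges:
                if e.child.is_reticulate:
                    major = max(e.child.parent_edges, key=lambda pe: pe.gamma)
                    if major is not e:
                        continue
                clone.add(build(e.child, e.length))
            return clone

        root = build(self.root, 0.0)
        _suppress_unary_chain(root)
        tree = GeneTree(root, validate=False)
        if sorted(tree.leaf_labels()) != self.leaf_names():
            raise NetworkError(
                "removing minor reticulation edges does not yield a tree "
                "over all leaves")
        return tree

    def to_gene_tree(self) -> GeneTree:
        """Convert a reticulation-free network to a species-labelled tree."""
        if not self.is_tree:
            raise NetworkError("network has reticulations; use major_tree()")
        return self.major_tree()


def _suppress_unary_chain(root: TreeNode) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            if node is root or len(node.children) != 1:
                continue
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            parent.children[parent.children.index(node)] = child
            child.parent = parent
            changed = True
    while len(root.children) == 1 and root.children[0].children:
        root.children = root.children[0].children
        for c in root.children:
            c.parent = root


# ---------------------------------------------------------------------------
# rich newick parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.hybrids: dict[str, NetNode] = {}

    def error(self, message: str):
        raise NewickParseError(
            f"{message} at character offset {self.pos}")

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> NetNode:
        root = self.subtree()
        if self.peek() != ";":
            self.error("expected ';'")
        return root

    def subtree(self) -> NetNode:
        children: list[tuple[NetNode, float, float | None]] = []
        if self.peek() == "(":
            self.pos += 1
            while True:
                children.append(self.child())
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                self.error("expected ',' or ')'")
        name = self.name()
        hybrid = self.hybrid_tag()
        if hybrid is not None:
            node = self.hybrids.get(hybrid)
            if node is None:
                node = NetNode(name, hybrid)
                self.hybrids[hybrid] = node
            elif name and not node.name:
                node.name = name
        else:
            if children == [] and not name:
                self.error("expected a taxon name")
            node = NetNode(name or None)
        for child, length, gamma in children:
            edge = NetEdge(node, child, length, gamma)
            node.child_edges.append(edge)
            child.parent_edges.append(edge)
        return node

    def child(self) -> tuple[NetNode, float, float | None]:
        node = self.subtree()
        length, gamma = 0.0, None
        if self.peek() == ":":
            self.pos += 1
            length = self.number(default=0.0)
            if self.peek() == ":":  # support slot (ignored on networks)
                self.pos += 1
                self.number(default=None)
                if self.peek() == ":":
                    self.pos += 1
                    gamma = self.number(default=None)
        return node, length, gamma

    def name(self) -> str:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "'":
            end = self.text.find("'", self.pos + 1)
            if end < 0:
                self.error("unterminated quoted name")
            value = self.text[self.pos + 1:end]
            self.pos = end + 1
            return value
        m = _NAME_RE.match(self.text, self.pos)
        if not m:
            return ""
        self.pos = m.end()
        return m.group()

    def hybrid_tag(self) -> str | None:
        if self.peek() != "#":
            return None
        self.pos += 1
        m = _NAME_RE.match(self.text, self.pos)
        if not m:
            self.error("expected a hybrid tag after '#'")
        self.pos = m.end()
        return m.group()

    def number(self, default):
        m = _NUM_RE.match(self.text, self.pos)
        if not m:
            return default
        self.pos = m.end()
        return float(m.group())


def _parse_rich_newick(text: str) -> NetNode:
    parser = _Parser(text)
    root = parser.parse()
    # fill in the complementary gamma when only one side is annotated
    stack, seen = [root], set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        if len(node.parent_edges) == 2:
            g = [e.gamma for e in node.parent_edges]
            if g[0] is None and g[1] is not None:
                node.parent_edges[0].gamma = 1.0 - g[1]
            elif g[1] is None and g[0] is not None:
                node.parent_edges[1].gamma = 1.0 - g[0]
        stack.extend(e.child for e in node.child_edges)
    return root
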