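"""Rooted gene trees: data model, newick I/O, rooting and clade queries.

The central object is :class:`GeneTree`, a rooted tree whose tips carry gene
identifiers mapped to species names.  Branch lengths are in substitutions per
site (or coalescent units for simulated trees) and internal edges may carry a
bootstrap-style support value in [0, 100].  Parsing of plain newick goes
through dendropy; the lightweight node structure here keeps simulation and
batch classification fast.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

from .errors import (
    MissingSpeciesError,
    NewickParseError,
    RootingError,
    SpeciesMappingError,
)

__all__ = [
    "TreeNode",
    "GeneTree",
    "GroupScheme",
    "read_newick",
    "write_newick",
    "MissingBranchLengthWarning",
]


class MissingBranchLengthWarning(UserWarning):
    """Emitted when a newick tree lacks branch lengths (treated as 0)."""


class TreeNode:
    """A node of a rooted tree.

    ``length`` is the length of the edge above the node (0.0 at the root),
    ``support`` the support of that same edge (internal edges only).
    """

    __slots__ = ("children", "parent", "label", "length", "support")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.label = label
        self.length = length
        self.support = support

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        mapping: dict[int, TreeNode] = {}
        for node in self.postorder():
            clone = TreeNode(node.label, node.length, node.support)
            for child in node.children:
                clone.add(mapping[id(child)])
            mapping[id(node)] = clone
        return mapping[id(self)]


class GeneTree:
    """Rooted gene tree with a tip -> species mapping.

    Parameters
    ----------
    root:
        Root :class:`TreeNode` of the topology.
    tip_species:
        Mapping from tip label (gene identifier) to species name.  When
        omitted, tip labels are taken to *be* species names.
    tree_id:
        Opaque identifier, carried through the pipeline.
    gene_location:
        Optional ``(chromosome, position)`` for the chromosome-distribution
        test of the topology census.
    flags:
        Free-form annotation set (e.g. ``"outgroup_non_monophyletic"``).
    """

    __slots__ = ("root", "tip_species", "tree_id", "gene_location", "flags")

    def __init__(self, root: TreeNode,
                 tip_species: Mapping[str, str] | None = None,
                 tree_id: str | None = None,
                 gene_location: tuple[str, int] | None = None,
                 flags: set[str] | None = None,
                 validate: bool = True):
        self.root = root
        leaves = root.leaves()
        if tip_species is None:
            tip_species = {leaf.label: leaf.label for leaf in leaves}
        self.tip_species = dict(tip_species)
        self.tree_id = tree_id
        self.gene_location = gene_location
        self.flags: set[str] = set(flags) if flags else set()
        if validate:
            self._validate(leaves)

    def _validate(self, leaves: list[TreeNode]) -> None:
        for leaf in leaves:
            if leaf.label is None:
                raise SpeciesMappingError("unlabeled tip in tree")
            if leaf.label not in self.tip_species:
                raise SpeciesMappingError(
                    f"tip {leaf.label!r} has no species assignment")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError(
                    f"support {node.support} outside [0, 100]")

    # -- basic queries ------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def species_of(self, tip_label: str) -> str:
        return self.tip_species[tip_label]

    def species_set(self) -> set[str]:
        return {self.tip_species[l] for l in self.leaf_labels()}

    def n_tips(self) -> int:
        return len(self.leaves())

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), dict(self.tip_species),
                        self.tree_id, self.gene_location, set(self.flags),
                        validate=False)

    def depths(self) -> dict[TreeNode, float]:
        """Cumulative branch length from the root to each node."""
        out: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.root.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def clade_tip_sets(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """Every node paired with the frozenset of tip labels below it."""
        sets: dict[int, frozenset[str]] = {}
        result = []
        for node in self.root.postorder():
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            result.append((node, s))
        return result

    def mrca(self, tip_labels: Iterable[str]) -> TreeNode:
        targets = set(tip_labels)
        missing = targets - set(self.leaf_labels())
        if missing:
            raise MissingSpeciesError(f"tips absent from tree: {sorted(missing)}")
        best = None
        for node, tips in self.clade_tip_sets():
            if targets <= tips and (best is None or len(tips) < best[1]):
                best = (node, len(tips))
        return best[0]

    # -- species-level operations ------------------------------------------

    def is_monophyletic(self, species_set: Iterable[str]) -> bool:
        """True iff some clade contains exactly the tips of ``species_set``.

        Multi-copy species are handled at the induced-tip level: the clade
        must contain *every* tip whose species lies in the set and no other.
        """
        species = set(species_set)
        if not species:
            raise MissingSpeciesError("empty species set")
        present = self.species_set()
        missing = species - present
        if missing:
            raise MissingSpeciesError(
                f"species absent from tree: {sorted(missing)}")
        target = frozenset(l for l in self.leaf_labels()
                           if self.tip_species[l] in species)
        return any(tips == target for _, tips in self.clade_tip_sets())

    def prune_to_species(self, keep_species: Iterable[str]) -> "GeneTree":
        """Restrict to tips of the given species; suppress unary nodes.

        Merged edges sum their lengths; the support of a merged edge is the
        minimum of the non-missing supports along the merged path.
        """
        keep = set(keep_species)
        return self.prune_to_tips(
            [l for l in self.leaf_labels() if self.tip_species[l] in keep])

    def prune_to_tips(self, keep_tips: Iterable[str]) -> "GeneTree":
        keep = set(keep_tips)
        if not keep:
            raise MissingSpeciesError("pruning would remove every tip")
        built: dict[int, TreeNode | None] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                if node.label in keep:
                    built[id(node)] = TreeNode(node.label, node.length or 0.0)
                else:
                    built[id(node)] = None
                continue
            kids = [built[id(c)] for c in node.children if built[id(c)] is not None]
            if not kids:
                built[id(node)] = None
            elif len(kids) == 1:
                child = kids[0]
                child.length += node.length or 0.0
                if node.support is not None:
                    child.support = (node.support if child.support is None
                                     else min(child.support, node.support))
                built[id(node)] = child
            else:
                clone = TreeNode(node.label if not _is_number(node.label) else None,
                                 node.length or 0.0, node.support)
                for kid in kids:
                    clone.add(kid)
                built[id(node)] = clone
        new_root = built[id(self.root)]
        new_root.parent = None
        new_root.length = 0.0
        species = {l: self.tip_species[l] for l in keep}
        return GeneTree(new_root, species, self.tree_id, self.gene_location,
                        set(self.flags), validate=False)

    # -- serialization ------------------------------------------------------

    def write_newick(self, include_support: bool = True) -> str:
        return write_newick(self, include_support=include_support)

    def topology_key(self) -> tuple:
        """Canonical hashable form of the rooted topology (labels only)."""
        def key(node: TreeNode):
            if node.is_leaf:
                return (node.label,)
            return tuple(sorted((key(c) for c in node.children), key=str))
        return key(self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GeneTree {self.tree_id or ''} with {self.n_tips()} tips>"


@dataclass(frozen=True)
class GroupScheme:
    """Assignment of species to named groups, with a designated outgroup.

    ``groups`` maps species name -> group label (e.g. ``"monocots"``);
    ``outgroup`` names the group whose members root the trees.
    """

    groups: Mapping[str, str]
    outgroup: str

    def __post_init__(self):
        if self.outgroup not in set(self.groups.values()):
            raise ValueError(
                f"outgroup label {self.outgroup!r} matches no species")

    def species_in(self, label: str) -> set[str]:
        return {sp for sp, g in self.groups.items() if g == label}

    def group_of(self, species: str) -> str | None:
        return self.groups.get(species)

    @property
    def outgroup_species(self) -> set[str]:
        return self.species_in(self.outgroup)


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _is_number(text) -> bool:
    if text is None:
        return False
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def read_newick(text: str,
                species_map: Mapping[str, str] | None = None,
                support_dialect: str = "internal_label",
                tree_id: str | None = None,
                gene_location: tuple[str, int] | None = None) -> GeneTree:
    """Parse a newick string into a :class:`GeneTree`.

    ``support_dialect`` selects where edge supports live: ``"internal_label"``
    (the IQ-TREE convention, numeric internal node labels) or ``"comment"``
    (a numeric ``[&...]`` comment attached to the node).
    """
    if support_dialect not in ("internal_label", "comment"):
        raise ValueError(f"unknown support dialect {support_dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False)
    except Exception as exc:  # dendropy raises several error types
        offset = text.find(";")
        raise NewickParseError(
            f"malformed newick (near character offset "
            f"{offset if offset >= 0 else len(text)}): {exc}") from exc

    missing_length = False
    converted: dict[int, TreeNode] = {}
    for dnode in dtree.postorder_node_iter():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                missing_length = True
            length = 0.0
        support = None
        if dnode.child_nodes():
            raw = None
            if support_dialect == "internal_label":
                raw = dnode.label
            else:
                for comment in (dnode.edge.comments or []) + (dnode.comments or []):
                    stripped = comment.strip("&[] ")
                    if "=" in stripped:  # e.g. "&support=95"
                        stripped = stripped.rsplit("=", 1)[1]
                    if _is_number(stripped):
                        raw = stripped
                        break
            if _is_number(raw):
                support = float(raw)
                label = None
        node = TreeNode(label, float(length), support)
        for child in dnode.child_nodes():
            node.add(converted[id(child)])
        converted[id(dnode)] = node
    root = converted[id(dtree.seed_node)]
    if missing_length:
        warnings.warn("newick tree has edges without branch lengths; "
                      "treating them as 0", MissingBranchLengthWarning,
                      stacklevel=2)

    tips = [n.label for n in root.leaves()]
    if species_map is not None:
        missing = [t for t in tips if t not in species_map]
        if missing:
            raise SpeciesMappingError(
                f"tips without species assignment: {sorted(missing)}")
        tip_species = {t: species_map[t] for t in tips}
    else:
        tip_species = {t: t for t in tips}
    return GeneTree(root, tip_species, tree_id=tree_id,
                    gene_location=gene_location)


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: GeneTree, include_support: bool = True) -> str:
    """Serialize a :class:`GeneTree` (supports as internal node labels)."""
    out = io.StringIO()

    def visit(node: TreeNode, is_root: bool) -> None:
        if node.is_leaf:
            out.write(node.label)
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                visit(child, False)
            out.write(")")
            if include_support and node.support is not None:
                sup = node.support
                out.write(f"{sup:g}")
            elif node.label:
                out.write(node.label)
        if not is_root:
            out.write(f":{_format_length(node.length or 0.0)}")

    visit(tree.root, True)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# outgroup rooting
# ---------------------------------------------------------------------------

def root_by_outgroup(tree: GeneTree, scheme: GroupScheme) -> GeneTree:
    """Root a gene tree on the edge best separating outgroup from ingroup.

    If the outgroup is monophyletic in the unrooted topology the root is
    placed on the edge subtending it (splitting that edge at its midpoint);
    otherwise the edge maximizing outgroup/ingroup separation is chosen and
    the result is flagged ``"outgroup_non_monophyletic"``.  The operation is
    idempotent: a tree already rooted at the optimal edge is returned as an
    unchanged copy.
    """
    out_species = scheme.outgroup_species
    tips = tree.leaf_labels()
    out_tips = frozenset(t for t in tips if tree.tip_species[t] in out_species)
    if not out_tips:
        raise RootingError("tree contains no outgroup tips")
    if len(out_tips) == len(tips):
        raise RootingError("every tip belongs to the outgroup")
    n = len(tips)

    clades = tree.clade_tip_sets()
    all_tips = frozenset(tips)

    def score(below: frozenset[str]) -> int:
        # correctly-separated tip count for the better orientation
        inside = len(below & out_tips) + len((all_tips - below) - out_tips)
        flipped = len((all_tips - below) & out_tips) + len(below - out_tips)
        return max(inside, flipped)

    best_node, best_score = None, -1
    for node, below in clades:
        if node is tree.root:
            continue
        s = score(below)
        if s > best_score:
            best_node, best_score = node, s
    perfect = best_score == n

    # already optimally rooted? (a root child realizes the best bipartition)
    for child in tree.root.children:
        below = next(s for nd, s in clades if nd is child)
        if score(below) == best_score and (below == out_tips
                                           or (all_tips - below) == out_tips
                                           or not perfect):
            result = tree.copy()
            if not perfect:
                result.flags.add("outgroup_non_monophyletic")
            return result

    result = tree.copy()
    # locate the matching node in the copy via parallel postorder
    pairs = list(zip(tree.root.postorder(), result.root.postorder()))
    target = next(c for o, c in pairs if o is best_node)
    _reroot_on_edge(result, target)
    if not perfect:
        result.flags.add("outgroup_non_monophyletic")
    return result


def _reroot_on_edge(tree: GeneTree, node: TreeNode, fraction: float = 0.5) -> None:
    """Re-root ``tree`` in place on the edge above ``node``."""
    old_parent = node.parent
    if old_parent is None:
        return
    edge_len = node.length or 0.0
    new_root = TreeNode()

    old_parent.children.remove(node)
    node.parent = None

    # reverse the path old_parent -> ... -> old root
    path = []
    p = old_parent
    while p is not None:
        path.append(p)
        p = p.parent
    # walk from old_parent upward, reversing parent pointers
    prev_len = None
    prev_sup = None
    for i, cur in enumerate(path):
        nxt = path[i + 1] if i + 1 < len(path) else None
        cur_len, cur_sup = cur.length, cur.support
        if nxt is not None:
            nxt.children.remove(cur)
        if i == 0:
            cur.parent = None  # attached to new_root below
        else:
            path[i - 1].add(cur)
            cur.length = prev_len
            cur.support = prev_sup
        prev_len, prev_sup = cur_len, cur_sup

    new_root.add(node)
    node.length = edge_len * fraction
    new_root.add(old_parent)
    old_parent.length = edge_len * (1.0 - fraction)
    old_parent.support = node.support

    # suppress the old root if it became a unary node
    _suppress_unary(new_root)
    tree.root = new_root


def _suppress_unary(root: TreeNode) -> None:
    for node in list(root.postorder()):
        if node is root or len(node.children) != 1:
            continue
        child = node.children[0]
        child.length = (child.length or 0.0) + (node.length or 0.0)
        if child.support is None:
            child.support = node.support
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent
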