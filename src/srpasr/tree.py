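"""Rooted phylogenetic trees.

A light tree structure tailored to the pruning kernels: nodes carry parent
links, branch lengths (substitutions/site), optional support values in [0, 1]
and optional names.  Newick parsing/writing is delegated to dendropy; internal
node labels that parse as numbers in [0, 1] are interpreted as posterior
supports, anything else as node names (nodes of interest such as ``preLUCA``
or ``LUCA_Ffh`` are named this way).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Optional

import dendropy

from .errors import DomainError, PruneError, TreeError


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 support: Optional[float] = None):
        if length < 0 or length != length:
            raise TreeError(f"branch length {length} is negative or not finite")
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or '?'} {kind} t={self.length:g}>"


class PhyloTree:
    """Rooted tree with a designated root node."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        #: False when the input had a trifurcating (unrooted-style) root;
        #: accepted but flagged so callers can warn.
        self.rooted = rooted
        self._validate()

    def _validate(self):
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {dup[:5]}")
        if any(n is None for n in names):
            raise TreeError("unnamed leaf in tree")

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r}")

    def internal_names(self) -> list[str]:
        return [n.name for n in self.postorder() if not n.is_leaf and n.name]

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=True,
                                   preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"invalid Newick: {exc}") from exc
        return cls._from_dendropy(dt)

    @classmethod
    def from_newick_file(cls, path: str | Path) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(path=str(path), schema="newick",
                                   suppress_internal_node_taxa=True,
                                   preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"invalid Newick in {path}: {exc}") from exc
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            name, support = label, None
            if label is not None and dn.child_nodes():
                try:
                    val = float(label)
                except ValueError:
                    pass
                else:
                    if 0.0 <= val <= 1.0:
                        name, support = None, val
            length = dn.edge.length if dn.edge.length is not None else 0.0
            node = Node(name=name, length=length, support=support)
            for child in dn.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dt.seed_node)
        rooted = len(root.children) <= 2
        return cls(root, rooted=rooted)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                label = node.name if node.name is not None else (
                    format(node.support, "g") if node.support is not None else "")
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + (label or "")
            if node is self.root:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(name=n.name, length=n.length, support=n.support)
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root), rooted=self.rooted)


def prune_tree(tree: PhyloTree, keep: set[str] | list[str],
               protected: Optional[set[str]] = None) -> PhyloTree:
    """Restrict ``tree`` to the leaves in ``keep``.

    Unary internal nodes introduced by the pruning are suppressed with their
    branch lengths summed onto the surviving child.  ``protected`` names the
    internal nodes of interest whose ancestral state must stay identifiable:
    if pruning empties one side of such a node (so it would be suppressed) a
    :class:`PruneError` is raised.  By default every named internal node is
    protected; pass an explicit (possibly empty) set to protect only the
    nodes a downstream analysis targets.  The root is always protected: with
    one side gone it would become a different ancestral point.
    """
    keep = set(keep)
    if len(keep) < 2:
        raise DomainError("prune_tree requires at least 2 leaves to keep")
    missing = keep - set(tree.leaf_names())
    if missing:
        raise PruneError(f"keep set contains unknown leaves: {sorted(missing)[:5]}")

    work = tree.copy()

    def is_protected(node: Node) -> bool:
        if node is work.root:
            return True
        if node.name is None:
            return False
        return protected is None or node.name in protected

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.name in keep:
                return Node(name=node.name, length=node.length, support=node.support)
            return None
        kept = [c for c in (rebuild(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            if is_protected(node):
                raise PruneError(
                    f"named node {node.name or 'root'!r} lost all descendants "
                    "on one side during pruning")
            child = kept[0]
            child.length += node.length
            return child
        new = Node(name=node.name, length=node.length, support=node.support)
        for c in kept:
            new.add(c)
        return new

    new_root = rebuild(work.root)
    if new_root is None or new_root.is_leaf:
        raise PruneError("pruning left fewer than 2 leaves")
    new_root.length = 0.0
    new_root.parent = None
    return PhyloTree(new_root, rooted=tree.rooted)
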