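"""Minimal rooted-tree structure shared by the generator and the graph fitter.

Branch lengths are drift amounts (dimensionless, >= 0).  Newick text is the
interchange format; dendropy handles parsing.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["Node", "parse_newick"]


class Node:
    """A rooted tree node; ``length`` is the branch above this node."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.traverse() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def traverse(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.traverse())

    def ancestors(self) -> list["Node"]:
        """Path of nodes from this node's parent up to the root."""
        out = []
        node = self.parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def find(self, name: str) -> "Node":
        for n in self.traverse():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def copy(self) -> "Node":
        clone = Node(self.name, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        label = self.name or ""
        if self.is_leaf:
            body = label
        else:
            body = "(" + ",".join(c._newick_part() for c in self.children) + ")" + label
        if self.parent is not None:
            body += f":{self.length:.10g}"
        return body

    def bipartitions(self) -> set[frozenset]:
        """Leaf-name sets below each internal edge (non-trivial splits)."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for n in self.traverse():
            if n is self or n.is_leaf:
                continue
            below = frozenset(n.leaf_names())
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(min(below, all_leaves - below, key=sorted))
        return out

    def __repr__(self) -> str:
        return f"Node({self.to_newick()!r})"


def _from_dendropy(dnode) -> Node:
    name = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(name, dnode.edge.length or 0.0)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str) -> Node:
    tree = dendropy.Tree.get(data=text, schema="newick")
    return _from_dendropy(tree.seed_node)
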