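"""Minimal rooted-tree structure with Newick I/O and bipartition utilities.

Trees are stored rooted; unrooted semantics (bipartitions, re-rooting) are
provided on top.  Supports are attached to internal nodes and interpreted
as the support of the edge above the node.
"""

from __future__ import annotations

from typing import Iterator

__all__ = ["Node", "Tree", "parse_newick"]


class Node:
    __slots__ = ("children", "parent", "label", "length", "support")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.label = label
        self.length = length
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- basic queries ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            for child in node.children:
                new.add(clone(child))
            return new

        return Tree(clone(self.root))

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as frozensets excluding a reference taxon.

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest leaf is the canonical representation.
        Returns a set, or a ``{bipartition: support}`` dict if requested.
        """
        names = set(self.leaf_names())
        ref = min(names)
        result: dict = {}
        for node in self.postorder():
            if node.is_leaf or node.parent is None:
                continue
            clade = frozenset(l.label for l in node.leaves())
            side = names - clade if ref in clade else clade
            if 2 <= len(side) <= len(names) - 2:
                result[frozenset(side)] = node.support
        return result if with_support else set(result)

    # -- newick -------------------------------------------------------------

    def newick(self, lengths: bool = True, supports: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if supports and node.support is not None:
                    lab = f"{node.support:g}"
                elif node.label:
                    lab = node.label
                s = f"({inner}){lab}"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick(supports=True) + "\n")


def parse_newick(text: str) -> Tree:
    """Parse a Newick string; internal labels are read as supports when numeric."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.label = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at {pos}")
    return Tree(root)
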