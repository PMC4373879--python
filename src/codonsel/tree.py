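"""Phylogenies with per-branch class marks.

Trees are read from Newick with an optional ``#<int>`` suffix on any tip or
clade, the convention used by codon-model software to designate foreground
branches (class 0 = background).  The mark applies to the branch subtending
the labelled node.  This dialect is not standard Newick, so the parser is
implemented here rather than delegated to a general tree library.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class TreeError(ValueError):
    pass


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    mark: int = 0
    children: list = field(default_factory=list)
    parent: "Node | None" = None
    index: int = -1  # assigned by LabeledTree

    @property
    def is_tip(self) -> bool:
        return not self.children


class LabeledTree:
    """Rooted tree with branch lengths and integer branch-class marks.

    Nodes are indexed in postorder (root last); ``node.index`` identifies the
    branch from the node to its parent.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self._assign_indices()

    def _assign_indices(self):
        self.nodes = []

        def post(node):
            for ch in node.children:
                ch.parent = node
                post(ch)
            node.index = len(self.nodes)
            self.nodes.append(node)

        self.root.parent = None
        post(self.root)

    # -- basic queries -------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips]

    @property
    def branches(self) -> list[Node]:
        """Non-root nodes; each identifies the branch to its parent."""
        return [n for n in self.nodes if n.parent is not None]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def find(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r}")

    def mrca(self, names) -> Node:
        """Most recent common ancestor of the named tips."""
        paths = []
        for nm in names:
            node = self.find(nm)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        if anc is None:
            raise TreeError("no common ancestor")
        return anc

    def clade_tips(self, node: Node) -> list[str]:
        out = []

        def walk(n):
            if n.is_tip:
                out.append(n.name)
            for ch in n.children:
                walk(ch)

        walk(node)
        return out

    def is_ancestor(self, a: Node, b: Node) -> bool:
        node = b.parent
        while node is not None:
            if node is a:
                return True
            node = node.parent
        return False

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches)

    def set_lengths(self, lengths) -> None:
        """Assign branch lengths from an array indexed like ``branches``."""
        for n, t in zip(self.branches, lengths):
            n.length = float(t)

    def get_lengths(self):
        return [n.length for n in self.branches]

    def copy(self) -> "LabeledTree":
        return read_tree(self.to_newick(marks=True))

    def check_against(self, taxa) -> None:
        tree_set, aln_set = set(self.tip_names), set(taxa)
        if tree_set != aln_set:
            missing = sorted(aln_set - tree_set)
            extra = sorted(tree_set - aln_set)
            raise TreeError(f"tip/taxa mismatch (missing from tree: {missing}; extra: {extra})")

    # -- serialization -------------------------------------------------

    def to_newick(self, marks: bool = True, lengths: bool = True) -> str:
        def fmt(node):
            if node.is_tip:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
                if node.name:
                    s += node.name
            if marks and node.mark and node.parent is not None:
                s += f" #{node.mark}"
            if lengths and node.length is not None and node.parent is not None:
                s += f":{node.length:.6g}"
            return s

        return fmt(self.root) + ";"


def read_tree(newick: str) -> LabeledTree:
    """Parse Newick text with optional ``#<int>`` branch-class marks."""
    text = newick.strip()
    if not text.endswith(";"):
        raise TreeError("newick must end with ';'")
    text = text[:-1]
    pos = 0

    def error(msg):
        raise TreeError(f"parse error at position {pos}: {msg}")

    def skip_ws():
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def parse_node():
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                skip_ws()
                if pos >= len(text):
                    error("unbalanced parentheses")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {text[pos]!r}")
        # optional label
        start = pos
        while pos < len(text) and text[pos] not in "():,;#" and not text[pos].isspace():
            pos += 1
        if pos > start:
            node.name = text[start:pos]
        skip_ws()
        # optional branch-class mark
        if pos < len(text) and text[pos] == "#":
            pos += 1
            start = pos
            while pos < len(text) and text[pos].isdigit():
                pos += 1
            if pos == start:
                error("dangling '#' without integer mark")
            node.mark = int(text[start:pos])
        skip_ws()
        # optional branch length
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and (text[pos].isdigit() or text[pos] in ".eE+-"):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                error("malformed branch length")
        return node

    root = parse_node()
    skip_ws()
    if pos != len(text):
        error("trailing characters after tree")
    if root.is_tip and root.name is None:
        error("empty tree")
    return LabeledTree(root)
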