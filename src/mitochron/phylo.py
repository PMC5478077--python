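"""Rooted/unrooted phylogenetic trees with branch lengths, supports and ages.

The tree container used across the package: neighbor-joining and maximum
likelihood produce :class:`PhyloTree`; relative-rate dating decorates its
nodes with rates and ages (see :mod:`mitochron.reltime`).  Newick text is
written here (with optional support or age decorations) and parsed with a
small recursive-descent reader that understands quoted labels, so taxon
names such as ``SNJ R. roxellana`` survive a round trip.
"""

from __future__ import annotations

import itertools
import re
from typing import Callable, Iterable, Iterator, Optional

__all__ = ["Node", "PhyloTree", "parse_newick", "write_newick"]

_NEWICK_META = re.compile(r"[\s()\[\],:;'\"]")


class Node:
    """One tree node. ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("label", "length", "parent", "children", "support", "age",
                 "rate", "rel_height", "ci")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.support: Optional[float] = None   # percent, internal nodes
        self.age: Optional[float] = None       # absolute age (Ma) after calibration
        self.rate: Optional[float] = None      # relative lineage rate (branch above)
        self.rel_height: Optional[float] = None  # relative node height
        self.ci: Optional[tuple] = None        # (low, high) age CI in Ma

    # -- structure ---------------------------------------------------------
    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.label, self.length)
        dup.support, dup.age, dup.rate = self.support, self.age, self.rate
        dup.rel_height, dup.ci = self.rel_height, self.ci
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class PhyloTree:
    """A phylogenetic tree; ``rooted`` records whether the root is meaningful.

    Unrooted trees are stored with an arbitrary (usually trifurcating) root
    node; topology comparisons use bipartitions and so ignore root placement.
    """

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted

    # -- basic queries -----------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def taxa(self) -> list[str]:
        return sorted(self.root.leaf_labels())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(label)

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of leaf labels (rooted tree)."""
        want = set(labels)
        for node in self.postorder():
            if want <= node.leaf_labels():
                return node
        raise ValueError(f"labels {sorted(want)} not all present")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.length is not None)

    # -- topology ----------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the smaller-or-canonical side.

        Each internal edge splits the taxa in two; the split is represented
        by the side not containing the alphabetically first taxon, making
        the representation root-invariant.
        """
        all_taxa = self.root.leaf_labels()
        anchor = min(all_taxa)
        splits: set[frozenset] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_labels()
            if anchor in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                splits.add(frozenset(side))
        return splits

    def same_topology(self, other: "PhyloTree") -> bool:
        """Unrooted topology equality: same taxa and same bipartition set."""
        if self.root.leaf_labels() != other.root.leaf_labels():
            return False
        return self.bipartitions() == other.bipartitions()

    def has_clade(self, labels: Iterable[str]) -> bool:
        """True if `labels` form a clade (rooted) / a split side (unrooted)."""
        want = frozenset(labels)
        all_taxa = self.root.leaf_labels()
        for node in self.postorder():
            side = node.leaf_labels()
            if side == want or (not self.rooted and all_taxa - side == want):
                return True
        return False

    # -- manipulation ------------------------------------------------------
    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation (new tree).

        The two root branches are merged into one edge carried by the leaf
        (or either) side; with two leaves the tree is returned unchanged
        apart from the rooted flag.
        """
        tree = self.copy()
        tree.rooted = False
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        absorb = b if not b.is_leaf() else a
        if absorb.is_leaf():
            return tree
        keep = a if absorb is b else b
        merged = (a.length or 0.0) + (b.length or 0.0)
        new_root = Node()
        keep.parent = None
        keep.length = merged
        new_root.add_child(keep)
        for child in list(absorb.children):
            child.parent = None
            new_root.add_child(child)
        tree.root = new_root
        return tree

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "PhyloTree":
        """Root the tree on the edge above `child`, splitting its length."""
        if child.parent is None:
            raise ValueError("cannot root on the root's (nonexistent) edge")
        blen = child.length if child.length is not None else 0.0
        upper = blen * (1.0 - fraction)
        lower = blen * fraction
        new_root = Node()
        old_parent = child.parent
        old_parent.children.remove(child)
        child.parent = None
        # reverse the path from old_parent up to the old root
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        orig_len = [n.length for n in path]
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        for i in range(len(path) - 1):
            path[i].add_child(path[i + 1])
            path[i + 1].length = orig_len[i]   # edge path[i] <-> path[i+1]
        path[0].parent = None
        old_root = path[-1]
        if len(old_root.children) == 1 and len(path) > 1:
            # suppress the now degree-2 old root
            only = old_root.children[0]
            grand = old_root.parent
            only.length = (only.length or 0.0) + (old_root.length or 0.0)
            grand.children.remove(old_root)
            grand.add_child(only)
        new_root.add_child(child)
        new_root.add_child(old_parent)
        child.length = lower
        old_parent.length = upper
        if len(old_parent.children) == 1 and old_parent is not child:
            # old_parent degenerated (e.g. binary node whose other side left)
            only = old_parent.children[0]
            only.length = (only.length or 0.0) + (old_parent.length or 0.0)
            new_root.children.remove(old_parent)
            new_root.add_child(only)
        return PhyloTree(new_root, rooted=True)

    # -- newick ------------------------------------------------------------
    def to_newick(self, decorations: Optional[str] = None,
                  digits: int = 10) -> str:
        return write_newick(self, decorations=decorations, digits=digits)

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "PhyloTree":
        return parse_newick(text, rooted=rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.leaves())} leaves rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick serialization


def _quote_label(label: str) -> str:
    if _NEWICK_META.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float, digits: int) -> str:
    return f"{x:.{digits}g}"


def write_newick(tree: PhyloTree, decorations: Optional[str] = None,
                 digits: int = 10) -> str:
    """Serialize a tree to Newick.

    decorations: None, "support" or "age" — written as internal node labels.
    Branch lengths are emitted with `digits` significant digits (>= 8 by
    default policy so round trips preserve them to 1e-9 relative).
    """
    if decorations not in (None, "support", "age"):
        raise ValueError(f"unknown decoration {decorations!r}")

    def node_text(node: Node) -> str:
        if node.is_leaf():
            text = _quote_label(node.label or "")
        else:
            inner = ",".join(node_text(c) for c in node.children)
            label = ""
            if decorations == "support" and node.support is not None:
                label = _fmt_length(node.support, digits)
            elif decorations == "age" and node.age is not None:
                label = _fmt_length(node.age, digits)
            elif node.label:
                label = _quote_label(node.label)
            text = f"({inner}){label}"
        if node.length is not None:
            text += f":{_fmt_length(node.length, digits)}"
        return text

    return node_text(tree.root) + ";"


def parse_newick(text: str, rooted: bool = False) -> PhyloTree:
    """Parse a Newick string (quoted labels, branch lengths, node labels)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> ValueError:
        return ValueError(f"newick parse error at {pos}: {msg}")

    def parse_label() -> Optional[str]:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise error("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos].strip()
        return label or None

    def parse_length() -> Optional[float]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in "+-.eE"):
                pos += 1
            return float(s[start:pos])
        return None

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected {s[pos]!r}")
            label = parse_label()
            if label is not None:
                # internal label: numeric labels read back as supports
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            node.label = parse_label()
        node.length = parse_length()
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing newick content at {pos}: {s[pos:]!r}")
    return PhyloTree(root, rooted=rooted)
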