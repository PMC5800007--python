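"""Rooted/unrooted phylogeny data model, Newick I/O and bipartition algebra.

Trees carry a ``length_units`` tag so that generation-scaled species trees,
substitution-scaled gene trees and coalescent-unit summary trees cannot be
mixed silently; unit conversions are explicit operations elsewhere.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import InputError, NewickParseError

LENGTH_UNITS = (
    "generations",
    "substitutions_per_site",
    "coalescent_units",
    "unitless",
)


class Node:
    """A tree node; tips carry a unique label, internal nodes may carry support labels."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, length={self.length})"


class Tree:
    """A phylogeny with typed branch-length units.

    ``rooted`` distinguishes a genuinely rooted tree from the conventional
    representation of an unrooted tree as a basal multifurcation.
    """

    def __init__(self, root: Node, rooted: bool = True, length_units: str = "unitless"):
        if length_units not in LENGTH_UNITS:
            raise InputError(f"unknown length_units {length_units!r}")
        self.root = root
        self.rooted = rooted
        self.length_units = length_units

    # -- basic accessors ---------------------------------------------------
    def nodes(self) -> list[Node]:
        return list(self.root.preorder())

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        for n in self.nodes():
            if n.children and len(n.children) != 2 and n is not self.root:
                return False
        if self.root.children and len(self.root.children) not in (2, 3):
            return False
        if self.rooted and self.root.children and len(self.root.children) != 2:
            return False
        return True

    def has_branch_lengths(self) -> bool:
        non_root = [n for n in self.nodes() if n is not self.root]
        return bool(non_root) and all(n.length is not None for n in non_root)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), rooted=self.rooted, length_units=self.length_units)

    def validate(self) -> None:
        labels = self.tip_labels()
        if any(not lab for lab in labels):
            raise InputError("tip labels must be non-empty")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InputError(f"duplicate tip labels: {dupes}")
        non_root = [n for n in self.nodes() if n is not self.root]
        lengths = [n.length for n in non_root]
        if any(l is not None for l in lengths) and any(l is None for l in lengths):
            raise InputError("branch lengths must be all present or all absent")
        if any(l is not None and l < 0 for l in lengths):
            raise InputError("negative branch length")
        for n in self.nodes():
            if n.children and len(n.children) < 2:
                raise InputError("internal node with a single child")

    # -- heights -----------------------------------------------------------
    def node_heights(self) -> dict[Node, float]:
        """Height of each node above the tips, assuming an ultrametric tree.

        For non-ultrametric trees this returns the maximum tip distance below
        each node (still useful for rooting / smoothing).
        """
        heights: dict[Node, float] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                heights[node] = 0.0
            else:
                heights[node] = max(
                    heights[c] + (c.length or 0.0) for c in node.children
                )
        return heights

    def max_height(self) -> float:
        return self.node_heights()[self.root]

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = []

        def walk(node: Node, d: float) -> None:
            if node.is_leaf:
                depths.append(d)
            for c in node.children:
                walk(c, d + (c.length or 0.0))

        walk(self.root, 0.0)
        if not depths:
            return True
        span = max(depths) - min(depths)
        scale = max(abs(max(depths)), 1e-300)
        return span <= rel_tol * scale or span <= 1e-12

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.n_tips} tips, rooted={self.rooted}, units={self.length_units})"


class Bipartition:
    """An unrooted split of the tip set into two non-empty sides.

    Canonical form: the side containing the lexicographically smallest label
    is stored first, so equal splits compare and hash equal.
    """

    __slots__ = ("side_a", "side_b")

    def __init__(self, side_a, side_b):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise InputError("bipartition sides must be non-empty")
        if a & b:
            raise InputError("bipartition sides must be disjoint")
        smallest = min(a | b)
        if smallest in a:
            self.side_a, self.side_b = a, b
        else:
            self.side_a, self.side_b = b, a

    @property
    def sides(self) -> tuple[frozenset, frozenset]:
        return (self.side_a, self.side_b)

    def full_set(self) -> frozenset:
        return self.side_a | self.side_b

    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side_a == other.side_a
            and self.side_b == other.side_b
        )

    def __hash__(self) -> int:
        return hash((self.side_a, self.side_b))

    def key(self) -> str:
        """Stable text key: smaller side (ties: canonical side) sorted, pipe, rest."""
        return ",".join(sorted(self.side_a)) + "|" + ",".join(sorted(self.side_b))

    def __repr__(self) -> str:
        return f"Bipartition({self.key()})"


def are_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Two splits on the same tip set can co-occur in one tree iff one of the
    four pairwise side intersections is empty."""
    return (
        not (b1.side_a & b2.side_a)
        or not (b1.side_a & b2.side_b)
        or not (b1.side_b & b2.side_a)
        or not (b1.side_b & b2.side_b)
    )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[]' \t\n")


def read_newick(text: str, length_units: str = "unitless") -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Malformed input raises :class:`NewickParseError` naming the character
    offset. Internal node labels (e.g. support values) are retained verbatim.
    A root with two children is flagged rooted; a basal multifurcation is
    treated as the conventional unrooted representation.
    """
    s = text.strip()
    pos = 0

    def error(msg: str, at: int) -> NewickParseError:
        return NewickParseError(f"{msg} at offset {at}", offset=at)

    def parse_label() -> Optional[str]:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos] if pos > start else None

    def parse_length() -> Optional[float]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE0123456789"):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error("invalid branch length", start) from None
        return None

    def parse_subtree() -> Node:
        nonlocal pos
        if pos >= len(s):
            raise error("unexpected end of input", pos)
        if s[pos] == "(":
            open_at = pos
            pos += 1
            node = Node()
            node.add_child(parse_subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add_child(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("unbalanced parenthesis opened", open_at)
            pos += 1
            node.label = parse_label()
            node.length = parse_length()
            return node
        node = Node()
        node.label = parse_label()
        if node.label is None:
            raise error(f"expected label, found {s[pos]!r}", pos)
        node.length = parse_length()
        return node

    if not s:
        raise error("empty Newick string", 0)
    root = parse_subtree()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';'", pos)
    if s[pos + 1 :].strip():
        raise error("trailing characters after ';'", pos + 1)
    rooted = len(root.children) == 2 or root.is_leaf
    tree = Tree(root, rooted=rooted, length_units=length_units)
    tree.validate()
    return tree


def write_newick(tree: Tree, precision: int = 10) -> str:
    """Serialize to Newick with deterministic child ordering.

    Children are sorted by their smallest descendant tip label so the same
    topology always yields the same string (diff-stable snapshots).
    """

    def min_label(node: Node) -> str:
        return min(t.label for t in node.leaves())

    def fmt(x: float) -> str:
        return format(x, f".{precision}g")

    def render(node: Node, with_length: bool) -> str:
        if node.is_leaf:
            body = node.label
        else:
            kids = sorted(node.children, key=min_label)
            body = "(" + ",".join(render(c, True) for c in kids) + ")"
            if node.label:
                body += node.label
        if with_length and node.length is not None:
            body += ":" + fmt(node.length)
        return body

    return render(tree.root, False) + ";"


def read_newick_file(path, length_units: str = "unitless") -> list[Tree]:
    """One tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_newick(line, length_units=length_units))
    return trees


def write_newick_file(trees: Sequence[Tree], path, precision: int = 10) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, precision=precision) + "\n")


# ---------------------------------------------------------------------------
# Bipartitions and distances on trees
# ---------------------------------------------------------------------------


def bipartition_set(tree: Tree) -> frozenset[Bipartition]:
    """Non-trivial unrooted splits, one per internal edge.

    The root edge of a rooted binary tree yields a single split (the two
    root-child clades induce the same bipartition; the set dedupes them).
    """
    all_tips = frozenset(tree.tip_labels())
    n = len(all_tips)
    out: set[Bipartition] = set()
    clades: dict[Node, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            clades[node] = frozenset([node.label])
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.children))
    for node in tree.nodes():
        if node is tree.root or node.is_leaf:
            continue
        clade = clades[node]
        if 2 <= len(clade) <= n - 2:
            out.add(Bipartition(clade, all_tips - clade))
    return frozenset(out)


def clade_sets(tree: Tree) -> dict[Node, frozenset]:
    clades: dict[Node, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            clades[node] = frozenset([node.label])
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.children))
    return clades


def tip_distance_matrix(
    tree: Tree, topological: bool = False
) -> tuple[list[str], np.ndarray]:
    """Pairwise tip-to-tip path lengths (branch-length sum, or edge counts)."""
    tips = tree.tips()
    labels = [t.label for t in tips]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    dm = np.zeros((n, n))
    # descending accumulation: at each internal node, combine child tip sets
    below: dict[Node, list[tuple[int, float]]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[node] = [(index[node], 0.0)]
        else:
            kids = []
            for c in node.children:
                step = 1.0 if topological else (c.length or 0.0)
                kids.append([(i, d + step) for i, d in below[c]])
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i, di in kids[a]:
                        for j, dj in kids[b]:
                            dm[i, j] = dm[j, i] = di + dj
            below[node] = [pair for k in kids for pair in k]
    return labels, dm


def quartet_resolution(d: np.ndarray, i: int, j: int, k: int, l: int) -> int:
    """Resolve quartet (i,j,k,l) from a (topological) tip distance matrix.

    Returns 0 for ij|kl, 1 for ik|jl, 2 for il|jk, -1 if unresolved (ties).
    """
    s0 = d[i, j] + d[k, l]
    s1 = d[i, k] + d[j, l]
    s2 = d[i, l] + d[j, k]
    m = min(s0, s1, s2)
    hits = (s0 == m) + (s1 == m) + (s2 == m)
    if hits > 1:
        return -1
    if s0 == m:
        return 0
    return 1 if s1 == m else 2


def unrooted_copy(tree: Tree) -> Tree:
    """Copy with a rooted-binary root suppressed into a basal trifurcation."""
    t = tree.copy()
    root = t.root
    if len(root.children) == 2:
        a, b = root.children
        keep, merge = (a, b) if not a.is_leaf else (b, a)
        if not keep.is_leaf:
            root.children = []
            for c in keep.children:
                root.add_child(c)
            merge.length = (merge.length or 0.0) + (keep.length or 0.0)
            root.add_child(merge)
            root.label = keep.label or root.label
    t.rooted = False
    return t
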