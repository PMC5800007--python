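"""Tree comparison statistics: Robinson–Foulds distances, one-tip-per-taxon
pruning, ultrametricization, relative node depths, and the
concatenation-vs-MSC node-depth bias table.

Node depths are compared on the relative scale (node height divided by root
height) after both trees are forced ultrametric; the bias statistic for a
matched split is (depth_A - depth_B) / depth_B, so positive values mean
tree A places the node deeper (older) than tree B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import spawn_rng
from .errors import InputError
from .msc import SampleMap
from .trees import (
    Bipartition,
    Node,
    Tree,
    bipartition_set,
    clade_sets,
    tip_distance_matrix,
)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the two
    trees' non-trivial bipartition sets. Polytomous trees simply contribute
    fewer splits."""
    s1, s2 = set(t1.tip_labels()), set(t2.tip_labels())
    if s1 != s2:
        raise InputError(
            f"tip sets differ: only in first {sorted(s1 - s2)}, only in second {sorted(s2 - s1)}"
        )
    return len(bipartition_set(t1) ^ bipartition_set(t2))


def rf_matrix(trees: Sequence[tuple[str, Tree]]) -> pd.DataFrame:
    """Symmetric RF matrix over a labeled list of trees (common tip set)."""
    names = [name for name, _ in trees]
    if len(set(names)) != len(names):
        raise InputError("duplicate tree labels")
    n = len(trees)
    mat = np.zeros((n, n), dtype=int)
    splits = [bipartition_set(t) for _, t in trees]
    for _, t in trees[1:]:
        if set(t.tip_labels()) != set(trees[0][1].tip_labels()):
            raise InputError("trees must share one tip set (prune first)")
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = len(splits[i] ^ splits[j])
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Pruning / rerooting
# ---------------------------------------------------------------------------


def prune_to_tips(tree: Tree, keep_labels) -> Tree:
    """Restriction of the tree to a tip subset; suppressed degree-2 nodes add
    their branch lengths, so retained tip-to-tip path lengths are unchanged."""
    keep = set(keep_labels)
    missing = keep - set(tree.tip_labels())
    if missing:
        raise InputError(f"labels not in tree: {sorted(missing)}")

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is None:
                child.length = child.length
            return child
        new = Node(node.label, node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = prune(tree.root)
    if root is None:
        raise InputError("no tips retained")
    root.length = None
    out = Tree(root, rooted=tree.rooted, length_units=tree.length_units)
    if len(root.children) > 2:
        out.rooted = tree.rooted and len(tree.root.children) > 2
    return out


def one_tip_per_taxon(
    tree: Tree,
    samples: SampleMap,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tree:
    """Keep one uniformly chosen tip per taxon and relabel it to the taxon id."""
    if rng is None:
        rng = spawn_rng(seed)
    tips = set(tree.tip_labels())
    chosen: dict[str, str] = {}
    for taxon in samples.taxa():
        candidates = sorted(
            h for h, (_i, _l, tax) in samples.haplotypes.items()
            if tax == taxon and h in tips
        )
        if not candidates:
            raise InputError(f"taxon {taxon!r} has no tips in the tree")
        chosen[taxon] = candidates[int(rng.integers(len(candidates)))]
    pruned = prune_to_tips(tree, chosen.values())
    relabel = {h: t for t, h in chosen.items()}
    for tip in pruned.tips():
        tip.label = relabel[tip.label]
    return pruned


def root_at_midpoint(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    if not tree.has_branch_lengths():
        raise InputError("midpoint rooting requires branch lengths")
    t = tree.copy()
    if t.n_tips < 2:
        t.rooted = True
        return t
    labels, dm = tip_distance_matrix(t)
    i, j = np.unravel_index(int(np.argmax(dm)), dm.shape)
    if labels[i] > labels[j]:
        i, j = j, i
    half = dm[i, j] / 2.0
    tip_nodes = {n.label: n for n in t.tips()}
    a, b = tip_nodes[labels[i]], tip_nodes[labels[j]]
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent
    anc_b_set = []
    node = b
    while node is not None:
        anc_b_set.append(node)
        node = node.parent
    lca = next(x for x in anc_a if x in anc_b_set)
    path = anc_a[: anc_a.index(lca)] + list(reversed(anc_b_set[: anc_b_set.index(lca)]))
    # path: a ... child-of-lca (a side), child-of-lca (b side) ... b, each a
    # node whose edge to its parent (toward the lca) lies on the path, except
    # the crossing point; walk from a accumulating edge lengths
    acc = 0.0
    a_index = anc_a.index(lca)
    for step, node in enumerate(path):
        length = node.length or 0.0
        if acc + length >= half or step == len(path) - 1:
            if step < a_index:
                # a-side edge: entered at the child (lower) end
                x = half - acc
            else:
                # b-side edge: entered at the parent (upper) end
                x = length - (half - acc)
            return _reroot_on_edge(t, node, x)
        acc += length
    raise RuntimeError("midpoint not located")  # pragma: no cover


def _suppress_unary(node: Node) -> None:
    for child in list(node.children):
        _suppress_unary(child)
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        child.length = (child.length or 0.0) + (node.length or 0.0)
        idx = node.parent.children.index(node)
        node.parent.children[idx] = child
        child.parent = node.parent


def _reroot_on_edge(tree: Tree, v: Node, dist_from_v: float) -> Tree:
    """New root on the edge above ``v``, ``dist_from_v`` along it."""
    edge_len = v.length or 0.0
    dist_from_v = float(np.clip(dist_from_v, 0.0, edge_len))
    u = v.parent
    if u is None:
        tree.rooted = True
        return tree
    u.children.remove(v)
    new_root = Node()
    new_root.add_child(v)
    v.length = dist_from_v
    prev, prev_len = new_root, edge_len - dist_from_v
    cur = u
    while cur is not None:
        nxt = cur.parent
        cur_len = cur.length
        if nxt is not None:
            nxt.children.remove(cur)
        cur.parent = None
        prev.add_child(cur)
        cur.length = prev_len
        prev_len = cur_len
        prev = cur
        cur = nxt
    _suppress_unary(new_root)
    out = Tree(new_root, rooted=True, length_units=tree.length_units)
    return out


# ---------------------------------------------------------------------------
# Ultrametricization and node depths
# ---------------------------------------------------------------------------


def make_ultrametric(tree: Tree) -> Tree:
    """Force equal root-to-tip path lengths by mean-path-length smoothing.

    Each node is placed at the mean of its subtree's root-to-tip path
    lengths and child subtrees are rescaled proportionally; an ultrametric
    input is a fixed point.
    """
    if not tree.has_branch_lengths():
        raise InputError("ultrametricization requires branch lengths")
    t = tree.copy()
    ntips: dict[int, int] = {}
    mean_depth: dict[int, float] = {}
    for node in t.root.postorder():
        if node.is_leaf:
            ntips[id(node)] = 1
            mean_depth[id(node)] = 0.0
        else:
            total_tips = sum(ntips[id(c)] for c in node.children)
            acc = sum(
                ntips[id(c)] * ((c.length or 0.0) + mean_depth[id(c)])
                for c in node.children
            )
            ntips[id(node)] = total_tips
            mean_depth[id(node)] = acc / total_tips

    def assign(node: Node, height: float) -> None:
        for child in node.children:
            b = child.length or 0.0
            denom = b + mean_depth[id(child)]
            if denom <= 0:
                child.length = height if child.is_leaf else 0.0
                assign(child, height)
            else:
                f = height / denom
                child.length = b * f
                assign(child, height - b * f)

    assign(t.root, mean_depth[id(t.root)])
    return t


def relative_node_depths(
    tree: Tree, rel_tol: float = 1e-6
) -> dict[Bipartition, float]:
    """Internal-node heights relative to the root height, keyed by the node's
    (non-trivial) bipartition; the root itself maps to 1 by definition.

    When a rooted tree's two root children induce the same split, the deeper
    node is reported.
    """
    depths_check = []

    def walk(node: Node, d: float) -> None:
        if node.is_leaf:
            depths_check.append(d)
        for c in node.children:
            walk(c, d + (c.length or 0.0))

    walk(tree.root, 0.0)
    span = max(depths_check) - min(depths_check)
    scale = max(abs(max(depths_check)), 1e-300)
    if span > rel_tol * scale and span > 1e-12:
        raise InputError(f"tree is not ultrametric (max tip-depth deviation {span:g})")
    heights = tree.node_heights()
    root_h = heights[tree.root]
    if root_h <= 0:
        raise InputError("zero-height tree")
    all_tips = frozenset(tree.tip_labels())
    n = len(all_tips)
    clades = clade_sets(tree)
    out: dict[Bipartition, float] = {}
    for node in tree.nodes():
        if node is tree.root or node.is_leaf:
            continue
        clade = clades[node]
        if not (2 <= len(clade) <= n - 2):
            continue
        b = Bipartition(clade, all_tips - clade)
        value = heights[node] / root_h
        if b not in out or value > out[b]:
            out[b] = value
    return out


@dataclass
class DepthTable:
    """Matched relative node depths of two ultrametricized trees."""

    tree_a_id: str
    tree_b_id: str
    table: pd.DataFrame  # columns: split, depth_a, depth_b, bias
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0

    def quartile_summary(self) -> pd.DataFrame:
        """Median bias by quartile of the reference (tree B) depth;
        quartile 1 = shallowest nodes."""
        if self.table.empty:
            return pd.DataFrame(columns=["quartile", "n", "median_bias"])
        depth_b = self.table["depth_b"].to_numpy()
        ranks = depth_b.argsort().argsort()
        quartile = (ranks * 4 // len(depth_b)) + 1
        df = self.table.assign(quartile=quartile)
        return (
            df.groupby("quartile")
            .agg(n=("bias", "size"), median_bias=("bias", "median"))
            .reset_index()
        )


def depth_bias(
    tree_a: Tree,
    tree_b: Tree,
    samples: Optional[SampleMap] = None,
    seed: int = 0,
    tree_a_id: str = "A",
    tree_b_id: str = "B",
) -> DepthTable:
    """Relative-depth bias (A - B)/B over splits shared by the two trees.

    Tree A (e.g. a concatenation estimate over all samples) is first reduced
    to one tip per taxon when a sample map is given; both trees are midpoint
    rooted if unrooted, then forced ultrametric.
    """

    def prepare(tree: Tree, do_prune: bool) -> dict[Bipartition, float]:
        t = tree
        if do_prune and samples is not None:
            t = one_tip_per_taxon(t, samples, seed=seed)
        if not t.rooted:
            t = root_at_midpoint(t)
        t = make_ultrametric(t)
        return relative_node_depths(t)

    depths_a = prepare(tree_a, do_prune=True)
    depths_b = prepare(tree_b, do_prune=False)
    shared = sorted(set(depths_a) & set(depths_b), key=lambda b: b.key())
    rows = []
    for b in shared:
        da, db = depths_a[b], depths_b[b]
        if db <= 0:
            continue
        rows.append(
            {"split": b.key(), "depth_a": da, "depth_b": db, "bias": (da - db) / db}
        )
    table = pd.DataFrame(rows, columns=["split", "depth_a", "depth_b", "bias"])
    result = DepthTable(
        tree_a_id,
        tree_b_id,
        table,
        n_unmatched_a=len(depths_a) - len(shared),
        n_unmatched_b=len(depths_b) - len(shared),
    )
    if len(shared) < 2:
        warnings.warn(
            f"fewer than 2 shared bipartitions between {tree_a_id} and {tree_b_id}",
            stacklevel=2,
        )
    return result
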