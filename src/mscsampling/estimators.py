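"""Gene-tree and species-tree estimation.

Gene trees come from neighbor joining on Jukes–Cantor distances with
pairwise deletion; the species tree comes either from concatenation (NJ on
the concatenated matrix) or from a quartet-agreement summary estimator that
maximizes, over candidate topologies, the total gene-tree quartet weight the
topology induces — the same objective family as summary multispecies
coalescent methods operating on inferred gene trees. Internal branch lengths
in coalescent units are recovered from quartet discordance via the standard
three-taxon formula: a branch of length tau (in units of 2Ne generations)
leaves a fraction 1 - (2/3)exp(-tau) of gene-tree quartets concordant, so
tau = -ln(1.5*(1-p)) for observed support p.

A moment estimator of per-taxon diversity (theta = 4*Ne*mu per site) from
the pairwise differences of each taxon's two assigned haplotypes stands in
for coalescent-model Ne estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seeds import spawn_rng
from .errors import ConfigurationError, InputError, SizingError
from .filters import Locus
from .sampling import AlleleAssignment
from .seqsim import FIRST_MISSING_CODE, Alignment
from .trees import (
    Bipartition,
    Node,
    Tree,
    bipartition_set,
    clade_sets,
    quartet_resolution,
    tip_distance_matrix,
    unrooted_copy,
    write_newick,
)

SATURATION_CAP = 5.0  # substitutions/site reported for p >= 0.75
COALESCENT_CAP = 10.0  # coalescent units reported for p -> 1


@dataclass
class DistanceMatrix:
    """Pairwise evolutionary distances with pairwise-deletion bookkeeping."""

    labels: list[str]
    d: np.ndarray
    comparable: np.ndarray  # per-pair count of jointly non-missing sites
    saturated: np.ndarray  # boolean mask of capped entries

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InputError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal not zero")


def _pairwise_mismatch(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mismatch count, comparable count) per pair, pairwise deletion."""
    valid = (codes < FIRST_MISSING_CODE).astype(np.float64)
    comparable = valid @ valid.T
    matches = np.zeros_like(comparable)
    for s in range(4):
        ind = (codes == s).astype(np.float64)
        matches += ind @ ind.T
    mismatches = comparable - matches
    return mismatches, comparable


def jc_distance_matrix(alignment: Alignment, cap: float = SATURATION_CAP) -> DistanceMatrix:
    """Jukes–Cantor distances with pairwise deletion of {N, -, ?}.

    p >= 0.75 (outside the JC domain) is reported as ``cap`` and flagged.
    """
    if alignment.n_seqs < 2:
        raise InputError("need at least 2 sequences")
    mism, comp = _pairwise_mismatch(alignment.codes)
    n = alignment.n_seqs
    off = ~np.eye(n, dtype=bool)
    if np.any(comp[off] == 0):
        i, j = np.argwhere((comp == 0) & off)[0]
        raise InputError(
            f"no comparable sites between {alignment.names[i]!r} and {alignment.names[j]!r}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(comp > 0, mism / comp, 0.0)
    saturated = (p >= 0.75) & off
    arg = 1.0 - 4.0 * p / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(saturated, cap, -0.75 * np.log(np.clip(arg, 1e-300, None)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(alignment.names), d, comp, saturated)


def neighbor_joining(
    dm: DistanceMatrix, length_units: str = "substitutions_per_site"
) -> Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch (the pair's summed length is preserved).
    Ties in the Q matrix resolve to the first (row-major) minimum, so the
    result is deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise InputError("need at least 2 labels")
    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(0.0, li + lj)
            lj = 0.0
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack(
            [
                np.hstack([d[np.ix_(keep, keep)], np.clip(dnew[keep], 0.0, None)[:, None]]),
                np.hstack([np.clip(dnew[keep], 0.0, None), [0.0]]),
            ]
        )
        nodes = [nodes[k] for k in keep] + [parent]

    root = Node()
    if len(nodes) == 1:
        root = nodes[0]
    elif len(nodes) == 2:
        half = d[0, 1] / 2.0
        for k in range(2):
            nodes[k].length = max(half, 0.0)
            root.add_child(nodes[k])
    else:
        la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, length in zip(nodes, (la, lb, lc)):
            node.length = max(length, 0.0)
            root.add_child(node)
    tree = Tree(root, rooted=False, length_units=length_units)
    return tree


@dataclass
class GeneTreeEstimate:
    locus_id: str
    tree: Tree
    bootstraps: list[Tree] = field(default_factory=list)
    degenerate: bool = False  # no variation in the alignment


def estimate_gene_trees(
    loci: Sequence[Locus],
    bootstrap_replicates: int = 100,
    seed: int = 0,
    labels: Optional[Iterable[str]] = None,
) -> dict[str, GeneTreeEstimate]:
    """NJ point tree plus site-resampled NJ bootstrap trees per locus.

    ``labels`` restricts estimation to a subset of sequences (e.g. the
    haplotypes chosen by an allele assignment).
    """
    out: dict[str, GeneTreeEstimate] = {}
    for idx, locus in enumerate(loci):
        aln = locus.alignment
        if labels is not None:
            aln = aln.subset([l for l in labels if l in aln.names])
        dm = jc_distance_matrix(aln)
        tree = neighbor_joining(dm)
        degenerate = bool(np.all(dm.d == 0))
        rng = spawn_rng(seed, 101, idx)
        boots = []
        for _b in range(bootstrap_replicates):
            cols = rng.integers(aln.length, size=aln.length)
            resampled = Alignment(list(aln.names), aln.codes[:, cols], frame=None)
            boots.append(neighbor_joining(jc_distance_matrix(resampled)))
        out[locus.id] = GeneTreeEstimate(locus.id, tree, boots, degenerate)
    return out


# ---------------------------------------------------------------------------
# Quartet table and quartet species tree
# ---------------------------------------------------------------------------


class QuartetTable:
    """Per-taxon-quartet topology weights accumulated over gene trees.

    For the sorted taxon quartet (a, b, c, d) the three unrooted resolutions
    are indexed 0: ab|cd, 1: ac|bd, 2: ad|bc. Each gene tree contributes, for
    every combination of one allele per taxon, weight 1/(number of
    combinations) to the resolution that gene tree induces; unresolved
    combinations contribute nothing.
    """

    def __init__(self, taxa: Sequence[str]):
        self.taxa = sorted(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxa")
        self.weights: dict[tuple[str, str, str, str], np.ndarray] = {
            q: np.zeros(3) for q in itertools.combinations(self.taxa, 4)
        }
        self.n_gene_trees = 0

    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.weights.values()))

    def add_gene_tree(self, tree: Tree, allele_to_taxon: dict[str, str]) -> None:
        labels, dmat = tip_distance_matrix(tree, topological=True)
        for lab in labels:
            if lab not in allele_to_taxon:
                raise InputError(f"gene-tree tip {lab!r} has no taxon mapping")
        by_taxon: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            by_taxon.setdefault(allele_to_taxon[lab], []).append(i)
        for q in self.weights:
            if not all(t in by_taxon for t in q):
                continue
            ia, ib, ic, idx = (np.asarray(by_taxon[t]) for t in q)
            dab = dmat[np.ix_(ia, ib)][:, :, None, None]
            dcd = dmat[np.ix_(ic, idx)][None, None, :, :]
            dac = dmat[np.ix_(ia, ic)][:, None, :, None]
            dbd = dmat[np.ix_(ib, idx)][None, :, None, :]
            dad = dmat[np.ix_(ia, idx)][:, None, None, :]
            dbc = dmat[np.ix_(ib, ic)][None, :, :, None]
            sums = np.stack(
                [dab + dcd, dac + dbd, dad + dbc]
            )  # (3, na, nb, nc, nd)
            mn = sums.min(axis=0)
            is_min = sums == mn
            resolved = is_min.sum(axis=0) == 1
            winner = sums.argmin(axis=0)
            ncombo = mn.size
            w = 1.0 / ncombo
            for t in range(3):
                self.weights[q][t] += w * np.count_nonzero((winner == t) & resolved)
        self.n_gene_trees += 1

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for q, w in self.weights.items():
            rows.append(
                {
                    "taxon_a": q[0],
                    "taxon_b": q[1],
                    "taxon_c": q[2],
                    "taxon_d": q[3],
                    "w_ab_cd": w[0],
                    "w_ac_bd": w[1],
                    "w_ad_bc": w[2],
                    "total": w.sum(),
                }
            )
        return pd.DataFrame(rows)


def build_quartet_table(
    gene_trees: Iterable[Tree], allele_to_taxon: dict[str, str]
) -> QuartetTable:
    taxa = sorted(set(allele_to_taxon.values()))
    table = QuartetTable(taxa)
    for tree in gene_trees:
        table.add_gene_tree(tree, allele_to_taxon)
    return table


def score_topology(tree: Tree, qt: QuartetTable) -> float:
    """Sum over quartets of the weight of the resolution the topology induces."""
    labels, dmat = tip_distance_matrix(tree, topological=True)
    pos = {l: i for i, l in enumerate(labels)}
    score = 0.0
    for q, w in qt.weights.items():
        if w.sum() == 0:
            continue
        if not all(t in pos for t in q):
            raise InputError(f"topology missing taxon from quartet {q}")
        res = quartet_resolution(dmat, pos[q[0]], pos[q[1]], pos[q[2]], pos[q[3]])
        if res >= 0:
            score += float(w[res])
    return score


def _tree_from_splits(taxa: Sequence[str], splits: Iterable[Bipartition]) -> Tree:
    """Build the (unrooted-representation) tree containing exactly the given
    compatible splits; the smallest taxon hangs off the basal node."""
    taxa = sorted(taxa)
    anchor = taxa[0]
    rest = frozenset(taxa[1:])
    clades = []
    for s in splits:
        clade = s.side_b if anchor in s.side_a else s.side_a
        clades.append(frozenset(clade))
    clades = sorted(set(clades), key=lambda c: (len(c), sorted(c)))

    def build(tipset: frozenset) -> Node:
        inside = [c for c in clades if c < tipset]
        maximal = [
            c for c in inside if not any(c < other for other in inside)
        ]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        node = Node()
        for c in sorted(maximal, key=lambda c: sorted(c)):
            child = build(c) if len(c) > 1 else Node(label=next(iter(c)))
            node.add_child(child)
        for tip in sorted(tipset - covered):
            node.add_child(Node(label=tip))
        return node

    root = Node()
    root.add_child(Node(label=anchor))
    top = build(rest)
    if len(rest) == 1:
        root.add_child(Node(label=next(iter(rest))))
    elif frozenset(rest) in set(clades):
        root.add_child(top)
    else:
        for child in top.children:
            root.add_child(child)
    return Tree(root, rooted=False, length_units="unitless")


def _enumerate_topologies(taxa: Sequence[str]):
    """All unrooted binary topologies as nested tuples (top level: 3 subtrees)."""
    taxa = list(taxa)

    def insert_all(sub, leaf):
        yield (sub, leaf)
        if isinstance(sub, tuple):
            for i, child in enumerate(sub):
                for new_child in insert_all(child, leaf):
                    yield sub[:i] + (new_child,) + sub[i + 1 :]

    def recurse(k):
        if k == 3:
            yield (taxa[0], taxa[1], taxa[2])
            return
        for t in recurse(k - 1):
            leaf = taxa[k - 1]
            for i, sub in enumerate(t):
                for new_sub in insert_all(sub, leaf):
                    yield t[:i] + (new_sub,) + t[i + 1 :]

    if len(taxa) < 3:
        raise InputError("need >= 3 taxa")
    yield from recurse(len(taxa))


def _tuple_to_tree(t) -> Tree:
    def build(sub) -> Node:
        if isinstance(sub, tuple):
            node = Node()
            for c in sub:
                node.add_child(build(c))
            return node
        return Node(label=sub)

    root = Node()
    for c in t:
        root.add_child(build(c))
    return Tree(root, rooted=False, length_units="unitless")


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """All topologies one nearest-neighbor interchange away."""
    taxa = sorted(tree.tip_labels())
    splits = set(bipartition_set(tree))
    all_tips = frozenset(taxa)
    clades = clade_sets(tree)
    neighbors = []
    for node in tree.nodes():
        if node is tree.root or node.is_leaf:
            continue
        clade = clades[node]
        if not (2 <= len(clade) <= len(taxa) - 2):
            continue
        if len(node.children) != 2:
            continue
        x1 = clades[node.children[0]]
        x2 = clades[node.children[1]]
        parent = node.parent
        others = [c for c in parent.children if c is not node]
        if parent is tree.root and len(others) == 2:
            y1, y2 = clades[others[0]], clades[others[1]]
        elif parent is not tree.root and len(others) == 1:
            y1 = clades[others[0]]
            y2 = all_tips - clades[parent]
        else:
            continue  # polytomy or rooted-binary root split; skip
        old = Bipartition(clade, all_tips - clade)
        for ya, yb in ((y1, y2), (y2, y1)):
            new = Bipartition(x1 | ya, x2 | yb)
            new_splits = (splits - {old}) | {new}
            neighbors.append(_tree_from_splits(taxa, new_splits))
    return neighbors


def quartet_species_tree(
    qt: QuartetTable,
    search: str = "nni",
    seed: int = 0,
    start: Optional[Tree] = None,
) -> tuple[Tree, float]:
    """Topology maximizing total induced quartet weight, plus the normalized
    score (best score / total table weight).

    ``exact`` enumerates every unrooted topology (allowed up to 9 taxa);
    ``nni`` hill-climbs by nearest-neighbor interchanges from an NJ tree on
    quartet-derived average distances, accepting strict improvements only.
    Co-optimal topologies resolve to the lexicographically smallest canonical
    Newick string.
    """
    taxa = qt.taxa
    n = len(taxa)
    total = qt.total_weight()
    if n < 4:
        tree = _tree_from_splits(taxa, []) if n == 3 else None
        if tree is None:
            raise InputError("need >= 3 taxa")
        return tree, 1.0 if total else 0.0

    if search == "exact":
        if n > 9:
            raise SizingError(f"exact search limited to 9 taxa, got {n}")
        best_score = -1.0
        best_newick = None
        best_tree = None
        for t in _enumerate_topologies(taxa):
            tree = _tuple_to_tree(t)
            s = score_topology(tree, qt)
            nwk = write_newick(tree)
            if s > best_score + 1e-12 or (
                abs(s - best_score) <= 1e-12 and nwk < best_newick
            ):
                best_score, best_newick, best_tree = s, nwk, tree
        return best_tree, (best_score / total if total else 0.0)

    if search != "nni":
        raise ConfigurationError(f"unknown search mode {search!r}")

    rng = spawn_rng(seed, 303)
    starts: list[Tree] = []
    if start is not None:
        starts.append(unrooted_copy(start))
    starts.append(_nj_start_tree(qt))
    for _ in range(11):  # random restarts guard against local optima
        starts.append(_random_topology(taxa, rng))

    best_tree, best_score, best_newick = None, -1.0, None
    for s0 in starts:
        tree, score = _nni_hill_climb(s0, qt)
        nwk = write_newick(tree)
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and nwk < best_newick
        ):
            best_tree, best_score, best_newick = tree, score, nwk
    return best_tree, (best_score / total if total else 0.0)


def _nni_hill_climb(start: Tree, qt: QuartetTable) -> tuple[Tree, float]:
    current = unrooted_copy(start)
    for node in current.nodes():
        node.length = None
    current_score = score_topology(current, qt)
    improved = True
    while improved:
        improved = False
        best_candidate, best_s = None, current_score
        for cand in _nni_neighbors(current):
            s = score_topology(cand, qt)
            if s > best_s + 1e-12 or (
                best_candidate is not None
                and abs(s - best_s) <= 1e-12
                and write_newick(cand) < write_newick(best_candidate)
            ):
                best_candidate, best_s = cand, s
        if best_candidate is not None:
            current, current_score = best_candidate, best_s
            improved = True
    return current, current_score


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> Tree:
    """Uniform-ish random unrooted binary topology by random edge insertion."""
    taxa = list(taxa)
    t = (taxa[0], taxa[1], taxa[2])

    def insert_all(sub, leaf):
        out = [(sub, leaf)]
        if isinstance(sub, tuple):
            for i, child in enumerate(sub):
                for new_child in insert_all(child, leaf):
                    out.append(sub[:i] + (new_child,) + sub[i + 1 :])
        return out

    for leaf in taxa[3:]:
        options = []
        for i, sub in enumerate(t):
            for new_sub in insert_all(sub, leaf):
                options.append(t[:i] + (new_sub,) + t[i + 1 :])
        t = options[int(rng.integers(len(options)))]
    return _tuple_to_tree(t)


def _nj_start_tree(qt: QuartetTable) -> Tree:
    """NJ on average 'together-ness' distances derived from the quartet table."""
    taxa = qt.taxa
    n = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for q, w in qt.weights.items():
        tw = w.sum()
        if tw == 0:
            continue
        a, b, c, d = (pos[t] for t in q)
        pairs = [((a, b), 0), ((c, d), 0), ((a, c), 1), ((b, d), 1), ((a, d), 2), ((b, c), 2)]
        for (i, j), t in pairs:
            together = w[t] / tw
            acc[i, j] += 1.0 - together
            acc[j, i] += 1.0 - together
            cnt[i, j] += 1
            cnt[j, i] += 1
    with np.errstate(invalid="ignore"):
        d = np.where(cnt > 0, acc / np.maximum(cnt, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    dm = DistanceMatrix(list(taxa), d, np.ones_like(d), np.zeros_like(d, bool))
    return neighbor_joining(dm, length_units="unitless")


def coalescent_branch_lengths(
    topology: Tree, qt: QuartetTable, cap: float = COALESCENT_CAP
) -> Tree:
    """Internal branch lengths in coalescent units from quartet support.

    For each internal branch, p = mean fraction of quartet weight supporting
    the branch's induced resolution over the quartets straddling it; the
    branch length is -ln(1.5*(1-p)), zero for p <= 1/3, capped for p -> 1.
    Tip branches are set to zero.
    """
    tree = unrooted_copy(topology)
    taxa = sorted(tree.tip_labels())
    all_tips = frozenset(taxa)
    pos = {t: i for i, t in enumerate(qt.taxa)}
    clades = clade_sets(tree)
    for node in tree.nodes():
        node_clade = clades.get(node)
        if node is tree.root:
            node.length = None
            continue
        if node.is_leaf or not (2 <= len(node_clade) <= len(taxa) - 2):
            node.length = 0.0
            continue
        if len(node.children) != 2:
            node.length = 0.0
            continue
        x1, x2 = clades[node.children[0]], clades[node.children[1]]
        parent = node.parent
        others = [c for c in parent.children if c is not node]
        if parent is tree.root and len(others) == 2:
            y1, y2 = clades[others[0]], clades[others[1]]
        elif parent is not tree.root and len(others) == 1:
            y1 = clades[others[0]]
            y2 = all_tips - clades[parent]
        else:
            node.length = 0.0
            continue
        fractions = []
        for a in sorted(x1):
            for b in sorted(x2):
                for c in sorted(y1):
                    for d in sorted(y2):
                        q = tuple(sorted((a, b, c, d)))
                        w = qt.weights.get(q)
                        if w is None or w.sum() == 0:
                            continue
                        # which resolution index puts {a,b} together?
                        qa, qb, qc, qd = q
                        if {qa, qb} == {a, b} or {qa, qb} == {c, d}:
                            idx = 0
                        elif {qa, qc} == {a, b} or {qa, qc} == {c, d}:
                            idx = 1
                        else:
                            idx = 2
                        fractions.append(float(w[idx] / w.sum()))
        p = float(np.mean(fractions)) if fractions else 1.0 / 3.0
        if p <= 1.0 / 3.0:
            node.length = 0.0
        elif p >= 1.0:
            node.length = cap
        else:
            node.length = min(-math.log(1.5 * (1.0 - p)), cap)
    tree.length_units = "coalescent_units"
    return tree


# ---------------------------------------------------------------------------
# Concatenation, bootstrap support, theta
# ---------------------------------------------------------------------------


def concatenated_alignment(loci: Sequence[Locus], labels: Sequence[str]) -> Alignment:
    """Loci concatenated in id order; absent labels padded with N."""
    labels = list(labels)
    present_anywhere = {lab for locus in loci for lab in locus.labels()}
    missing = [lab for lab in labels if lab not in present_anywhere]
    if missing:
        raise InputError(f"labels absent from every locus: {missing}")
    blocks = []
    for locus in sorted(loci, key=lambda l: l.id):
        aln = locus.alignment
        block = np.full((len(labels), aln.length), 4, dtype=np.uint8)  # N
        for row, lab in enumerate(labels):
            if lab in aln.names:
                block[row] = aln.codes[aln.names.index(lab)]
        blocks.append(block)
    codes = np.hstack(blocks) if blocks else np.zeros((len(labels), 0), np.uint8)
    return Alignment(labels, codes, frame=None)


def concatenation_tree(loci: Sequence[Locus], labels: Sequence[str]) -> Tree:
    """NJ on JC distances of the concatenated matrix (pairwise deletion)."""
    return neighbor_joining(jc_distance_matrix(concatenated_alignment(loci, labels)))


def multilocus_bootstrap_support(
    loci: Sequence[Locus],
    estimator: str = "quartet",
    replicates: int = 100,
    seed: int = 0,
    allele_to_taxon: Optional[dict[str, str]] = None,
    labels: Optional[Sequence[str]] = None,
) -> tuple[Tree, dict[Bipartition, float]]:
    """Point species tree plus per-split support from multi-locus bootstrap.

    Each replicate resamples whole loci with replacement and re-runs the
    estimator (no site resampling within loci); support = fraction of
    replicate trees containing each point-tree split.
    """
    if len(loci) < 2:
        raise InputError("need >= 2 loci for a multi-locus bootstrap")
    loci = sorted(loci, key=lambda l: l.id)

    if estimator == "quartet":
        if allele_to_taxon is None:
            raise ConfigurationError("quartet estimator needs allele_to_taxon")
        ests = estimate_gene_trees(loci, bootstrap_replicates=0, seed=seed)
        trees_by_locus = {lid: e.tree for lid, e in ests.items()}

        def run(subset: Sequence[Locus]) -> Tree:
            table = build_quartet_table(
                [trees_by_locus[l.id] for l in subset], allele_to_taxon
            )
            tree, _score = quartet_species_tree(table, search="nni", seed=seed)
            return tree

    elif estimator == "concatenation":
        if labels is None:
            labels = sorted({lab for locus in loci for lab in locus.labels()})

        def run(subset: Sequence[Locus]) -> Tree:
            return concatenation_tree(subset, labels)

    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")

    point = run(loci)
    point_splits = bipartition_set(point)
    counts = {b: 0 for b in point_splits}
    rng = spawn_rng(seed, 202)
    for _r in range(replicates):
        idx = rng.integers(len(loci), size=len(loci))
        rep_tree = run([loci[int(i)] for i in idx])
        rep_splits = bipartition_set(rep_tree)
        for b in point_splits:
            if b in rep_splits:
                counts[b] += 1
    support = {b: c / replicates for b, c in counts.items()} if replicates else {}
    return point, support


def per_taxon_theta(
    loci: Sequence[Locus], assignment: AlleleAssignment
) -> dict[str, float]:
    """Moment estimate of per-site theta from each taxon's two assigned
    haplotypes: mean over loci of (pairwise differences / comparable sites)."""
    out: dict[str, float] = {}
    for taxon, (h1, h2) in sorted(assignment.haplotypes.items()):
        ratios = []
        for locus in loci:
            names = locus.alignment.names
            if h1 not in names or h2 not in names:
                continue
            codes = locus.alignment.codes[[names.index(h1), names.index(h2)]]
            valid = (codes < FIRST_MISSING_CODE).all(axis=0)
            comparable = int(valid.sum())
            if comparable == 0:
                continue
            diffs = int((codes[0, valid] != codes[1, valid]).sum())
            ratios.append(diffs / comparable)
        if not ratios:
            raise InputError(f"no locus carries both haplotypes of taxon {taxon!r}")
        out[taxon] = float(np.mean(ratios))
    return out
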