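"""Multispecies-coalescent gene-tree simulation on a lineage-level species tree.

The species tree is an ultrametric population tree whose *tips are
intraspecific lineages*; a separate map assigns each lineage to its species
(taxon). Within every population branch, gene lineages coalesce as a
continuous-time Kingman coalescent: with ``k`` active lineages and diploid
effective size ``Ne``, each pair coalesces at rate ``1/(2*Ne)`` per
generation, so the total rate is ``k*(k-1)/2 / (2*Ne)``. Lineages that fail
to coalesce before the top of a branch are censored into the parent
population; above the root coalescence continues at the root-branch rate.

Gene trees come out in generations; :func:`scale_to_substitutions` applies a
per-locus relaxed clock (one lognormal mean-1 rate multiplier per locus,
strict clock within the locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._seeds import spawn_rng
from .errors import ConfigurationError, InputError, UnitError
from .trees import Node, Tree, clade_sets


def clade_key(tip_labels) -> str:
    """Stable text key for a clade: sorted tip labels joined by commas."""
    return ",".join(sorted(tip_labels))


@dataclass
class SpeciesTreeModel:
    """Ultrametric population tree + per-branch diploid Ne + lineage→taxon map.

    ``ne`` is keyed by the clade key of each node (the root key gives the
    ancestral Ne used above the root).
    """

    tree: Tree
    ne: dict[str, float]
    lineage_to_species: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.tree.validate()
        if self.tree.length_units != "generations":
            raise UnitError("species tree must be in generations")
        if not self.tree.is_ultrametric(rel_tol=1e-9):
            raise InputError("species tree must be ultrametric (rel tol 1e-9)")
        clades = clade_sets(self.tree)
        for node, clade in clades.items():
            key = clade_key(clade)
            if key not in self.ne:
                raise ConfigurationError(f"missing Ne for population {key!r}")
            if self.ne[key] <= 0:
                raise ConfigurationError(f"non-positive Ne for population {key!r}")
        tips = set(self.tree.tip_labels())
        mapped = set(self.lineage_to_species)
        if tips != mapped:
            raise ConfigurationError(
                f"lineage/taxon map mismatch: unmapped={sorted(tips - mapped)}, "
                f"unknown={sorted(mapped - tips)}"
            )
        # lineages of one taxon must be monophyletic (coalesce as populations
        # below the taxon's divergence from any other taxon)
        clade_values = set(clades.values())
        for taxon in set(self.lineage_to_species.values()):
            group = frozenset(
                l for l, t in self.lineage_to_species.items() if t == taxon
            )
            if len(group) > 1 and group not in clade_values:
                raise ConfigurationError(
                    f"lineages of taxon {taxon!r} are not monophyletic"
                )

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.lineage_to_species.values()))

    def lineages_of(self, taxon: str) -> list[str]:
        return sorted(l for l, t in self.lineage_to_species.items() if t == taxon)


@dataclass
class SampleMap:
    """haplotype id → (individual id, lineage id, taxon id); diploid individuals."""

    haplotypes: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        per_ind: dict[str, list[str]] = {}
        for hap, (ind, lineage, taxon) in self.haplotypes.items():
            per_ind.setdefault(ind, []).append(hap)
        for ind, haps in per_ind.items():
            if len(haps) != 2:
                raise ConfigurationError(
                    f"individual {ind!r} has {len(haps)} haplotypes; diploids need exactly 2"
                )

    def haplotype_ids(self) -> list[str]:
        return sorted(self.haplotypes)

    def individuals(self) -> list[str]:
        return sorted({ind for ind, _, _ in self.haplotypes.values()})

    def haplotypes_of_individual(self, individual: str) -> list[str]:
        return sorted(
            h for h, (ind, _, _) in self.haplotypes.items() if ind == individual
        )

    def individuals_of_lineage(self, lineage: str) -> list[str]:
        return sorted(
            {ind for ind, lin, _ in self.haplotypes.values() if lin == lineage}
        )

    def lineages_of_taxon(self, taxon: str) -> list[str]:
        return sorted({lin for _, lin, tax in self.haplotypes.values() if tax == taxon})

    def individuals_of_taxon(self, taxon: str) -> list[str]:
        return sorted({ind for ind, _, tax in self.haplotypes.values() if tax == taxon})

    def taxa(self) -> list[str]:
        return sorted({tax for _, _, tax in self.haplotypes.values()})

    def taxon_of(self, haplotype: str) -> str:
        return self.haplotypes[haplotype][2]

    def lineage_of(self, haplotype: str) -> str:
        return self.haplotypes[haplotype][1]

    def haplotype_to_taxon(self) -> dict[str, str]:
        return {h: rec[2] for h, rec in self.haplotypes.items()}

    def subset(self, haplotype_ids) -> "SampleMap":
        keep = set(haplotype_ids)
        sub = {h: rec for h, rec in self.haplotypes.items() if h in keep}
        # bypass the diploid check: a subset may carry one haplotype of a diploid
        obj = object.__new__(SampleMap)
        obj.haplotypes = sub
        return obj


@dataclass
class ClockModel:
    """Per-locus lognormal rate multipliers with mean exactly 1.

    ``rate_sd`` is the standard deviation of the log multiplier; the log mean
    is ``-rate_sd**2/2`` so E[multiplier] = 1. ``mu`` is the base mutation
    rate in substitutions/site/generation.
    """

    mu: float = 1e-8
    rate_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError("mu must be > 0")
        if self.rate_sd < 0:
            raise ConfigurationError("rate_sd must be >= 0")

    def draw_multiplier(self, rng: np.random.Generator) -> float:
        if self.rate_sd == 0:
            return 1.0
        return float(np.exp(rng.normal(-0.5 * self.rate_sd**2, self.rate_sd)))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_gene_tree(
    model: SpeciesTreeModel,
    samples: SampleMap,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tree:
    """Simulate one gene tree (units: generations) for all haplotypes in ``samples``."""
    if rng is None:
        rng = spawn_rng(seed if seed is not None else 0)

    clades = clade_sets(model.tree)
    heights = model.tree.node_heights()
    lineage_tip = {t.label: t for t in model.tree.tips()}
    for hap, (_ind, lineage, _tax) in samples.haplotypes.items():
        if lineage not in lineage_tip:
            raise ConfigurationError(
                f"haplotype {hap!r} maps to unknown lineage {lineage!r}"
            )

    # gene lineages entering each population node at its bottom
    entering: dict[Node, list[Node]] = {n: [] for n in model.tree.nodes()}
    gene_height: dict[Node, float] = {}
    for hap in samples.haplotype_ids():
        tip = Node(label=hap)
        gene_height[tip] = 0.0
        entering[lineage_tip[samples.haplotypes[hap][1]]].append(tip)

    def coalesce_interval(
        pool: list[Node], t0: float, t1: float, ne: float
    ) -> list[Node]:
        t = t0
        while len(pool) > 1:
            k = len(pool)
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            t = t + rng.exponential(1.0 / rate)
            if t >= t1:
                break
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            parent = Node()
            parent.add_child(a)
            parent.add_child(b)
            gene_height[parent] = t
            pool = [x for idx, x in enumerate(pool) if idx not in (i, j)]
            pool.append(parent)
        return pool

    # process populations bottom-up (postorder guarantees children first)
    for pop in model.tree.root.postorder():
        pool = entering[pop]
        ne = model.ne[clade_key(clades[pop])]
        t0 = heights[pop]
        t1 = heights[pop.parent] if pop.parent is not None else np.inf
        survivors = coalesce_interval(pool, t0, t1, ne)
        if pop.parent is not None:
            entering[pop.parent].extend(survivors)
        else:
            if len(survivors) != 1:  # pragma: no cover - t1=inf forces 1
                raise RuntimeError("coalescent did not complete above the root")
            gene_root = survivors[0]

    # convert heights to branch lengths
    for node in gene_root.preorder():
        for c in node.children:
            c.length = gene_height[node] - gene_height[c]
    gene_root.length = None
    tree = Tree(gene_root, rooted=True, length_units="generations")
    return tree


def scale_to_substitutions(
    gene_tree: Tree,
    clock: ClockModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    multiplier: Optional[float] = None,
) -> tuple[Tree, float]:
    """Rescale a generations tree to substitutions/site with one per-locus rate.

    Returns the scaled tree and the realized multiplier (for the manifest).
    """
    if gene_tree.length_units != "generations":
        raise UnitError(
            f"expected a tree in generations, got {gene_tree.length_units!r}"
        )
    if multiplier is None:
        if rng is None:
            rng = spawn_rng(seed if seed is not None else 0)
        multiplier = clock.draw_multiplier(rng)
    if multiplier <= 0:
        raise ConfigurationError("rate multiplier must be > 0")
    scaled = gene_tree.copy()
    factor = clock.mu * multiplier
    for node in scaled.nodes():
        if node.length is not None:
            node.length = node.length * factor
    scaled.length_units = "substitutions_per_site"
    return scaled, float(multiplier)
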