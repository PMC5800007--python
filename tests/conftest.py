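import numpy as np
import pytest

from mscsampling import (
    SampleMap,
    ScenarioConfig,
    SpeciesTreeModel,
    Tree,
    generate_study,
    read_newick,
)
from mscsampling.msc import clade_key
from mscsampling.trees import Node, clade_sets


def random_tree(labels, rng, lengths=True) -> Tree:
    """Random rooted binary topology (coalescent-style joins), exp(1) lengths."""
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        for k in (i, j):
            child = nodes[k]
            child.length = float(rng.exponential(1.0)) if lengths else None
            parent.add_child(child)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return Tree(nodes[0], rooted=True, length_units="unitless")


def one_population_model(ne: float = 10000.0) -> SpeciesTreeModel:
    tree = read_newick("P;", length_units="generations")
    return SpeciesTreeModel(tree, {"P": ne}, {"P": "pop"})


def species_model_from_newick(newick: str, ne: float) -> SpeciesTreeModel:
    """Species tree where every tip is its own single-lineage taxon."""
    tree = read_newick(newick, length_units="generations")
    ne_map = {clade_key(c): ne for c in clade_sets(tree).values()}
    return SpeciesTreeModel(tree, ne_map, {t: t for t in tree.tip_labels()})


def haploid_sample_map(lineages, n_individuals=1) -> SampleMap:
    """n diploid individuals per lineage (taxon id = lineage id)."""
    haps = {}
    for lin in lineages:
        for i in range(n_individuals):
            ind = f"{lin}_i{i}"
            for h in range(2):
                haps[f"{ind}_h{h}"] = (ind, lin, lin)
    return SampleMap(haps)


@pytest.fixture(scope="session")
def tiny_scenario() -> ScenarioConfig:
    return ScenarioConfig(n_loci=4, codons_per_locus=60, missing_rate=0.05,
                          missing_jitter=0.05)


@pytest.fixture(scope="session")
def tiny_study(tiny_scenario):
    return generate_study(tiny_scenario, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A mid-sized study shared by estimator/experiment tests."""
    scenario = ScenarioConfig(n_loci=40, codons_per_locus=100)
    return generate_study(scenario, seed=23)
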