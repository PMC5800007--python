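"""Prescribed species-tree scenarios with intraspecific lineage structure,
and end-to-end synthetic study generation.

The default scenario emulates a focal clade of 9 taxa in which 4 species
each comprise two deeply divergent phylogeographic lineages (lineage splits
at 37-50% of the shallowest interspecific divergence, i.e. 0.75-1.0
coalescent units deep), two diploid individuals per lineage, and a mixed
pectinate/balanced species topology with three internal branches of 0.3-0.4
coalescent units so that incomplete lineage sorting is concentrated near the
shallow species — the regime in which concatenation is expected to
overestimate shallow node depths and lineage-mixing sampling (2S2L) to
inflate per-taxon diversity.

Every stochastic step derives its generator from (seed, stage, locus), so a
bundle is a pure function of (scenario, seed) and regenerating it is
byte-identical.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from ._seeds import spawn_rng
from .errors import ConfigurationError
from .filters import Locus
from .msc import ClockModel, SampleMap, SpeciesTreeModel, clade_key, scale_to_substitutions, simulate_gene_tree
from .seqsim import Alignment, SubstitutionModel, inject_missing, simulate_alignment
from .trees import Node, Tree, clade_sets, read_newick, write_newick

DEFAULT_TAXON_NEWICK = (
    "((((t1:400000,t2:400000):80000,t3:480000):80000,"
    "(t4:500000,t5:500000):60000):1440000,"
    "((t6:600000,t7:600000):600000,(t8:700000,t9:700000):500000):800000);"
)

DEFAULT_LINEAGE_SPLITS = {"t1": 160000.0, "t4": 180000.0, "t6": 200000.0, "t8": 150000.0}


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic study."""

    taxon_tree_newick: str = DEFAULT_TAXON_NEWICK
    lineage_splits: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGE_SPLITS))
    ne: float = 100000.0  # diploid effective size, every branch
    ne_overrides: dict = field(default_factory=dict)  # clade key -> Ne
    mu: float = 1e-8  # substitutions/site/generation
    clock_sd: float = 0.3  # sd of log per-locus rate multiplier
    n_loci: int = 300
    codons_per_locus: int = 300
    individuals_per_lineage: int = 2
    missing_rate: float = 0.10  # mean per-sequence missing fraction
    missing_jitter: float = 0.10  # uniform half-width around the mean
    block_length_mean: float = 30.0
    kappa: float = 3.0
    pi: tuple = (0.3, 0.2, 0.2, 0.3)
    alpha: float = 0.5
    n_categories: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.codons_per_locus < 1:
            raise ConfigurationError("n_loci and codons_per_locus must be >= 1")
        if self.individuals_per_lineage < 1:
            raise ConfigurationError("individuals_per_lineage must be >= 1")
        if self.ne <= 0 or self.mu <= 0:
            raise ConfigurationError("ne and mu must be > 0")
        if self.clock_sd < 0:
            raise ConfigurationError("clock_sd must be >= 0")
        for taxon, split in self.lineage_splits.items():
            if split <= 0:
                raise ConfigurationError(f"lineage split for {taxon!r} must be > 0")

    @property
    def locus_length(self) -> int:
        return 3 * self.codons_per_locus

    def substitution_model(self) -> SubstitutionModel:
        return SubstitutionModel(
            kappa=self.kappa,
            pi=tuple(self.pi),
            alpha=self.alpha,
            n_categories=self.n_categories,
        )

    def clock_model(self) -> ClockModel:
        return ClockModel(mu=self.mu, rate_sd=self.clock_sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi"] = list(self.pi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "pi" in d:
            d["pi"] = tuple(d["pi"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _lineage_tree(config: ScenarioConfig) -> tuple[Tree, dict[str, str]]:
    """Expand the taxon tree into the lineage-level population tree."""
    taxon_tree = read_newick(config.taxon_tree_newick, length_units="generations")
    taxon_tree.validate()
    if not taxon_tree.is_ultrametric(rel_tol=1e-9):
        raise ConfigurationError("taxon tree must be ultrametric")
    heights = taxon_tree.node_heights()
    lineage_to_species: dict[str, str] = {}
    taxa = set(taxon_tree.tip_labels())
    unknown = set(config.lineage_splits) - taxa
    if unknown:
        raise ConfigurationError(f"lineage splits for unknown taxa: {sorted(unknown)}")
    tree = taxon_tree.copy()
    for tip in list(tree.tips()):
        taxon = tip.label
        split = config.lineage_splits.get(taxon)
        if split is None:
            tip.label = f"{taxon}_L1"
            lineage_to_species[tip.label] = taxon
            continue
        divergence = tip.length  # tip height is 0, so branch = parent height
        if split >= divergence:
            raise ConfigurationError(
                f"lineage split for {taxon!r} ({split:g}) must be below its "
                f"divergence from other taxa ({divergence:g})"
            )
        tip.label = None
        tip.length = divergence - split
        for k in (1, 2):
            lineage = f"{taxon}_L{k}"
            tip.add_child(Node(label=lineage, length=split))
            lineage_to_species[lineage] = taxon
    tree.validate()
    return tree, lineage_to_species


def focal_clade_scenario(
    overrides: Optional[dict] = None,
) -> tuple[ScenarioConfig, SpeciesTreeModel, SampleMap]:
    """The default 9-taxon / 4-multilineage-taxon scenario, with overrides."""
    config = ScenarioConfig.from_dict({**ScenarioConfig().to_dict(), **(overrides or {})})
    model, samples = build_model(config)
    return config, model, samples


def build_model(config: ScenarioConfig) -> tuple[SpeciesTreeModel, SampleMap]:
    lineage_tree, lineage_to_species = _lineage_tree(config)
    ne = {
        clade_key(clade): config.ne_overrides.get(clade_key(clade), config.ne)
        for clade in clade_sets(lineage_tree).values()
    }
    model = SpeciesTreeModel(tree=lineage_tree, ne=ne, lineage_to_species=lineage_to_species)
    haplotypes: dict[str, tuple[str, str, str]] = {}
    for lineage, taxon in sorted(lineage_to_species.items()):
        for k in range(config.individuals_per_lineage):
            individual = f"{lineage}_i{k}"
            for h in range(2):
                haplotypes[f"{individual}_h{h}"] = (individual, lineage, taxon)
    return model, SampleMap(haplotypes)


@dataclass
class StudyBundle:
    """Everything a downstream experiment needs, with the simulation truth."""

    scenario: ScenarioConfig
    seed: int
    model: SpeciesTreeModel
    samples: SampleMap
    taxon_tree: Tree  # the true species tree collapsed to taxa
    loci: list[Locus]
    gene_trees_generations: dict[str, Tree]
    gene_trees_substitutions: dict[str, Tree]
    rate_multipliers: dict[str, float]
    manifest: dict

    def haplotype_to_taxon(self) -> dict[str, str]:
        return self.samples.haplotype_to_taxon()

    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]


def generate_study(scenario: ScenarioConfig, seed: Optional[int] = None) -> StudyBundle:
    """Simulate the full study: per locus, an MSC gene tree, a relaxed-clock
    rescaling, an HKY+gamma alignment, and block missing data."""
    if seed is None:
        seed = scenario.seed
    model, samples = build_model(scenario)
    taxon_tree = read_newick(scenario.taxon_tree_newick, length_units="generations")
    subst = scenario.substitution_model()
    clock = scenario.clock_model()
    loci: list[Locus] = []
    gt_gen: dict[str, Tree] = {}
    gt_sub: dict[str, Tree] = {}
    multipliers: dict[str, float] = {}
    locus_records = []
    for i in range(scenario.n_loci):
        locus_id = f"locus_{i:04d}"
        gene_tree = simulate_gene_tree(model, samples, rng=spawn_rng(seed, 1, i))
        scaled, mult = scale_to_substitutions(
            gene_tree, clock, rng=spawn_rng(seed, 2, i)
        )
        aln = simulate_alignment(
            scaled, subst, scenario.locus_length, rng=spawn_rng(seed, 3, i)
        )
        aln = inject_missing(
            aln,
            scenario.missing_rate,
            block_length_mean=scenario.block_length_mean,
            rng=spawn_rng(seed, 4, i),
            jitter=scenario.missing_jitter,
        )
        aln.frame = 0
        locus = Locus(id=locus_id, alignment=aln)
        loci.append(locus)
        gt_gen[locus_id] = gene_tree
        gt_sub[locus_id] = scaled
        multipliers[locus_id] = mult
        fracs = aln.missing_fractions()
        locus_records.append(
            {
                "id": locus_id,
                "rate_multiplier": mult,
                "gene_tree_height_generations": gene_tree.max_height(),
                "mean_missing_fraction": round(float(np.mean(list(fracs.values()))), 6),
                "max_missing_fraction": round(float(max(fracs.values())), 6),
            }
        )
    manifest = {
        "seed": int(seed),
        "scenario": scenario.to_dict(),
        "n_loci": scenario.n_loci,
        "locus_length": scenario.locus_length,
        "taxa": taxon_tree.tip_labels(),
        "lineages": sorted(model.lineage_to_species),
        "n_haplotypes": len(samples.haplotypes),
        "loci": locus_records,
    }
    return StudyBundle(
        scenario=scenario,
        seed=int(seed),
        model=model,
        samples=samples,
        taxon_tree=taxon_tree,
        loci=loci,
        gene_trees_generations=gt_gen,
        gene_trees_substitutions=gt_sub,
        rate_multipliers=multipliers,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write the bundle as plain-text files; partial output is removed on failure."""
    outdir = Path(outdir)
    created = not outdir.exists()
    try:
        (outdir / "loci").mkdir(parents=True, exist_ok=True)
        bundle.scenario.to_yaml(outdir / "scenario.yaml")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
        with open(outdir / "sample_map.tsv", "w") as fh:
            fh.write("haplotype\tindividual\tlineage\ttaxon\n")
            for hap in bundle.samples.haplotype_ids():
                ind, lin, tax = bundle.samples.haplotypes[hap]
                fh.write(f"{hap}\t{ind}\t{lin}\t{tax}\n")
        with open(outdir / "species_tree_lineages.nwk", "w") as fh:
            fh.write(write_newick(bundle.model.tree) + "\n")
        with open(outdir / "species_tree_taxa.nwk", "w") as fh:
            fh.write(write_newick(bundle.taxon_tree) + "\n")
        with open(outdir / "ne.tsv", "w") as fh:
            fh.write("population\tne\n")
            for key in sorted(bundle.model.ne):
                fh.write(f"{key}\t{bundle.model.ne[key]:.10g}\n")
        ids = bundle.locus_ids()
        with open(outdir / "gene_trees_generations.nwk", "w") as fh:
            for lid in ids:
                fh.write(write_newick(bundle.gene_trees_generations[lid]) + "\n")
        with open(outdir / "gene_trees_substitutions.nwk", "w") as fh:
            for lid in ids:
                fh.write(write_newick(bundle.gene_trees_substitutions[lid]) + "\n")
        for locus in bundle.loci:
            locus.alignment.write_fasta(outdir / "loci" / f"{locus.id}.fasta")
    except Exception:
        if created and outdir.exists():
            shutil.rmtree(outdir)
        raise


def load_bundle(outdir) -> StudyBundle:
    outdir = Path(outdir)
    scenario = ScenarioConfig.from_yaml(outdir / "scenario.yaml")
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    seed = manifest["seed"]
    model, samples = build_model(scenario)
    taxon_tree = read_newick(scenario.taxon_tree_newick, length_units="generations")
    ids = [rec["id"] for rec in manifest["loci"]]
    loci = [
        Locus(id=lid, alignment=Alignment.read_fasta(outdir / "loci" / f"{lid}.fasta", frame=0))
        for lid in ids
    ]
    with open(outdir / "gene_trees_generations.nwk") as fh:
        gt_gen = {
            lid: read_newick(line.strip(), length_units="generations")
            for lid, line in zip(ids, fh)
        }
    with open(outdir / "gene_trees_substitutions.nwk") as fh:
        gt_sub = {
            lid: read_newick(line.strip(), length_units="substitutions_per_site")
            for lid, line in zip(ids, fh)
        }
    multipliers = {rec["id"]: rec["rate_multiplier"] for rec in manifest["loci"]}
    return StudyBundle(
        scenario=scenario,
        seed=seed,
        model=model,
        samples=samples,
        taxon_tree=taxon_tree,
        loci=loci,
        gene_trees_generations=gt_gen,
        gene_trees_substitutions=gt_sub,
        rate_multipliers=multipliers,
        manifest=manifest,
    )
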