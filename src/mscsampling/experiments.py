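"""The three headline experiments, as pure functions of (config, seed).

* sampling experiment — treatments x replicates of 32-locus species-tree
  analyses with per-replicate allele assignments, RF concordance among
  replicates and against the all-data quartet tree, the concatenation tree
  and the true tree, plus per-taxon theta and a tree-height index;
* depth-bias experiment — relative node depths of the concatenation tree
  against a reference MSC tree (the true tree, or the quartet tree with
  coalescent branch lengths);
* method comparison — RF matrix over the estimator grid
  {concatenation, quartet} x {CL, CIL} x {all positions, positions 1+2}.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .comparison import DepthTable, depth_bias, one_tip_per_taxon, rf_matrix
from .errors import ConfigurationError
from .estimators import (
    build_quartet_table,
    coalescent_branch_lengths,
    concatenation_tree,
    estimate_gene_trees,
    per_taxon_theta,
    quartet_species_tree,
)
from .filters import (
    Locus,
    relative_tree_certainty,
    select_complete_loci,
    select_informative_loci,
    strip_third_positions,
)
from .sampling import Treatment, assign_alleles, draw_locus_sets
from .study import ScenarioConfig, StudyBundle, generate_study
from .trees import Tree, write_newick

TREATMENTS_DEFAULT = ("1S", "2S1L", "2S2L")


@dataclass
class ExperimentConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    treatments: tuple = TREATMENTS_DEFAULT
    n_replicates: int = 9
    loci_per_replicate: int = 32
    estimator_search: str = "nni"
    bootstrap_replicates: int = 100
    locus_pool: str = "CL"  # all | CL | CIL
    reference: str = "true"  # true | quartet
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.treatments) - {t.value for t in Treatment}
        if unknown:
            raise ConfigurationError(f"unknown treatments: {sorted(unknown)}")
        if self.locus_pool not in ("all", "CL", "CIL"):
            raise ConfigurationError(f"unknown locus_pool {self.locus_pool!r}")
        if self.reference not in ("true", "quartet"):
            raise ConfigurationError(f"unknown reference {self.reference!r}")
        if self.n_replicates < 1 or self.loci_per_replicate < 1:
            raise ConfigurationError("replicate design must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario"] = self.scenario.to_dict()
        d["treatments"] = list(self.treatments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "scenario" in d:
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "treatments" in d:
            d["treatments"] = tuple(d["treatments"])
        return cls(**d)


def locus_pool(config: ExperimentConfig, study: StudyBundle) -> list[Locus]:
    """Apply the configured locus filter (none, CL, or CL+TC>0.25)."""
    required = study.samples.haplotype_ids()
    if config.locus_pool == "all":
        return list(study.loci)
    cl = select_complete_loci(study.loci, required)
    if config.locus_pool == "CL":
        return cl
    ests = estimate_gene_trees(
        cl, bootstrap_replicates=config.bootstrap_replicates, seed=derive_seed(config.seed, 5)
    )
    scored = []
    for locus in cl:
        est = ests[locus.id]
        tc = (
            relative_tree_certainty(est.tree, est.bootstraps)
            if est.bootstraps and not est.degenerate
            else 0.0
        )
        scored.append(Locus(locus.id, locus.alignment, relative_tc=tc))
    return select_informative_loci(scored)


@dataclass
class ReplicateAnalysis:
    treatment: str
    replicate: int
    locus_ids: list[str]
    assignment_manifest: dict
    tree: Tree  # taxon-level topology
    cu_tree: Tree  # with coalescent-unit internal branch lengths
    quartet_score: float
    theta: dict[str, float]
    height_index: float
    internal_cu: float


@dataclass
class SamplingExperimentResult:
    config: ExperimentConfig
    analyses: list[ReplicateAnalysis]
    all_data_quartet_tree: Tree
    concatenation_taxon_tree: Tree
    true_tree: Tree
    rf: dict[str, pd.DataFrame]
    theta_table: pd.DataFrame
    height_table: pd.DataFrame
    manifest: dict

    @property
    def n_analyses(self) -> int:
        return len(self.analyses)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
        self.theta_table.to_csv(outdir / "theta.tsv", sep="\t", index=False)
        self.height_table.to_csv(outdir / "heights.tsv", sep="\t", index=False)
        for treatment, mat in self.rf.items():
            mat.to_csv(outdir / f"rf_{treatment}.tsv", sep="\t")
        with open(outdir / "replicate_trees.nwk", "w") as fh:
            for a in self.analyses:
                fh.write(write_newick(a.tree) + "\n")


def _replicate_analysis(
    study: StudyBundle,
    config: ExperimentConfig,
    treatment: str,
    replicate: int,
    loci: Sequence[Locus],
    multilineage_taxa: set[str],
) -> ReplicateAnalysis:
    t_index = sorted({t.value for t in Treatment}).index(treatment)
    a_seed = derive_seed(config.seed, 20, t_index, replicate)
    assignment = assign_alleles(
        study.samples, Treatment.from_string(treatment), multilineage_taxa, seed=a_seed
    )
    haps = assignment.all_haplotypes()
    hap_to_taxon = {
        h: taxon for taxon, pair in assignment.haplotypes.items() for h in pair
    }
    ests = estimate_gene_trees(
        loci, bootstrap_replicates=0,
        seed=derive_seed(config.seed, 21, t_index, replicate), labels=haps,
    )
    table = build_quartet_table([e.tree for e in ests.values()], hap_to_taxon)
    tree, score = quartet_species_tree(
        table, search=config.estimator_search, seed=a_seed
    )
    cu_tree = coalescent_branch_lengths(tree, table)
    theta = per_taxon_theta(loci, assignment)
    internal_cu = sum(
        n.length for n in cu_tree.nodes() if n.length is not None and not n.is_leaf
    )
    height_index = internal_cu + float(np.mean(list(theta.values()))) / 2.0
    return ReplicateAnalysis(
        treatment=treatment,
        replicate=replicate,
        locus_ids=[l.id for l in loci],
        assignment_manifest=assignment.to_manifest(),
        tree=tree,
        cu_tree=cu_tree,
        quartet_score=score,
        theta=theta,
        height_index=height_index,
        internal_cu=internal_cu,
    )


def run_sampling_experiment(
    config: ExperimentConfig, study: Optional[StudyBundle] = None
) -> SamplingExperimentResult:
    """Treatments x replicates of quartet species-tree analyses on disjoint
    32-locus sets, with concordance, theta and height summaries."""
    if study is None:
        study = generate_study(config.scenario, config.seed)
    pool = locus_pool(config, study)
    pool_ids = {l.id: l for l in pool}
    locus_sets = draw_locus_sets(
        sorted(pool_ids),
        n_sets=config.n_replicates,
        set_size=config.loci_per_replicate,
        seed=derive_seed(config.seed, 10),
    )
    multilineage = {t for t in study.samples.taxa()
                    if len(study.samples.lineages_of_taxon(t)) >= 2}
    hap_to_taxon = study.haplotype_to_taxon()

    # full-data reference estimates
    all_ests = estimate_gene_trees(
        pool, bootstrap_replicates=0, seed=derive_seed(config.seed, 11)
    )
    all_table = build_quartet_table([e.tree for e in all_ests.values()], hap_to_taxon)
    quartet_all_tree, _ = quartet_species_tree(
        all_table, search=config.estimator_search, seed=config.seed
    )
    concat_full = concatenation_tree(pool, study.samples.haplotype_ids())
    concat_taxon = one_tip_per_taxon(
        concat_full, study.samples, seed=derive_seed(config.seed, 12)
    )

    analyses: list[ReplicateAnalysis] = []
    for treatment in config.treatments:
        for r in range(config.n_replicates):
            loci_r = [pool_ids[lid] for lid in locus_sets[r]]
            analyses.append(
                _replicate_analysis(study, config, treatment, r, loci_r, multilineage)
            )

    # RF matrices per treatment: replicates + reference trees
    rf: dict[str, pd.DataFrame] = {}
    for treatment in config.treatments:
        labeled = [
            (f"rep{a.replicate}", a.tree)
            for a in analyses
            if a.treatment == treatment
        ]
        labeled += [
            ("quartet_all", quartet_all_tree),
            ("concatenation", concat_taxon),
            ("true", study.taxon_tree),
        ]
        rf[treatment] = rf_matrix(labeled)

    theta_rows, height_rows = [], []
    for a in analyses:
        for taxon, th in a.theta.items():
            theta_rows.append(
                {
                    "treatment": a.treatment,
                    "replicate": a.replicate,
                    "taxon": taxon,
                    "theta": th,
                    "multilineage": taxon in multilineage,
                }
            )
        height_rows.append(
            {
                "treatment": a.treatment,
                "replicate": a.replicate,
                "height_index": a.height_index,
                "internal_cu": a.internal_cu,
                "mean_theta": float(np.mean(list(a.theta.values()))),
            }
        )
    theta_table = pd.DataFrame(theta_rows)
    height_table = pd.DataFrame(height_rows)

    manifest = {
        "config": config.to_dict(),
        "study_seed": study.seed,
        "pool_size": len(pool),
        "locus_sets": {f"set_{i}": s for i, s in enumerate(locus_sets)},
        "n_analyses": len(analyses),
        "analyses": [
            {
                "treatment": a.treatment,
                "replicate": a.replicate,
                "locus_set": f"set_{a.replicate}",
                "assignment": a.assignment_manifest,
                "tree": write_newick(a.tree),
                "cu_tree": write_newick(a.cu_tree),
                "quartet_score": a.quartet_score,
                "height_index": a.height_index,
            }
            for a in analyses
        ],
        "reference_trees": {
            "quartet_all": write_newick(quartet_all_tree),
            "concatenation": write_newick(concat_taxon),
            "true": write_newick(study.taxon_tree),
        },
    }
    return SamplingExperimentResult(
        config=config,
        analyses=analyses,
        all_data_quartet_tree=quartet_all_tree,
        concatenation_taxon_tree=concat_taxon,
        true_tree=study.taxon_tree,
        rf=rf,
        theta_table=theta_table,
        height_table=height_table,
        manifest=manifest,
    )


def run_depth_bias_experiment(
    config: ExperimentConfig, study: Optional[StudyBundle] = None
) -> DepthTable:
    """Concatenation vs reference-MSC relative node depths on one study."""
    if study is None:
        study = generate_study(config.scenario, config.seed)
    pool = locus_pool(config, study)
    concat = concatenation_tree(pool, study.samples.haplotype_ids())
    if config.reference == "true":
        reference = study.taxon_tree
        ref_id = "true"
    else:
        ests = estimate_gene_trees(
            pool, bootstrap_replicates=0, seed=derive_seed(config.seed, 11)
        )
        table = build_quartet_table(
            [e.tree for e in ests.values()], study.haplotype_to_taxon()
        )
        topo, _ = quartet_species_tree(
            table, search=config.estimator_search, seed=config.seed
        )
        reference = coalescent_branch_lengths(topo, table)
        ref_id = "quartet"
    return depth_bias(
        concat,
        reference,
        samples=study.samples,
        seed=derive_seed(config.seed, 13),
        tree_a_id="concatenation",
        tree_b_id=ref_id,
    )


def run_method_comparison(
    config: ExperimentConfig,
    study: Optional[StudyBundle] = None,
    sampling_result: Optional[SamplingExperimentResult] = None,
) -> pd.DataFrame:
    """RF matrix over {concatenation, quartet} x {CL, CIL} x {all, pos 1+2},
    optionally including per-replicate sampling-experiment trees."""
    if study is None:
        study = generate_study(config.scenario, config.seed)
    required = study.samples.haplotype_ids()
    cl = select_complete_loci(study.loci, required)
    ests_cl = estimate_gene_trees(
        cl, bootstrap_replicates=config.bootstrap_replicates,
        seed=derive_seed(config.seed, 5),
    )
    scored = []
    for locus in cl:
        est = ests_cl[locus.id]
        tc = (
            relative_tree_certainty(est.tree, est.bootstraps)
            if est.bootstraps and not est.degenerate
            else 0.0
        )
        scored.append(Locus(locus.id, locus.alignment, relative_tc=tc))
    cil = select_informative_loci(scored)
    hap_to_taxon = study.haplotype_to_taxon()

    datasets = {"CL": cl}
    if cil:
        datasets["CIL"] = cil
    labeled: list[tuple[str, Tree]] = []
    for ds_name, ds_loci in datasets.items():
        for pos_name, variant in (
            ("all", list(ds_loci)),
            ("12", [strip_third_positions(l) for l in ds_loci]),
        ):
            concat = concatenation_tree(variant, required)
            labeled.append(
                (
                    f"concatenation_{ds_name}_{pos_name}",
                    one_tip_per_taxon(
                        concat, study.samples, seed=derive_seed(config.seed, 14)
                    ),
                )
            )
            ests = estimate_gene_trees(
                variant, bootstrap_replicates=0, seed=derive_seed(config.seed, 15)
            )
            table = build_quartet_table([e.tree for e in ests.values()], hap_to_taxon)
            qtree, _ = quartet_species_tree(
                table, search=config.estimator_search, seed=config.seed
            )
            labeled.append((f"quartet_{ds_name}_{pos_name}", qtree))
    labeled.append(("true", study.taxon_tree))
    if sampling_result is not None:
        for a in sampling_result.analyses:
            labeled.append((f"{a.treatment}_rep{a.replicate}", a.tree))
    return rf_matrix(labeled)
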