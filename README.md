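# mscsampling

Species-tree estimation under the multispecies coalescent (MSC) assumes
that each "species" is a panmictic population. Many real species are not:
they harbor deeply divergent phylogeographic lineages, so the alleles a
phylogeneticist assigns to a taxon may come from populations separated by
hundreds of thousands of generations. `mscsampling` is a simulation and
analysis toolkit for asking what that does to phylogenetic inference. It is
aimed at systematists and statistical phylogeneticists who want a
desk-scale, fully reproducible testbed rather than a cluster-scale Bayesian
pipeline.

The package provides:

- **MSC simulation on lineage-structured species trees.** A species tree
  whose tips are intraspecific lineages, with per-branch diploid effective
  size *N*<sub>e</sub>; gene trees coalesce within branches at pairwise rate
  1/(2*N*<sub>e</sub>) per generation, and are rescaled to
  substitutions/site by per-locus lognormal (mean 1) relaxed-clock rates.
- **Sequence simulation** under HKY+Γ (single κ and α, four discrete gamma
  categories) with block-structured missing data mimicking exon-capture
  dropout.
- **Locus filters**: codon trimming (any site >20% missing removes the
  codon), "complete loci" (CL: every sample present, every sequence <35%
  missing), "complete and informative loci" (CIL: relative tree certainty
  TC > 0.25 from 100 bootstrap gene trees), third-codon-position stripping,
  and parsimony-informative counts.
- **Haplotype-sampling treatments**: each taxon is represented by two
  alleles drawn as 1S (both haplotypes of one individual), 2S1L (one
  haplotype from each of two individuals of one lineage), or 2S2L (one
  haplotype from each of two divergent lineages — a deliberate violation of
  panmixia).
- **Estimators**: neighbor joining on Jukes–Cantor distances for gene trees
  and concatenation, a quartet-agreement summary-MSC species-tree estimator
  (exact search to 9 taxa, NNI hill climbing with restarts otherwise),
  coalescent-unit branch lengths from quartet discordance
  (τ̂ = −ln(1.5(1−p))), multi-locus bootstrap support, and a moment
  estimator of per-taxon diversity θ̂ (≈ 4*N*<sub>e</sub>μ) from each
  taxon's two alleles.
- **Comparisons**: Robinson–Foulds distances and matrices,
  one-tip-per-taxon pruning, mean-path ultrametricization, relative node
  depths, and the concatenation-vs-MSC depth-bias table
  (concatenation − MSC)/MSC.

## Worked example

```python
import numpy as np
from mscsampling import (
    ExperimentConfig, ScenarioConfig, generate_study, run_sampling_experiment,
)

scenario = ScenarioConfig()           # 9 taxa, 4 with two deep lineages,
study = generate_study(scenario, 7)   # 300 loci x 900 sites
config = ExperimentConfig(scenario=scenario, seed=7)
result = run_sampling_experiment(config, study=study)

print(result.n_analyses)
tt = result.theta_table
print(tt[tt.multilineage].groupby("treatment").theta.mean().round(5))
reps = [f"rep{i}" for i in range(9)]
for t in ("1S", "2S1L", "2S2L"):
    print(t, np.mean([result.rf[t].loc[r, "true"] for r in reps]))
```

Output:

```
27
treatment
1S      0.00387
2S1L    0.00403
2S2L    0.00719
Name: theta, dtype: float64
1S 0.4444444444444444
2S1L 0.8888888888888888
2S2L 0.2222222222222222
```

The experiment runs 3 treatments × 9 replicates = 27 species-tree analyses
on disjoint 32-locus sets. Mixing alleles across lineages (2S2L) inflates
the per-taxon diversity of the manipulated taxa by ~80% — the estimator is
absorbing the lineage split into within-taxon coalescence — yet the 2S2L
replicate topologies are, if anything, *closer* to the true species tree
(mean RF 0.22 vs 0.44/0.89): sampling across lineages hurts the diversity
parameters, not the topology.

A CLI mirrors the library (`mscsampling simulate|filter|estimate|compare|
experiment sampling|depth-bias|methods`).

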