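# Methods

## The generating model

The simulation truth is a rooted ultrametric *population* tree whose tips
are intraspecific lineages, together with a map from lineages to species
(taxa). Time is measured in generations; every branch (including the root
branch, which extends to infinity) carries a diploid effective population
size *N*e. Gene trees are generated by the standard multispecies coalescent:
within a branch holding *k* gene lineages, the waiting time to the next
coalescence is exponential with rate *k*(*k*−1)/2 × 1/(2*N*e) per
generation; lineages that fail to coalesce are censored into the parent
branch. Time is continuous — there is no generation-discrete approximation.
The diploid convention (pairwise rate 1/(2*N*e), so E[T₂] = 2*N*e and
θ = 4*N*e·μ) is used throughout.

Gene trees are rescaled to substitutions/site by a per-locus relaxed clock:
one multiplier *r* per locus drawn lognormal with E[*r*] = 1 (log-sd
`clock_sd`, default 0.3, log-mean −`clock_sd`²/2), strict clock within the
locus, branch length = generations × μ × *r*. μ defaults to 10⁻⁸
substitutions/site/generation. Units travel with every tree
(`generations`, `substitutions_per_site`, `coalescent_units`) and are never
converted implicitly.

Sequences evolve under HKY+Γ: a single κ (default 3) and base frequencies
π, with discrete-gamma rate heterogeneity (default α = 0.5, 4 categories;
category rates are the means of the equal-probability quantile bins of
Gamma(α, rate α), renormalized to mean exactly 1). The rate matrix is
normalized to one expected substitution per unit branch length. Sites draw
their category independently and uniformly.

Missing data are injected per sequence as contiguous N blocks (geometric
block lengths, default mean 30 sites) until a per-sequence target fraction
is reached; the target is the configured mean rate plus a uniform jitter
(default 0.10 ± 0.10), emulating exon-capture dropout rather than i.i.d.
site missingness. With zero jitter the injected count is exact, which the
filter tests exploit.

## The default scenario

The focal scenario has 9 taxa on a mixed pectinate/balanced topology with
root height 2×10⁶ generations and constant *N*e = 10⁵. Three internal
branches are short (0.3–0.4 coalescent units; 1 CU = 2*N*e generations), so
incomplete lineage sorting is concentrated near the shallow species. Four
taxa are split into two lineages each, with splits at 150–200 kgen — 0.75–1
CU deep, i.e. 37–50% of the shallowest interspecific divergence. That depth
is a stated assumption: it makes across-lineage allele pairs roughly twice
as divergent as within-lineage pairs
(E[π] = 2μ(t_split + 2*N*e) ≈ 0.0072 vs 4*N*e·μ = 0.004 per site), so the
2S2L treatment is a gross violation of panmixia by construction. Each
lineage carries two diploid individuals (two phased haplotypes each,
`*_h0`/`*_h1`), 52 haplotypes in total. The default study is 300 loci of
300 codons — the scale of a curated informative-locus set, not of a full
capture experiment — and everything is configurable upward.

What the generator does *not* emulate: selection, migration/gene flow
after lineage separation, recombination within loci, indels, alignment
error, base-composition heterogeneity among lineages, and linked loci.
Passing tests therefore demonstrate correctness of the inference machinery
under the MSC's own assumptions, not robustness to every real-data
pathology.

## Filters

Missing characters are {N, −, ?} everywhere. Boundaries follow the wording
they implement exactly: codon trimming removes a codon when any of its
three sites has missing fraction strictly greater than 0.20; a locus is
"complete" (CL) when every required sample is present and every sequence is
strictly below 0.35 missing; "complete and informative" (CIL) additionally
requires relative tree certainty strictly above 0.25.

Tree certainty uses the original internode-certainty definition on the two
most frequent conflicting splits: for a reference split with bootstrap
frequency *p*₁ and strongest incompatible split frequency *p*₂,
IC = 1 + Σ p̂ᵢ log₂ p̂ᵢ with p̂ᵢ = pᵢ/(p₁+p₂), signed negative when the
conflict is more frequent than the split itself; relative TC is the mean IC
over the reference tree's internal splits. Bootstrap gene trees come from
the package's own NJ estimator (100 site-resampling replicates by
default) — a deliberate desk-scale stand-in for maximum-likelihood
bootstrapping; the TC variant is documented rather than asserted to match
any particular ML implementation's normalization.

## Estimators

Gene trees and concatenation trees are neighbor joining on Jukes–Cantor
distances with pairwise deletion. NJ resolves Q-matrix ties to the first
row-major minimum (deterministic); negative limb estimates are clamped to
zero with the deficit moved to the sister limb, preserving the pair's
summed length; p ≥ 0.75 is outside the JC domain and is reported as a
capped distance of 5 substitutions/site with a saturation flag. Distance/NJ
stands in for ML tree search throughout: it is deterministic, fast, exact
on additive inputs, and sufficient for the comparative questions the
experiments ask.

The summary-MSC estimator maximizes total quartet agreement with the
estimated gene trees. Each gene tree contributes, for every taxon quartet
and every combination of one allele per taxon, weight 1/(number of
combinations) to the resolution it induces (ties — unresolved quartets —
contribute nothing). Exact search enumerates all unrooted topologies (up to
9 taxa, 135,135 trees); the default search hill-climbs by
nearest-neighbor interchanges from an NJ tree on quartet-derived average
distances plus 11 random restarts, accepting strict improvements; co-optimal
topologies resolve to the lexicographically smallest canonical Newick.
Internal branch lengths in coalescent units invert the three-taxon
discordance formula: with *p* the mean fraction of straddling-quartet
weight supporting a branch, τ̂ = −ln(1.5(1−*p*)), zero for *p* ≤ 1/3 and
capped at 10 CU as *p* → 1.

Multi-locus bootstrap support resamples whole loci with replacement
(no site resampling within loci — a config-level choice, since gene-tree
level resampling is what the locus-resampling design tests); support is the
fraction of replicate trees containing each point-tree split.

θ̂ per taxon is the mean over loci of pairwise differences per comparable
site between the taxon's two assigned haplotypes — a moment stand-in for
model-based *N*e estimates; E[θ̂] = 4*N*e·μ within a panmictic lineage and
2μ(t + 2*N*e) across lineages split t generations ago.

## Comparisons

Robinson–Foulds distances are symmetric differences of non-trivial split
sets; polytomous trees simply contribute fewer splits. Concatenation trees
(tips = haplotypes) are reduced to one uniformly chosen tip per taxon
before comparison, with path lengths preserved through suppressed nodes.
Unrooted estimates are midpoint-rooted. Ultrametricization uses mean-path
smoothing — each node sits at the mean of its subtree's root-to-tip path
lengths, children rescaled proportionally — which is deterministic, has no
smoothing hyperparameter, fixes ultrametric inputs, and places the root at
the least-squares-optimal single height for the observed tip depths. It is
a stand-in for penalized-likelihood rate smoothing. Relative node depths
are node heights divided by root height, keyed by split; when a rooted
tree's two root children induce the same split, the deeper node is used.
The depth-bias statistic for a matched split is (A − B)/B, summarized by
quartile of the reference depth; unmatched splits are counted and reported,
never silently dropped.

The depth-bias experiment can compare concatenation against the true tree
or against the quartet tree with coalescent branch lengths; neither is
claimed identical to a posterior-mean-height composite, and both modes are
provided.

## Experiments and reproducibility

The sampling experiment draws nine pairwise-disjoint 32-locus sets (without
replacement) from the filtered pool and shares them across the three
treatments, so treatment contrasts are paired by replicate. The pool
defaults to the complete (CL) loci; with a 300-locus study a strict CIL
subset cannot supply 9×32 = 288 disjoint loci, and the CIL filter is
instead exercised by the method-comparison experiment. The reported
"tree height" index is the sum of estimated internal coalescent-unit
branch lengths plus a θ̂/2 tip term; it is an index for comparing
treatments, not a posterior tree height.

Every stochastic step derives its generator from the master seed plus a
fixed stage/replicate tag (numpy `SeedSequence`), so studies, assignments
and experiments are pure functions of (config, seed), and regenerated
bundles are byte-identical. Manifests record locus sets, assignments with
full provenance, seeds, trees and scores — enough to replay any analysis
without re-simulation.

## Numerical choices and degenerate inputs

Ultrametricity checks use relative tolerance 10⁻⁹; quartet-weight sums are
validated to 10⁻⁹; HKY transition matrices are computed by symmetric
eigendecomposition, clipped at zero and row-renormalized. Zero-variation
loci yield star-like NJ trees and are flagged degenerate (their TC is
reported as 0). Zero-length branches are permitted and contribute splits
only if the edge exists structurally. A single sampled haplotype yields a
single-tip gene tree of height zero.

## Known limitations

The estimators are deliberate stand-ins for the heavyweight tools they
model (ML tree search, Bayesian MSC inference): absolute accuracies will
differ even where directional conclusions agree. The quartet-table cost
grows as C(taxa, 4) × allele combinations, which is fine to ~15 taxa and a
few alleles but not genome-scale. The exact topology search is capped at 9
taxa. Allele weighting for multi-allele taxa (uniform over combinations) is
one defensible choice among several, and is documented rather than claimed
canonical.
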