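"""Allele-assignment treatments and replicate locus-set draws.

Each species-tree analysis uses exactly two alleles (haplotype sequences)
per taxon. The treatments differ in where those two alleles come from:

* ``1S``   — both haplotypes of one randomly chosen diploid individual;
* ``2S1L`` — one haplotype from each of two individuals of one randomly
  chosen intraspecific lineage;
* ``2S2L`` — one haplotype from one individual in each of two deeply
  divergent lineages (a deliberate violation of within-taxon panmixia).

Taxa without designated multi-lineage structure follow the 2S1L rule under
every treatment, falling back to 1S when only a single individual exists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seeds import spawn_rng
from .errors import ConfigurationError, SamplingError, SizingError
from .msc import SampleMap


class Treatment(str, enum.Enum):
    ONE_SAMPLE = "1S"
    TWO_SAMPLES_ONE_LINEAGE = "2S1L"
    TWO_SAMPLES_TWO_LINEAGES = "2S2L"

    @classmethod
    def from_string(cls, value: str) -> "Treatment":
        for t in cls:
            if t.value == value:
                return t
        raise ConfigurationError(f"unknown treatment {value!r}")


@dataclass
class AlleleAssignment:
    """Chosen haplotype pair per taxon, with full provenance."""

    treatment: Treatment
    seed: int
    haplotypes: dict[str, tuple[str, str]]  # taxon -> (hap, hap)
    provenance: dict[str, list[dict]] = field(default_factory=dict)

    def validate(self, samples: SampleMap, multilineage_taxa: set[str]) -> None:
        for taxon, pair in self.haplotypes.items():
            if len(pair) != 2 or len(set(pair)) != 2:
                raise SamplingError(f"taxon {taxon!r}: need 2 distinct haplotypes")
            for hap in pair:
                if hap not in samples.haplotypes:
                    raise SamplingError(f"unknown haplotype {hap!r}")
                if samples.taxon_of(hap) != taxon:
                    raise SamplingError(
                        f"haplotype {hap!r} does not belong to taxon {taxon!r}"
                    )
            inds = {samples.haplotypes[h][0] for h in pair}
            lins = {samples.haplotypes[h][1] for h in pair}
            if taxon in multilineage_taxa:
                if self.treatment is Treatment.ONE_SAMPLE and len(inds) != 1:
                    raise SamplingError(f"1S violated for taxon {taxon!r}")
                if self.treatment is Treatment.TWO_SAMPLES_ONE_LINEAGE and (
                    len(inds) != 2 or len(lins) != 1
                ):
                    fallback_ok = len(inds) == 1 and not any(
                        len(samples.individuals_of_lineage(l)) >= 2
                        for l in samples.lineages_of_taxon(taxon)
                    )
                    if not fallback_ok:
                        raise SamplingError(f"2S1L violated for taxon {taxon!r}")
                if self.treatment is Treatment.TWO_SAMPLES_TWO_LINEAGES and len(lins) != 2:
                    raise SamplingError(f"2S2L violated for taxon {taxon!r}")

    def all_haplotypes(self) -> list[str]:
        return sorted(h for pair in self.haplotypes.values() for h in pair)

    def to_manifest(self) -> dict:
        return {
            "treatment": self.treatment.value,
            "seed": self.seed,
            "haplotypes": {t: list(p) for t, p in sorted(self.haplotypes.items())},
            "provenance": {t: self.provenance[t] for t in sorted(self.provenance)},
        }


def _one_sample(samples: SampleMap, taxon: str, rng) -> tuple[tuple[str, str], list[dict]]:
    inds = samples.individuals_of_taxon(taxon)
    ind = inds[int(rng.integers(len(inds)))]
    h = samples.haplotypes_of_individual(ind)
    prov = [
        {"haplotype": hap, "individual": ind, "lineage": samples.lineage_of(hap)}
        for hap in h
    ]
    return (h[0], h[1]), prov


def _two_samples_one_lineage(
    samples: SampleMap, taxon: str, rng, allow_fallback: bool
) -> tuple[tuple[str, str], list[dict]]:
    lineages = [
        l
        for l in samples.lineages_of_taxon(taxon)
        if len(samples.individuals_of_lineage(l)) >= 2
    ]
    if not lineages:
        if allow_fallback and samples.individuals_of_taxon(taxon):
            return _one_sample(samples, taxon, rng)
        raise SamplingError(
            f"taxon {taxon!r}: no lineage with >=2 individuals for 2S1L"
        )
    lineage = lineages[int(rng.integers(len(lineages)))]
    inds = samples.individuals_of_lineage(lineage)
    picked = rng.choice(len(inds), size=2, replace=False)
    pair, prov = [], []
    for idx in sorted(int(i) for i in picked):
        ind = inds[idx]
        haps = samples.haplotypes_of_individual(ind)
        hap = haps[int(rng.integers(2))]
        pair.append(hap)
        prov.append({"haplotype": hap, "individual": ind, "lineage": lineage})
    return (pair[0], pair[1]), prov


def _two_samples_two_lineages(
    samples: SampleMap, taxon: str, rng
) -> tuple[tuple[str, str], list[dict]]:
    lineages = samples.lineages_of_taxon(taxon)
    if len(lineages) < 2:
        raise ConfigurationError(
            f"taxon {taxon!r}: 2S2L requires >=2 lineages, found {len(lineages)}"
        )
    picked = rng.choice(len(lineages), size=2, replace=False)
    pair, prov = [], []
    for idx in sorted(int(i) for i in picked):
        lineage = lineages[idx]
        inds = samples.individuals_of_lineage(lineage)
        ind = inds[int(rng.integers(len(inds)))]
        haps = samples.haplotypes_of_individual(ind)
        hap = haps[int(rng.integers(2))]
        pair.append(hap)
        prov.append({"haplotype": hap, "individual": ind, "lineage": lineage})
    return (pair[0], pair[1]), prov


def assign_alleles(
    samples: SampleMap,
    treatment: Treatment,
    multilineage_taxa: Iterable[str],
    seed: int,
    allow_fallback: bool = True,
) -> AlleleAssignment:
    """Draw one two-allele assignment per taxon under the given treatment.

    Pure function of (samples, treatment, multilineage_taxa, seed).
    """
    if isinstance(treatment, str):
        treatment = Treatment.from_string(treatment)
    multi = set(multilineage_taxa)
    taxa = samples.taxa()
    unknown = multi - set(taxa)
    if unknown:
        raise ConfigurationError(f"multilineage taxa not in sample map: {sorted(unknown)}")
    rng = spawn_rng(seed)
    haplotypes: dict[str, tuple[str, str]] = {}
    provenance: dict[str, list[dict]] = {}
    for taxon in taxa:  # sorted -> deterministic consumption of the stream
        if taxon in multi:
            if treatment is Treatment.ONE_SAMPLE:
                pair, prov = _one_sample(samples, taxon, rng)
            elif treatment is Treatment.TWO_SAMPLES_ONE_LINEAGE:
                pair, prov = _two_samples_one_lineage(samples, taxon, rng, allow_fallback)
            else:
                pair, prov = _two_samples_two_lineages(samples, taxon, rng)
        else:
            pair, prov = _two_samples_one_lineage(samples, taxon, rng, allow_fallback)
        haplotypes[taxon] = pair
        provenance[taxon] = prov
    assignment = AlleleAssignment(
        treatment=treatment, seed=seed, haplotypes=haplotypes, provenance=provenance
    )
    assignment.validate(samples, multi)
    return assignment


def draw_locus_sets(
    pool: Sequence[str],
    n_sets: int = 9,
    set_size: int = 32,
    seed: int = 0,
) -> list[list[str]]:
    """Pairwise-disjoint random locus sets drawn without replacement."""
    pool = list(pool)
    if len(set(pool)) != len(pool):
        raise ConfigurationError("locus pool contains duplicate ids")
    needed = n_sets * set_size
    if needed > len(pool):
        raise SizingError(
            f"need {needed} loci ({n_sets} sets x {set_size}) but pool has {len(pool)}"
        )
    rng = spawn_rng(seed)
    order = rng.permutation(len(pool))
    return [
        [pool[int(order[s * set_size + i])] for i in range(set_size)]
        for s in range(n_sets)
    ]
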