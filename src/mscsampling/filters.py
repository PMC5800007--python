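"""Alignment-processing rules applied per locus before tree estimation.

These reproduce the pipeline's filtering semantics exactly as worded:
codon columns are trimmed when any site exceeds 20% missing data (strict),
"complete" loci (CL) require every sample present with every sequence under
35% missing (strict), and "complete and informative" loci (CIL) additionally
require a relative tree certainty (TC) strictly above 0.25. Missing
characters are {N, -, ?}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .seqsim import FIRST_MISSING_CODE, Alignment
from .trees import Bipartition, Tree, are_compatible, bipartition_set


@dataclass
class Locus:
    """A codon-aware alignment with filter metadata."""

    id: str
    alignment: Alignment
    relative_tc: Optional[float] = None
    parsimony_informative_count: Optional[int] = None
    degenerate: bool = False  # no variation; gene tree/TC not meaningful

    @property
    def frame(self) -> Optional[int]:
        return self.alignment.frame

    def missing_fractions(self) -> dict[str, float]:
        return self.alignment.missing_fractions()

    def labels(self) -> list[str]:
        return list(self.alignment.names)


def trim_codons(locus: Locus, max_missing_site_fraction: float = 0.20) -> Locus:
    """Drop every codon column triplet containing a site with missing fraction
    strictly above the threshold."""
    if locus.frame is None:
        raise ConfigurationError(f"locus {locus.id!r}: codon frame not set")
    aln = locus.alignment
    if aln.length % 3 != 0:
        raise ConfigurationError(f"locus {locus.id!r}: length not divisible by 3")
    miss = aln.missing_mask().mean(axis=0)  # per-site missing fraction
    bad_site = miss > max_missing_site_fraction
    bad_codon = bad_site.reshape(-1, 3).any(axis=1)
    keep_cols = np.repeat(~bad_codon, 3)
    trimmed = aln.take_columns(np.nonzero(keep_cols)[0])
    trimmed.frame = 0
    return replace(locus, alignment=trimmed, relative_tc=None,
                   parsimony_informative_count=None)


def strip_third_positions(locus: Locus) -> Locus:
    """Remove every third codon position; the result has no codon frame, so a
    second application is rejected."""
    if locus.frame is None:
        raise ConfigurationError(f"locus {locus.id!r}: codon frame not set")
    aln = locus.alignment
    keep = [i for i in range(aln.length) if i % 3 != 2]
    stripped = aln.take_columns(keep)
    stripped.frame = None
    return replace(locus, alignment=stripped, relative_tc=None,
                   parsimony_informative_count=None)


def count_parsimony_informative(alignment: Alignment) -> int:
    """Columns with >=2 distinct non-missing states each present in >=2 sequences."""
    codes = alignment.codes
    count = 0
    for col in codes.T:
        col = col[col < FIRST_MISSING_CODE]
        if col.size < 4:
            continue
        _vals, freq = np.unique(col, return_counts=True)
        if (freq >= 2).sum() >= 2:
            count += 1
    return count


def internode_certainty(p1: float, p2: float) -> float:
    """IC from the frequencies of a split and its strongest conflicting split.

    IC = 1 + sum_i phat_i log2 phat_i with phat_i = p_i / (p1 + p2).
    Returns 0.0 when neither split was ever observed.
    """
    total = p1 + p2
    if total <= 0:
        return 0.0
    ic = 1.0
    for p in (p1, p2):
        ph = p / total
        if ph > 0:
            ic += ph * np.log2(ph)
    # sign convention: a branch whose strongest conflict is more frequent than
    # the branch itself carries negative certainty
    return float(ic if p1 >= p2 else -ic)


def relative_tree_certainty(
    reference_tree: Tree, bootstrap_trees: Sequence[Tree]
) -> float:
    """Mean internode certainty over the reference tree's internal splits,
    from bootstrap split frequencies. Value in [-1, 1]."""
    if not bootstrap_trees:
        raise InputError("need at least one bootstrap tree")
    ref_tips = frozenset(reference_tree.tip_labels())
    for bt in bootstrap_trees:
        if frozenset(bt.tip_labels()) != ref_tips:
            raise InputError("bootstrap tree tip set differs from reference")
    n_boot = len(bootstrap_trees)
    counts: dict[Bipartition, int] = {}
    for bt in bootstrap_trees:
        for b in bipartition_set(bt):
            counts[b] = counts.get(b, 0) + 1
    ref_splits = bipartition_set(reference_tree)
    if not ref_splits:
        return 0.0
    ics = []
    for b in ref_splits:
        p1 = counts.get(b, 0) / n_boot
        conflict = [
            c / n_boot for other, c in counts.items()
            if other != b and not are_compatible(b, other)
        ]
        p2 = max(conflict) if conflict else 0.0
        ics.append(internode_certainty(p1, p2))
    return float(np.mean(ics))


def select_complete_loci(
    loci: Sequence[Locus],
    required_samples: Iterable[str],
    max_missing_fraction: float = 0.35,
) -> list[Locus]:
    """CL rule: every required sample present, and every sequence strictly
    under the missing-fraction threshold."""
    required = set(required_samples)
    if not required:
        raise ConfigurationError("required sample set is empty")
    kept = []
    for locus in loci:
        present = set(locus.labels())
        if not required <= present:
            continue
        if all(f < max_missing_fraction for f in locus.missing_fractions().values()):
            kept.append(locus)
    return kept


def select_informative_loci(
    loci: Sequence[Locus], tc_threshold: float = 0.25
) -> list[Locus]:
    """CIL rule: relative TC strictly above the threshold; order preserved."""
    for locus in loci:
        if locus.relative_tc is None:
            raise InputError(f"locus {locus.id!r} has no relative TC score")
    return [l for l in loci if l.relative_tc > tc_threshold]


def locus_report(
    loci: Sequence[Locus],
    required_samples: Optional[Iterable[str]] = None,
    max_missing_fraction: float = 0.35,
    tc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-locus TSV-ready table: length, missingness, PI count, TC, CL/CIL flags."""
    rows = []
    required = set(required_samples) if required_samples is not None else None
    for locus in loci:
        fracs = locus.missing_fractions()
        complete = (
            (required is None or required <= set(locus.labels()))
            and all(f < max_missing_fraction for f in fracs.values())
        )
        pi = locus.parsimony_informative_count
        if pi is None:
            pi = count_parsimony_informative(locus.alignment)
        rows.append(
            {
                "locus": locus.id,
                "length": locus.alignment.length,
                "n_seqs": locus.alignment.n_seqs,
                "max_missing_fraction": max(fracs.values()) if fracs else 0.0,
                "mean_missing_fraction": float(np.mean(list(fracs.values()))) if fracs else 0.0,
                "parsimony_informative": pi,
                "relative_tc": locus.relative_tc,
                "complete": complete,
                "informative": (
                    complete
                    and locus.relative_tc is not None
                    and locus.relative_tc > tc_threshold
                ),
            }
        )
    return pd.DataFrame(rows)
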