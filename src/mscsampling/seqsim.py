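"""HKY+Γ sequence simulation along substitution-scaled gene trees, plus
block-structured missing-data injection mimicking exon-capture dropout.

The substitution model is nucleotide-level HKY with discrete-gamma rate
heterogeneity: sites fall with equal probability into ``n_categories``
categories whose rates are the means of the equal-probability quantile bins
of a Gamma(alpha, 1/alpha) distribution, renormalized to mean 1. The rate
matrix is normalized to one expected substitution per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammainc

from ._seeds import spawn_rng
from .errors import ConfigurationError, InputError, UnitError
from .trees import Tree

ALPHABET = "ACGTN-?"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
MISSING_CODES = (4, 5, 6)  # N, -, ?
FIRST_MISSING_CODE = 4


class Alignment:
    """Equal-length sequence records over {A,C,G,T,N,-,?}.

    Internally a (n_seqs, length) uint8 code matrix for fast column work;
    ``frame`` is the codon-frame offset (``None`` when no frame applies,
    e.g. after third-position stripping).
    """

    def __init__(self, names: list[str], codes: np.ndarray, frame: Optional[int] = None):
        if len(names) != codes.shape[0]:
            raise InputError("names/row count mismatch")
        if len(set(names)) != len(names):
            raise InputError("duplicate sequence labels")
        if codes.size and codes.max() >= len(ALPHABET):
            raise InputError("invalid sequence codes")
        self.names = list(names)
        self.codes = np.asarray(codes, dtype=np.uint8)
        self.frame = frame

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]], frame: Optional[int] = None
    ) -> "Alignment":
        names, rows = [], []
        for name, seq in records:
            names.append(name)
            seq = seq.upper()
            try:
                rows.append([_CODE[c] for c in seq])
            except KeyError as exc:
                raise InputError(f"invalid character {exc.args[0]!r} in {name!r}") from None
        arr = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, 0), np.uint8)
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise InputError(f"unequal sequence lengths: {sorted(lengths)}")
        return cls(names, arr, frame=frame)

    # -- accessors ---------------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, name: str) -> str:
        row = self.codes[self.names.index(name)]
        return "".join(ALPHABET[c] for c in row)

    def to_records(self) -> list[tuple[str, str]]:
        return [(n, self.sequence(n)) for n in self.names]

    def missing_mask(self) -> np.ndarray:
        return self.codes >= FIRST_MISSING_CODE

    def missing_fractions(self) -> dict[str, float]:
        if self.length == 0:
            return {n: 0.0 for n in self.names}
        fr = self.missing_mask().mean(axis=1)
        return {n: float(f) for n, f in zip(self.names, fr)}

    def subset(self, names: Iterable[str]) -> "Alignment":
        names = list(names)
        idx = [self.names.index(n) for n in names]
        return Alignment(names, self.codes[idx].copy(), frame=self.frame)

    def take_columns(self, columns) -> "Alignment":
        cols = np.asarray(columns, dtype=int)
        return Alignment(list(self.names), self.codes[:, cols].copy(), frame=self.frame)

    def copy(self) -> "Alignment":
        return Alignment(list(self.names), self.codes.copy(), frame=self.frame)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.frame == other.frame
            and self.codes.shape == other.codes.shape
            and bool(np.all(self.codes == other.codes))
        )

    # -- FASTA I/O ---------------------------------------------------------
    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.to_records()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def read_fasta(cls, path, frame: Optional[int] = None) -> "Alignment":
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls.from_records(records, frame=frame)


@dataclass
class SubstitutionModel:
    """HKY + discrete-gamma rates.

    kappa: transition/transversion rate ratio; pi: stationary base frequencies
    (A, C, G, T); alpha: gamma shape; n_categories: discrete categories.
    """

    kappa: float = 3.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 0.5
    n_categories: int = 4

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ConfigurationError("pi must be 4 positive frequencies summing to 1")
        if self.kappa <= 0 or self.alpha <= 0:
            raise ConfigurationError("kappa and alpha must be > 0")
        if self.n_categories < 1:
            raise ConfigurationError("n_categories must be >= 1")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator normalized to 1 expected substitution per unit time."""
        pi = np.asarray(self.pi, float)
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = (self.kappa if (i, j) in transitions else 1.0) * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate

    def category_rates(self) -> np.ndarray:
        """Mean-of-quantile-bin discrete gamma rates (mean exactly 1)."""
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        from scipy.stats import gamma as gamma_dist

        a = self.alpha
        bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean of Gamma(a, rate=a) over (lo, hi), times k (each bin has mass 1/k)
        upper = gammainc(a + 1, a * bounds[1:])
        lower = gammainc(a + 1, a * bounds[:-1])
        rates = k * (upper - lower)
        return rates / rates.mean()

    def _eigen(self):
        q = self.rate_matrix()
        pi = np.asarray(self.pi, float)
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2.0)
        return w, u, d

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t), row-stochastic; rows = parent state, columns = child state."""
        if t < 0:
            raise InputError("negative branch length")
        w, u, d = self._eigen()
        p = (u * np.exp(w * t)) @ u.T
        p = p / d[:, None] * d[None, :]
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def simulate_alignment(
    gene_tree: Tree,
    model: SubstitutionModel,
    length: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Alignment:
    """Evolve ``length`` sites independently down a substitution-scaled tree."""
    if gene_tree.length_units != "substitutions_per_site":
        raise UnitError(
            f"expected substitutions_per_site, got {gene_tree.length_units!r}"
        )
    if length <= 0:
        raise ConfigurationError("length must be positive")
    if rng is None:
        rng = spawn_rng(seed if seed is not None else 0)

    pi = np.asarray(model.pi, float)
    rates = model.category_rates()
    k = len(rates)
    site_cat = rng.integers(k, size=length)
    w, u, d = model._eigen()

    def pmat(t: float, rate: float) -> np.ndarray:
        p = (u * np.exp(w * t * rate)) @ u.T
        p = p / d[:, None] * d[None, :]
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(4, size=length, p=pi)
    states[id(gene_tree.root)] = root_states
    tip_states: dict[str, np.ndarray] = {}
    if gene_tree.root.is_leaf:
        tip_states[gene_tree.root.label] = root_states

    for node in gene_tree.root.preorder():
        parent_states = states[id(node)]
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            child_states = np.empty(length, dtype=np.int64)
            for c in range(k):
                mask = site_cat == c
                m = int(mask.sum())
                if m == 0:
                    continue
                cum = np.cumsum(pmat(t, rates[c]), axis=1)
                rows = cum[parent_states[mask]]
                udraw = rng.random(m)
                child_states[mask] = (udraw[:, None] > rows).sum(axis=1)
            states[id(child)] = child_states
            if child.is_leaf:
                tip_states[child.label] = child_states

    names = gene_tree.tip_labels()
    codes = np.vstack([tip_states[n] for n in names]).astype(np.uint8)
    frame = 0 if length % 3 == 0 else None
    return Alignment(names, codes, frame=frame)


def inject_missing(
    alignment: Alignment,
    per_sequence_rate: float,
    block_length_mean: float = 30.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.0,
) -> Alignment:
    """Replace contiguous blocks with N until each sequence hits its target
    missing fraction.

    The per-sequence target is ``per_sequence_rate`` plus a uniform jitter on
    ``[-jitter, +jitter]`` (clipped to [0, 0.95]); ``jitter=0`` gives every
    sequence exactly the requested count of N sites. Block lengths are
    geometric with the given mean, emulating capture dropout.
    """
    if not (0 <= per_sequence_rate < 1):
        raise ConfigurationError("per_sequence_rate must be in [0, 1)")
    if jitter < 0 or per_sequence_rate + jitter >= 1:
        raise ConfigurationError("jitter out of range")
    if block_length_mean < 1:
        raise ConfigurationError("block_length_mean must be >= 1")
    if rng is None:
        rng = spawn_rng(seed if seed is not None else 0)

    out = alignment.copy()
    L = out.length
    if L == 0 or per_sequence_rate == 0 and jitter == 0:
        return out
    p_block = 1.0 / block_length_mean
    for i in range(out.n_seqs):
        target_frac = per_sequence_rate
        if jitter > 0:
            target_frac = float(
                np.clip(per_sequence_rate + rng.uniform(-jitter, jitter), 0.0, 0.95)
            )
        target = int(round(target_frac * L))
        if target == 0:
            continue
        mask = np.zeros(L, dtype=bool)
        masked = 0
        while masked < target:
            start = int(rng.integers(L))
            blen = int(rng.geometric(p_block))
            block = np.arange(start, min(L, start + blen))
            new = block[~mask[block]]
            need = target - masked
            if len(new) > need:
                new = new[:need]
            mask[new] = True
            masked += len(new)
        row = out.codes[i]
        row[mask] = _CODE["N"]
    return out
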