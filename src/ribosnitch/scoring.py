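"""SNP scoring: accessibility correlation, exhaustive mutation scan, empirical p-value.

The score of a substitution is the Pearson correlation coefficient between
the wild-type and mutant *accessibility vectors* — the per-nucleotide
probability of being paired, obtained as column sums of the base-pair
probability matrix.  A correlation near 1 means the mutation leaves the
Boltzmann ensemble essentially unchanged; low values flag candidate
riboSNitches.  Significance is assigned non-parametrically: all 3n possible
single substitutions of the sequence are scored, and the p-value of the
variant of interest is its rank (ties counted conservatively, self
included) divided by 3n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import BASES, EnergyModel
from .sequence import Mutation, RnaSequence
from .thermo import BasePairProbabilityMatrix, partition_function

logger = logging.getLogger(__name__)

#: two constant vectors are "equal" (r := 1) below this elementwise tolerance
_CONST_TOL = 1e-12


def apply_mutation(seq: RnaSequence, mut: Mutation) -> RnaSequence:
    """The sequence with *mut* applied; id gains a ``|label`` suffix."""
    mut.validate_against(seq)
    res = seq.residues
    new = res[: mut.position - 1] + mut.variant + res[mut.position :]
    return RnaSequence(id=f"{seq.id}|{mut.label}", residues=new)


def enumerate_mutations(seq: RnaSequence) -> list[Mutation]:
    """All 3n single substitutions, position ascending, variant base A<C<G<U."""
    out = []
    for pos in range(1, len(seq) + 1):
        wild = seq.residues[pos - 1]
        for base in BASES:
            if base != wild:
                out.append(Mutation(position=pos, wild=wild, variant=base))
    return out


def accessibility(bppm: BasePairProbabilityMatrix) -> np.ndarray:
    """Per-nucleotide probability of being paired: column sums of P(i, j)."""
    return bppm.matrix.sum(axis=0)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with an explicit convention for zero-variance inputs.

    If both vectors are constant: r = 1 when they are elementwise equal
    (within 1e-12), else 0.  If exactly one is constant: r = 0.  Both
    degenerate outcomes are logged; they keep every mutation rankable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    x_const = np.ptp(x) < _CONST_TOL
    y_const = np.ptp(y) < _CONST_TOL
    if x_const or y_const:
        if x_const and y_const and np.allclose(x, y, atol=_CONST_TOL):
            logger.debug("both vectors constant and equal; r := 1.0")
            return 1.0
        logger.warning("zero-variance accessibility vector; r := 0.0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r, 1.0)


def structural_correlation(
    seq: RnaSequence,
    mut: Mutation,
    model: EnergyModel | None = None,
    wt_accessibility: np.ndarray | None = None,
    pf=None,
) -> float:
    """Pearson correlation between wild-type and mutant accessibility vectors.

    Pass *wt_accessibility* to reuse a precomputed wild-type vector (the
    mutation scan computes the wild type once for all 3n mutants).  *pf* is
    an optional folding engine ``seq -> BasePairProbabilityMatrix``; the
    default is the internal partition function under *model*.
    """
    model = model or EnergyModel.default()
    if pf is None:
        pf = lambda s: partition_function(s, model)  # noqa: E731
    if wt_accessibility is None:
        wt_accessibility = accessibility(pf(seq))
    mutant = apply_mutation(seq, mut)
    mut_vec = accessibility(pf(mutant))
    return pearson(wt_accessibility, mut_vec)


@dataclass(frozen=True)
class MutationScanResult:
    """Correlation coefficients for every one of the 3n single substitutions."""

    sequence_id: str
    n: int
    mutations: tuple[Mutation, ...]
    correlations: np.ndarray  # aligned with `mutations`

    def __post_init__(self) -> None:
        if len(self.mutations) != 3 * self.n:
            raise ValueError(f"expected {3 * self.n} mutations, got {len(self.mutations)}")
        if len(self.correlations) != len(self.mutations):
            raise ValueError("one correlation per mutation required")
        if np.any(self.correlations > 1 + 1e-12):
            raise ValueError("correlation coefficients cannot exceed 1")

    def correlation_of(self, mut: Mutation) -> float:
        for m, r in zip(self.mutations, self.correlations):
            if m == mut:
                return float(r)
        raise KeyError(f"mutation {mut.label} is not part of this scan")

    def heat_map(self) -> np.ndarray:
        """4 x n matrix (rows A, C, G, U); wild-type cells are NaN sentinels."""
        hm = np.full((4, self.n), np.nan)
        for m, r in zip(self.mutations, self.correlations):
            hm[BASES.index(m.variant), m.position - 1] = r
        return hm


@dataclass(frozen=True)
class SnpScore:
    """Score of one substitution within its sequence's full mutation scan."""

    mutation: Mutation
    correlation: float
    rank: int
    total: int  # 3n

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.total:
            raise ValueError(f"rank {self.rank} outside 1..{self.total}")

    @property
    def p_value(self) -> float:
        return self.rank / self.total


class ScanBudgetError(ValueError):
    """Scan refused: sequence longer than the compute budget allows."""


def mutation_scan(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    max_length: int = 1000,
    force: bool = False,
    pf=None,
) -> MutationScanResult:
    """Score all 3n single substitutions of *seq*.

    The wild-type partition function is computed once and reused across
    mutants.  Sequences above *max_length* are refused unless *force* is
    set (the scan is O(n) partition functions, each O(n^3)).
    """
    model = model or EnergyModel.default()
    if len(seq) > max_length and not force:
        raise ScanBudgetError(
            f"sequence {seq.id!r} has {len(seq)} nt, above the scan budget of "
            f"{max_length}; pass force=True (CLI: --force) to override"
        )
    if pf is None:
        pf = lambda s: partition_function(s, model)  # noqa: E731
    wt = accessibility(pf(seq))
    muts = enumerate_mutations(seq)
    corrs = np.empty(len(muts))
    for idx, mut in enumerate(muts):
        corrs[idx] = structural_correlation(seq, mut, model, wt_accessibility=wt, pf=pf)
    return MutationScanResult(
        sequence_id=seq.id, n=len(seq), mutations=tuple(muts), correlations=corrs
    )


def empirical_p_value(target: Mutation, scan: MutationScanResult) -> SnpScore:
    """Rank-based p-value of *target* within *scan*.

    rank = number of scanned mutations with r <= r(target), the target
    itself included; ties therefore increase the rank (conservative).
    p = rank / 3n, so p is in [1/3n, 1].
    """
    r_target = scan.correlation_of(target)
    rank = int(np.sum(scan.correlations <= r_target))
    return SnpScore(
        mutation=target, correlation=r_target, rank=rank, total=len(scan.mutations)
    )
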