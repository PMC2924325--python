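"""Deterministic generators of test inputs with known structural behaviour.

Real regulatory UTRs come with unknown ground truth; these constructs do
not.  Three generators, all pure functions of their seeds:

* :func:`random_sequence` — i.i.d. sequences at a target GC fraction;
* :func:`design_hairpin` — a GC-stem hairpin whose full stem is the unique
  MFE structure at small sizes;
* :func:`design_switch` — a two-helix construct whose ensemble is dominated
  by helix A, with a designated *toggling* mutation that breaks an A pair
  and hands the ensemble to the mutually exclusive helix B, and a
  designated *neutral* mutation that leaves the ensemble unchanged.  Every
  designed instance is certified against the exhaustive-enumeration oracle
  at construction time, so downstream tests inherit sharp expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import EnergyModel
from .scoring import empirical_p_value, mutation_scan
from .sequence import Mutation, RnaSequence
from .thermo import enumerate_structures

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# two-helix switch layout (1-based): strand1 1-4, loop1 5-7, shared strand
# 8-11, loop2 12-14, strand3 15-18.  Helix A pairs strand1 with the shared
# strand; helix B pairs the shared strand with strand3.
_SWITCH_N = 18
_HELIX_A = ((1, 11), (2, 10), (3, 9), (4, 8))
_HELIX_B = ((8, 18), (9, 17), (10, 16), (11, 15))
_LOOP_POSITIONS = (5, 6, 7, 12, 13, 14)


def random_sequence(n: int, gc: float = 0.5, seed: int = 0) -> RnaSequence:
    """Seeded i.i.d. random RNA with expected GC fraction *gc*.

    G and C are equiprobable at gc/2 each, likewise A and U at (1-gc)/2.
    """
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc fraction must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    residues = "".join(rng.choice(list("ACGU"), size=n, p=probs))
    return RnaSequence(id=f"random_n{n}_gc{gc:g}_s{seed}", residues=residues)


def design_hairpin(stem: int, loop: int = 3) -> RnaSequence:
    """A GC-stem hairpin: G*stem + A*loop + C*stem."""
    if stem < 1 or loop < 3:
        raise ValueError("need stem >= 1 and loop >= 3")
    return RnaSequence(
        id=f"hairpin_s{stem}_l{loop}", residues="G" * stem + "A" * loop + "C" * stem
    )


@dataclass(frozen=True)
class SwitchDesign:
    """A certified two-state construct (see module docstring).

    The oracle-computed diagnostics are stored so tests can assert against
    the exact quantities the design was certified on.
    """

    sequence: RnaSequence
    helix_a: tuple[tuple[int, int], ...]
    helix_b: tuple[tuple[int, int], ...]
    toggling: Mutation
    neutral: Mutation
    p_helix_a_wt: float
    p_helix_a_toggled: float
    toggling_rank: int
    neutral_correlation: float


def _helix_probability(
    seq: RnaSequence, helix: tuple[tuple[int, int], ...], model: EnergyModel
) -> float:
    """Oracle probability that every pair of *helix* is formed simultaneously."""
    structures = enumerate_structures(seq, model)
    rt = model.rt
    weights = np.array([math.exp(-e / rt) for _, e in structures])
    z = weights.sum()
    need = set(helix)
    hit = sum(
        w for (s, _), w in zip(structures, weights) if need.issubset(set(s.pairs))
    )
    return float(hit / z)


def design_switch(
    seed: int = 0,
    model: EnergyModel | None = None,
    max_attempts: int = 100_000,
) -> SwitchDesign:
    """Search for a switch construct satisfying all certification checks.

    Candidate sequences are generated deterministically from *seed* and
    rejected until one passes every oracle check: the wild type forms helix
    A with probability > 0.8; the toggling mutation drops that below 0.4
    and ranks within the lowest 10% of the full mutation scan; the neutral
    mutation scores r > 0.99.  Raises if no candidate is found within
    *max_attempts*.
    """
    model = model or EnergyModel.default()
    rng = np.random.Generator(np.random.PCG64(seed))
    attempts = 0
    while attempts < max_attempts:
        attempts += 1
        shared = "".join(rng.choice(list("GC"), size=4))
        if "G" not in shared:
            continue  # the weakened helix-B pair needs a G.U wobble site
        # strand1 closes helix A against the shared strand; strand3 would
        # close helix B with the same letters, weakened at one wobble site.
        strand1 = "".join(_COMPLEMENT[b] for b in shared[::-1])
        strand3 = list(strand1)
        g_sites = [k for k, b in enumerate(shared) if b == "G"]
        weak = int(rng.choice(g_sites))
        # helix B pair for shared position 8+weak is (8+weak, 18-weak)
        strand3[3 - weak] = "U"
        residues = strand1 + "AAA" + shared + "AAA" + "".join(strand3)
        seq = RnaSequence(id=f"switch_s{seed}", residues=residues)
        p_a = _helix_probability(seq, _HELIX_A, model)
        if p_a <= 0.8:
            continue
        scan = mutation_scan(seq, model)
        design = _pick_mutations(seq, scan, p_a, model)
        if design is not None:
            return design
    raise RuntimeError(
        f"no admissible switch design found in {max_attempts} attempts (seed {seed})"
    )


def _pick_mutations(seq, scan, p_a, model):
    n = len(seq)
    toggling = None
    for pos in (2, 3):
        partner = dict(_HELIX_A)[pos] if pos in dict(_HELIX_A) else None
        wild = seq.residues[pos - 1]
        for variant in "ACGU":
            if variant == wild:
                continue
            if _COMPLEMENT.get(variant) == seq.residues[partner - 1]:
                continue  # still pairs; not a disruption
            mut = Mutation(position=pos, wild=wild, variant=variant)
            mutant = RnaSequence(id="cand", residues=seq.residues[: pos - 1] + variant + seq.residues[pos:])
            p_a_mut = _helix_probability(mutant, _HELIX_A, model)
            if p_a_mut >= 0.4:
                continue
            score = empirical_p_value(mut, scan)
            if score.rank <= 0.1 * 3 * n:
                toggling = (mut, p_a_mut, score.rank)
                break
        if toggling:
            break
    if toggling is None:
        return None
    for pos in _LOOP_POSITIONS:
        wild = seq.residues[pos - 1]
        for variant in "CGU":
            if variant == wild:
                continue
            mut = Mutation(position=pos, wild=wild, variant=variant)
            r = scan.correlation_of(mut)
            if r > 0.99:
                return SwitchDesign(
                    sequence=seq,
                    helix_a=_HELIX_A,
                    helix_b=_HELIX_B,
                    toggling=toggling[0],
                    neutral=mut,
                    p_helix_a_wt=p_a,
                    p_helix_a_toggled=toggling[1],
                    toggling_rank=toggling[2],
                    neutral_correlation=float(r),
                )
    return None
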