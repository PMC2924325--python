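"""Partition function, MFE folding, Boltzmann sampling, and the enumeration oracle.

Three routes into the same ensemble
-----------------------------------
The equilibrium ensemble of a sequence under an :class:`~ribosnitch.model.EnergyModel`
assigns every admissible nested structure ``S`` the probability
``exp(-E(S)/RT) / Z``.  This module exposes:

* :func:`partition_function` — O(n^3) inside-outside dynamic programming
  (McCaskill-style) giving the base-pair probability matrix P(i,j) and Z;
* :func:`mfe_structure` — minimum-free-energy folding (Zuker-style) over the
  identical energy decomposition;
* :func:`sample_structures` — i.i.d. Boltzmann draws by stochastic traceback
  through the inside matrices;
* :func:`enumerate_structures` — exhaustive enumeration for short sequences,
  the independent oracle the dynamic programs are validated against.

All four agree exactly on which structures are admissible and on their
energies, so the oracle checks are sharp (1e-9, not statistical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from ._kernels import INF
from .model import EnergyModel, encode_sequence
from .sequence import RnaSequence
from .structure import SecondaryStructure

_TIE_TOL = 1e-6  # energies are sums of 0.1-granular table entries

#: default length cap for exhaustive enumeration
DEFAULT_ENUMERATION_CAP = 20

#: MFE-derived rescaling uses a small safety margin so suboptimal structures
#: slightly above the MFE still scale well (standard practice for long RNAs)
_SCALE_SAFETY = 1.07


class EnumerationCapError(ValueError):
    """Enumeration refused because the sequence exceeds the length cap."""


@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Symmetric n x n matrix of equilibrium pairing probabilities P(i, j).

    ``z`` is the partition function (>= 1 because the empty structure has
    energy 0); ``log_z`` is exact even when ``z`` itself would overflow.
    Indexing of :meth:`probability` is 1-based like the rest of the API.
    """

    matrix: np.ndarray
    z: float
    log_z: float
    sequence_id: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("base-pair probability matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("base-pair probability matrix must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-9:
            raise ValueError("pairing probabilities must lie in [0, 1]")
        rows = m.sum(axis=1)
        if rows.max(initial=0.0) > 1 + 1e-6:
            raise ValueError("a residue pairs with at most one partner: row sum > 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def probability(self, i: int, j: int) -> float:
        return float(self.matrix[i - 1, j - 1])


@dataclass(frozen=True)
class EnsembleSample:
    """An ordered list of i.i.d. Boltzmann-sampled structures.

    Reproducible: identical (sequence, model, count, seed) gives the
    identical list.  The RNG is numpy's PCG64 seeded with ``seed``.
    """

    structures: tuple[SecondaryStructure, ...]
    seed: int
    sequence_id: str
    n: int

    @property
    def count(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# shared tables
# ---------------------------------------------------------------------------

def _tables(seq: RnaSequence, model: EnergyModel):
    enc = encode_sequence(seq.residues)
    n = len(enc)
    pt = model.pair_type_table()
    ptype = -np.ones((n, n), dtype=np.int64)
    for i in range(n):
        ptype[i, i + 1 :] = pt[enc[i], enc[i + 1 :]]
    hp_e, bu_e, il_e = model.loop_energy_tables(n)
    return enc, ptype, hp_e, bu_e, il_e


def _weights(model: EnergyModel, *energy_arrays):
    rt = model.rt
    out = []
    for e in energy_arrays:
        w = np.where(e > INF / 2, 0.0, np.exp(-np.minimum(e, INF / 2) / rt))
        out.append(w)
    return out


def _mfe_energy_fill(seq: RnaSequence, model: EnergyModel):
    _, ptype, hp_e, bu_e, il_e = _tables(seq, model)
    V, M, M1, W = _kernels.fill_mfe(
        ptype, model.min_hairpin_loop, model.max_interior_loop,
        hp_e, bu_e, il_e, model.stack,
        model.ml_closing, model.ml_branch, model.ml_unpaired,
    )
    return ptype, hp_e, bu_e, il_e, V, M, M1, W


def _inside(seq: RnaSequence, model: EnergyModel):
    """Inside matrices plus the rescaling vector used by sampling/outside."""
    n = len(seq)
    ptype, hp_e, bu_e, il_e, *_rest, W = _mfe_energy_fill(seq, model)
    e_mfe = W[n]
    q1 = math.exp(_SCALE_SAFETY * e_mfe / (model.rt * n)) if e_mfe < 0 else 1.0
    q1pow = q1 ** np.arange(n + 2, dtype=float)
    whp, wbu, wil = _weights(model, hp_e, bu_e, il_e)
    wstack = np.where(model.stack > INF / 2, 0.0, np.exp(-np.minimum(model.stack, INF / 2) / model.rt))
    wml_c = math.exp(-model.ml_closing / model.rt)
    wml_b = math.exp(-model.ml_branch / model.rt)
    wml_u = math.exp(-model.ml_unpaired / model.rt)
    QB, QM, QM1, Q = _kernels.fill_inside(
        ptype, model.min_hairpin_loop, model.max_interior_loop,
        whp, wbu, wil, wstack, wml_c, wml_b, wml_u, q1pow,
    )
    return {
        "ptype": ptype, "q1pow": q1pow, "q1": q1,
        "whp": whp, "wbu": wbu, "wil": wil, "wstack": wstack,
        "wml_c": wml_c, "wml_b": wml_b, "wml_u": wml_u,
        "QB": QB, "QM": QM, "QM1": QM1, "Q": Q,
    }


# ---------------------------------------------------------------------------
# partition function
# ---------------------------------------------------------------------------

def partition_function(seq: RnaSequence, model: EnergyModel | None = None) -> BasePairProbabilityMatrix:
    """Base-pair probability matrix and partition function of *seq*.

    Runs the inside-outside dynamic program in O(n^3) time and O(n^2)
    memory.  Entries (i, j) whose pair is disallowed, or closer than the
    minimum hairpin loop, are exactly zero.
    """
    model = model or EnergyModel.default()
    n = len(seq)
    t = _inside(seq, model)
    if n <= model.min_hairpin_loop:  # no pair can form at all
        return BasePairProbabilityMatrix(
            matrix=np.zeros((n, n)), z=1.0, log_z=0.0, sequence_id=seq.id
        )
    P = _kernels.fill_outside(
        t["ptype"], model.min_hairpin_loop, model.max_interior_loop,
        t["whp"], t["wbu"], t["wil"], t["wstack"],
        t["wml_c"], t["wml_b"], t["wml_u"],
        t["q1pow"], t["QB"], t["QM"], t["Q"],
    )
    z_scaled = t["Q"][0, n - 1]
    log_z = math.log(z_scaled) - n * math.log(t["q1"])
    z = math.exp(log_z) if log_z < 700 else math.inf
    return BasePairProbabilityMatrix(matrix=P, z=z, log_z=log_z, sequence_id=seq.id)


# ---------------------------------------------------------------------------
# MFE folding
# ---------------------------------------------------------------------------

def mfe_structure(seq: RnaSequence, model: EnergyModel | None = None) -> tuple[SecondaryStructure, float]:
    """A minimum-free-energy structure and its energy (kcal/mol).

    Ties between co-optimal structures are broken deterministically: the
    traceback prefers, in fixed order, pairing over leaving residues
    unpaired and the smallest admissible indices, so repeated calls always
    return the same structure.
    """
    model = model or EnergyModel.default()
    n = len(seq)
    ptype, hp_e, bu_e, il_e, V, M, M1, W = _mfe_energy_fill(seq, model)
    h = model.min_hairpin_loop
    maxloop = model.max_interior_loop
    stack_e = model.stack
    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        target = V[i, j]
        if abs(hp_e[j - i - 1] - target) < _TIE_TOL:
            return
        kmax = min(i + maxloop + 1, j - 1)
        for k in range(i + 1, kmax + 1):
            g1 = k - i - 1
            for l in range(max(k + h + 1, j - 1 - (maxloop - g1)), j):
                pt2 = ptype[k, l]
                if pt2 < 0 or V[k, l] > INF / 2:
                    continue
                g2 = j - l - 1
                if g1 == 0 and g2 == 0:
                    e = stack_e[ptype[i, j], pt2]
                elif g1 == 0 or g2 == 0:
                    e = bu_e[g1 + g2]
                else:
                    e = il_e[g1 + g2]
                if e < INF / 2 and abs(e + V[k, l] - target) < _TIE_TOL:
                    pairs.append((k, l))
                    trace_v(k, l)
                    return
        for k in range(i + 2, j):
            if M[i + 1, k - 1] < INF / 2 and M1[k, j - 1] < INF / 2:
                if abs(model.ml_closing + M[i + 1, k - 1] + M1[k, j - 1] - target) < _TIE_TOL:
                    trace_m(i + 1, k - 1)
                    trace_m1(k, j - 1)
                    return
        raise AssertionError(f"MFE traceback failed at pair ({i},{j})")  # pragma: no cover

    def trace_m1(i: int, j: int) -> None:
        target = M1[i, j]
        for l in range(j, i + h, -1):
            if V[i, l] < INF / 2 and abs(V[i, l] + model.ml_branch + model.ml_unpaired * (j - l) - target) < _TIE_TOL:
                pairs.append((i, l))
                trace_v(i, l)
                return
        raise AssertionError(f"M1 traceback failed at ({i},{j})")  # pragma: no cover

    def trace_m(i: int, j: int) -> None:
        target = M[i, j]
        for k in range(i, j + 1):
            if M1[k, j] > INF / 2:
                continue
            if abs(model.ml_unpaired * (k - i) + M1[k, j] - target) < _TIE_TOL:
                trace_m1(k, j)
                return
            if k > i and M[i, k - 1] < INF / 2 and abs(M[i, k - 1] + M1[k, j] - target) < _TIE_TOL:
                trace_m(i, k - 1)
                trace_m1(k, j)
                return
        raise AssertionError(f"M traceback failed at ({i},{j})")  # pragma: no cover

    j = n - 1
    while j >= 0:
        target = W[j + 1]
        chosen = -1
        for k in range(0, j - h):
            if V[k, j] < INF / 2 and abs(W[k] + V[k, j] - target) < _TIE_TOL:
                chosen = k
                break
        if chosen >= 0:
            pairs.append((chosen, j))
            trace_v(chosen, j)
            j = chosen - 1
        else:
            j -= 1
    struct = SecondaryStructure(pairs=tuple((i + 1, j + 1) for i, j in pairs))
    return struct, float(W[n])


# ---------------------------------------------------------------------------
# Boltzmann sampling
# ---------------------------------------------------------------------------

def sample_structures(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    count: int = 1000,
    seed: int = 0,
) -> EnsembleSample:
    """Draw *count* structures i.i.d. from the Boltzmann distribution.

    Stochastic traceback through the inside matrices: every decomposition
    step chooses a branch with probability proportional to its share of the
    local partition function, which yields exact (not approximate) samples.
    """
    model = model or EnergyModel.default()
    if count < 1:
        raise ValueError("count must be >= 1")
    n = len(seq)
    t = _inside(seq, model)
    rng = np.random.Generator(np.random.PCG64(seed))
    h = model.min_hairpin_loop
    maxloop = model.max_interior_loop
    ptype, q1pow = t["ptype"], t["q1pow"]
    whp, wbu, wil, wstack = t["whp"], t["wbu"], t["wil"], t["wstack"]
    wml_c, wml_b, wml_u = t["wml_c"], t["wml_b"], t["wml_u"]
    QB, QM, QM1, Q = t["QB"], t["QM"], t["QM1"], t["Q"]
    q1 = t["q1"]
    uq = wml_u * q1

    def _choose(options: list[tuple[float, tuple]], r: float) -> tuple:
        total = 0.0
        for w, _ in options:
            total += w
        x = r * total
        acc = 0.0
        for w, action in options:
            acc += w
            if x < acc:
                return action
        return options[-1][1]  # float-drift guard

    def draw_one() -> SecondaryStructure:
        pairs: list[tuple[int, int]] = []
        stack: list[tuple[str, int, int]] = [("Q", 0, n - 1)]
        while stack:
            kind, i, j = stack.pop()
            if j <= i and kind != "QB":
                continue
            if kind == "Q":
                opts: list[tuple[float, tuple]] = [(Q[i, j - 1] * q1, ("u",))]
                for k in range(i, j - h):
                    if ptype[k, j] >= 0 and QB[k, j] > 0.0:
                        left = 1.0 if k == i else Q[i, k - 1]
                        opts.append((left * QB[k, j], ("p", k)))
                act = _choose(opts, rng.random())
                if act[0] == "u":
                    stack.append(("Q", i, j - 1))
                else:
                    k = act[1]
                    pairs.append((k, j))
                    stack.append(("QB", k, j))
                    if k > i:
                        stack.append(("Q", i, k - 1))
            elif kind == "QB":
                d = j - i
                opts = [(whp[d - 1] * q1pow[d + 1], ("h",))]
                kmax = min(i + maxloop + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    for l in range(max(k + h + 1, j - 1 - (maxloop - g1)), j):
                        pt2 = ptype[k, l]
                        if pt2 < 0 or QB[k, l] <= 0.0:
                            continue
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            w = wstack[ptype[i, j], pt2]
                        elif g1 == 0 or g2 == 0:
                            w = wbu[g1 + g2]
                        else:
                            w = wil[g1 + g2]
                        if w > 0.0:
                            opts.append((w * QB[k, l] * q1pow[g1 + g2 + 2], ("i", k, l)))
                for k in range(i + 2, j):
                    w = wml_c * q1pow[2] * QM[i + 1, k - 1] * QM1[k, j - 1]
                    if w > 0.0:
                        opts.append((w, ("m", k)))
                act = _choose(opts, rng.random())
                if act[0] == "i":
                    _, k, l = act
                    pairs.append((k, l))
                    stack.append(("QB", k, l))
                elif act[0] == "m":
                    k = act[1]
                    stack.append(("QM", i + 1, k - 1))
                    stack.append(("QM1", k, j - 1))
            elif kind == "QM":
                opts = [(QM1[i, j], ("one", i))]
                upow = uq
                for k in range(i + 1, j + 1):
                    tqm1 = QM1[k, j]
                    if tqm1 > 0.0:
                        opts.append((upow * tqm1, ("one", k)))
                        opts.append((QM[i, k - 1] * tqm1, ("more", k)))
                    upow *= uq
                act = _choose(opts, rng.random())
                k = act[1]
                stack.append(("QM1", k, j))
                if act[0] == "more":
                    stack.append(("QM", i, k - 1))
            elif kind == "QM1":
                opts = []
                for l in range(i + h + 1, j + 1):
                    if QB[i, l] > 0.0:
                        opts.append((QB[i, l] * wml_b * uq ** (j - l), ("b", l)))
                act = _choose(opts, rng.random())
                l = act[1]
                pairs.append((i, l))
                stack.append(("QB", i, l))
        return SecondaryStructure(pairs=tuple((a + 1, b + 1) for a, b in pairs))

    structures = tuple(draw_one() for _ in range(count))
    return EnsembleSample(structures=structures, seed=seed, sequence_id=seq.id, n=n)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def structure_energy(seq: RnaSequence, structure: SecondaryStructure, model: EnergyModel | None = None) -> float:
    """Free energy of one structure by loop decomposition (kcal/mol).

    Returns ``math.inf`` if the structure is inadmissible under the model
    (a disallowed pair, a hairpin loop shorter than the minimum, or a
    bulge/internal loop above the size cap).  Independent of the dynamic
    programs: walks the loop tree explicitly.
    """
    model = model or EnergyModel.default()
    n = len(seq)
    pairs = structure.pairs
    if not pairs:
        return 0.0
    if max(j for _, j in pairs) > n:
        raise ValueError("structure has a pair beyond the sequence length")
    enc = encode_sequence(seq.residues)
    pt_tab = model.pair_type_table()
    hp_e, bu_e, il_e = model.loop_energy_tables(n)
    h = model.min_hairpin_loop

    ptypes = {}
    for i, j in pairs:
        if j - i - 1 < h:
            return math.inf
        pt = pt_tab[enc[i - 1], enc[j - 1]]
        if pt < 0:
            return math.inf
        ptypes[(i, j)] = pt

    # children of each pair in the loop tree (pairs are sorted by (i, j))
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for i, j in pairs:
        while stack and stack[-1][1] < i:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append((i, j))
        children.setdefault((i, j), [])
        stack.append((i, j))

    energy = 0.0
    for key, kids in children.items():
        if key is None:
            continue  # exterior loop is free
        i, j = key
        if len(kids) == 0:
            energy += hp_e[j - i - 1]
        elif len(kids) == 1:
            (k, l) = kids[0]
            g1, g2 = k - i - 1, j - l - 1
            if g1 == 0 and g2 == 0:
                energy += model.stack[ptypes[(i, j)], ptypes[(k, l)]]
            elif g1 == 0 or g2 == 0:
                energy += bu_e[g1 + g2]
            else:
                energy += il_e[g1 + g2]
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += (
                model.ml_closing
                + model.ml_branch * len(kids)
                + model.ml_unpaired * unpaired
            )
    return float(energy) if energy < INF / 2 else math.inf


def enumerate_structures(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[tuple[SecondaryStructure, float]]:
    """Every admissible nested structure of *seq* with its energy.

    Exhaustive recursion over all non-crossing pair sets satisfying the
    model constraints — the validation oracle for the dynamic programs.
    Refuses sequences longer than *cap* residues (combinatorial explosion).
    The empty structure is always included.  Output is sorted by energy,
    ties broken by the pair list, and contains no duplicates.
    """
    model = model or EnergyModel.default()
    n = len(seq)
    if n > cap:
        raise EnumerationCapError(
            f"sequence {seq.id!r} has {n} residues, above the enumeration cap of {cap}"
        )
    enc = encode_sequence(seq.residues)
    pt_tab = model.pair_type_table()
    h = model.min_hairpin_loop
    pairable = [
        [pt_tab[enc[i], enc[j]] >= 0 and j - i - 1 >= h for j in range(n)]
        for i in range(n)
    ]

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i < h + 1:
            return ((),)
        out = list(region(i, j - 1))  # j unpaired
        for k in range(i, j - h):
            if pairable[k][j]:
                for left in region(i, k - 1) if k > i else ((),):
                    for inner in region(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        return tuple(out)

    results = []
    for raw in region(0, n - 1):
        s = SecondaryStructure(pairs=tuple((a + 1, b + 1) for a, b in raw))
        e = structure_energy(seq, s, model)
        if math.isfinite(e):
            results.append((s, e))
    region.cache_clear()
    results.sort(key=lambda se: (se[1], se[0].pairs))
    return results


def oracle_pair_probabilities(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> tuple[np.ndarray, float]:
    """(P, Z) from exhaustive enumeration — the brute-force reference.

    P[i-1, j-1] sums Boltzmann weights of every structure containing the
    pair (i, j), divided by Z.  Only feasible for short sequences.
    """
    model = model or EnergyModel.default()
    n = len(seq)
    structures = enumerate_structures(seq, model, cap=cap)
    rt = model.rt
    weights = np.array([math.exp(-e / rt) for _, e in structures])
    z = float(weights.sum())
    P = np.zeros((n, n))
    for (s, _), w in zip(structures, weights):
        for i, j in s.pairs:
            P[i - 1, j - 1] += w
            P[j - 1, i - 1] += w
    P /= z
    return P, z
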