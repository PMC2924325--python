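"""Characterising *how* an ensemble shifts: PCA of sampled structures.

A low wild-type/mutant correlation says the ensemble changed; it does not
say how.  To visualise the change, structures Boltzmann-sampled from each
sequence are encoded as binary paired/unpaired vectors, a PCA basis is
built from a pooled subsample across all sequences being compared
(wild type and mutants share one basis, so their clouds are directly
comparable), every sampled structure is projected onto the first two
components, and cluster occupancies are read off with seeded k-means.
A riboSNitch shows up as probability mass moving between clusters.

The module also provides the multi-SNP summary (mean absolute change in
per-nucleotide pairing probability across a set of variants) and the
MFE-versus-partition-function comparison of mutation sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .model import EnergyModel
from .scoring import accessibility, apply_mutation, mutation_scan, pearson
from .sequence import Mutation, RnaSequence
from .structure import SecondaryStructure
from .thermo import EnsembleSample, mfe_structure, partition_function


def structure_to_vector(s: SecondaryStructure, n: int) -> np.ndarray:
    """Binary encoding of a structure: bit k = 1 iff residue k is paired."""
    bits = np.zeros(n, dtype=np.int8)
    for i, j in s.pairs:
        if j > n:
            raise ValueError(f"pair ({i},{j}) beyond sequence length {n}")
        bits[i - 1] = 1
        bits[j - 1] = 1
    return bits


def sample_matrix(sample: EnsembleSample) -> np.ndarray:
    """Stack a sample's structures into a (count, n) binary matrix."""
    return np.array([structure_to_vector(s, sample.n) for s in sample.structures])


class DegenerateEnsembleError(ValueError):
    """All pooled structures are identical; no principal axes exist."""


@dataclass(frozen=True)
class PcaBasis:
    """Top-2 principal components of pooled binary structure vectors.

    ``mean`` is the pooled-subsample mean used for centering; ``components``
    is 2 x n with a deterministic sign convention (the largest-magnitude
    loading of each component is positive); ``explained_variance`` is the
    corresponding pair of eigenvalues; ``provenance`` records which
    sequences and subsample sizes seeded the basis.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    provenance: tuple[tuple[str, int], ...]
    seed: int


@dataclass(frozen=True)
class PcaProjection:
    """Coordinates of one sequence's sampled structures in the shared basis."""

    sequence_id: str
    coordinates: np.ndarray  # (count, 2)


@dataclass(frozen=True)
class ClusterSummary:
    """Relative occupancy of structural clusters per sequence."""

    k: int
    occupancy: dict  # sequence_id -> np.ndarray of k fractions
    assignments: dict  # sequence_id -> integer labels per structure
    centroids: np.ndarray  # (k, 2)
    rule: str = "k-means on pooled 2-component projections"

    def __post_init__(self) -> None:
        for sid, frac in self.occupancy.items():
            if abs(frac.sum() - 1.0) > 1e-9:
                raise ValueError(f"occupancies of {sid!r} do not sum to 1")


def build_shared_basis(
    samples: list[EnsembleSample],
    subsample_per_sequence: int = 1000,
    seed: int = 0,
) -> PcaBasis:
    """PCA basis from a pooled random subsample of every sequence's ensemble.

    Default 1000 structures per sequence.  Sequences must share one length.
    Mean-centered covariance eigendecomposition, no variance scaling (the
    inputs are homoscedastic 0/1 bits).  If a sample holds fewer structures
    than the subsample size, all of them are used.
    """
    if not samples:
        raise ValueError("at least one ensemble sample is required")
    lengths = {s.n for s in samples}
    if len(lengths) != 1:
        raise ValueError(f"samples must come from equal-length sequences, got {lengths}")
    rng = np.random.Generator(np.random.PCG64(seed))
    pooled = []
    provenance = []
    for samp in samples:
        mat = sample_matrix(samp)
        take = min(subsample_per_sequence, len(mat))
        idx = rng.choice(len(mat), size=take, replace=False)
        pooled.append(mat[np.sort(idx)])
        provenance.append((samp.sequence_id, take))
    X = np.vstack(pooled).astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / max(len(X) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:2]
    comps = evecs[:, order][:, :2].T.copy()
    if evals[0] < 1e-12:
        raise DegenerateEnsembleError(
            "pooled structures have zero variance; no principal components exist"
        )
    for c in range(2):
        lead = np.argmax(np.abs(comps[c]))
        if comps[c, lead] < 0:
            comps[c] = -comps[c]
    return PcaBasis(
        mean=mean,
        components=comps,
        explained_variance=evals,
        provenance=tuple(provenance),
        seed=seed,
    )


def project(sample: EnsembleSample, basis: PcaBasis) -> PcaProjection:
    """Project a full ensemble sample onto the shared 2-component basis."""
    mat = sample_matrix(sample).astype(float)
    if mat.shape[1] != basis.mean.shape[0]:
        raise ValueError(
            f"sample dimension {mat.shape[1]} does not match basis dimension "
            f"{basis.mean.shape[0]}"
        )
    coords = (mat - basis.mean) @ basis.components.T
    return PcaProjection(sequence_id=sample.sequence_id, coordinates=coords)


def cluster_populations(
    projections: list[PcaProjection],
    k: int = 3,
    seed: int = 0,
) -> ClusterSummary:
    """Per-sequence occupancy of k clusters fit on the pooled projections.

    Seeded k-means with 50 restarts, fit once on the union of all
    sequences' coordinates so cluster identities are shared; each
    sequence's occupancy vector is the fraction of its structures assigned
    to each cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pooled = np.vstack([p.coordinates for p in projections])
    distinct = np.unique(pooled, axis=0)
    if len(distinct) < k:
        raise DegenerateEnsembleError(
            f"only {len(distinct)} distinct projected points for k={k} clusters"
        )
    if k == 1:
        labels_all = np.zeros(len(pooled), dtype=int)
        centroids = pooled.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=50, random_state=seed)
        labels_all = km.fit_predict(pooled)
        centroids = km.cluster_centers_
    occupancy = {}
    assignments = {}
    start = 0
    for p in projections:
        stop = start + len(p.coordinates)
        lab = labels_all[start:stop]
        assignments[p.sequence_id] = lab
        occupancy[p.sequence_id] = np.bincount(lab, minlength=k) / len(lab)
        start = stop
    return ClusterSummary(k=k, occupancy=occupancy, assignments=assignments, centroids=centroids)


def representative_structures(
    samples: list[EnsembleSample],
    projections: list[PcaProjection],
    summary: ClusterSummary,
) -> dict:
    """Per cluster, the sampled structure nearest the centroid in PC space."""
    best: dict[int, tuple[float, SecondaryStructure]] = {}
    for samp, proj in zip(samples, projections):
        lab = summary.assignments[proj.sequence_id]
        for s, xy, c in zip(samp.structures, proj.coordinates, lab):
            d = float(np.sum((xy - summary.centroids[c]) ** 2))
            if c not in best or d < best[c][0]:
                best[c] = (d, s)
    return {c: s for c, (_, s) in sorted(best.items())}


def mean_abs_delta_accessibility(
    seq: RnaSequence,
    mutations: list[Mutation],
    model: EnergyModel | None = None,
) -> np.ndarray:
    """Mean over mutations of |accessibility(mutant) - accessibility(WT)|.

    The per-nucleotide summary used when several independent variants of
    one RNA converge on the same phenotype: positions where the average
    absolute change concentrates are the structurally sensitive ones.
    """
    if not mutations:
        raise ValueError("at least one mutation is required")
    model = model or EnergyModel.default()
    wt = accessibility(partition_function(seq, model))
    deltas = np.zeros(len(seq))
    for mut in mutations:
        mv = accessibility(partition_function(apply_mutation(seq, mut), model))
        deltas += np.abs(mv - wt)
    return deltas / len(mutations)


def mfe_vs_partition_distributions(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    max_length: int = 1000,
    force: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two 3n-length correlation distributions: ensemble-based vs MFE-based.

    For every possible substitution: (a) the Pearson correlation of
    wild-type/mutant accessibility vectors (the ensemble score), and
    (b) the correlation of the binary paired/unpaired vectors of the
    single MFE structures.  The single-structure view saturates (many
    mutations leave the MFE structure bit vector identical), so it is far
    less sensitive than the ensemble view.
    """
    model = model or EnergyModel.default()
    scan = mutation_scan(seq, model, max_length=max_length, force=force)
    n = len(seq)
    wt_bits = structure_to_vector(mfe_structure(seq, model)[0], n).astype(float)
    mfe_corrs = np.empty(3 * n)
    for idx, mut in enumerate(scan.mutations):
        mut_bits = structure_to_vector(
            mfe_structure(apply_mutation(seq, mut), model)[0], n
        ).astype(float)
        mfe_corrs[idx] = pearson(wt_bits, mut_bits)
    return scan.correlations.copy(), mfe_corrs
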