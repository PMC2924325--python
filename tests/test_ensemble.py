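"""Structure vectors, shared PCA basis, projections, clustering, multi-SNP deltas."""

import numpy as np
import pytest

from ribosnitch import (
    RnaSequence,
    SecondaryStructure,
    apply_mutation,
    build_shared_basis,
    cluster_populations,
    mean_abs_delta_accessibility,
    mfe_structure,
    mfe_vs_partition_distributions,
    mutation_scan,
    project,
    sample_structures,
    structure_to_vector,
)
from ribosnitch.ensemble import DegenerateEnsembleError, PcaProjection, sample_matrix
from ribosnitch.scoring import accessibility, pearson
from ribosnitch.thermo import EnsembleSample


def _fake_sample(pair_sets, n, sid="fake", seed=0):
    structures = tuple(SecondaryStructure(pairs=p) for p in pair_sets)
    return EnsembleSample(structures=structures, seed=seed, sequence_id=sid, n=n)


class TestStructureVector:
    def test_empty_structure_is_all_zero(self):
        s = SecondaryStructure(pairs=())
        assert structure_to_vector(s, 5).tolist() == [0, 0, 0, 0, 0]

    def test_stem_marks_both_strands(self):
        s = SecondaryStructure(pairs=((1, 9), (2, 8), (3, 7)))
        assert structure_to_vector(s, 9).tolist() == [1, 1, 1, 0, 0, 0, 1, 1, 1]

    def test_bit_sum_is_twice_the_pair_count(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=50, seed=4)
        for s in samp.structures:
            assert structure_to_vector(s, 9).sum() == 2 * len(s.pairs)

    def test_out_of_range_pair_rejected(self):
        s = SecondaryStructure(pairs=((1, 9),))
        with pytest.raises(ValueError, match="beyond sequence length"):
            structure_to_vector(s, 5)


class TestSharedBasis:
    def test_identical_structures_are_degenerate(self):
        samp = _fake_sample([((1, 9),)] * 40, n=12)
        with pytest.raises(DegenerateEnsembleError):
            build_shared_basis([samp], subsample_per_sequence=40, seed=0)

    def test_component_ordering_and_sign_convention(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=400, seed=5)
        basis = build_shared_basis([samp], subsample_per_sequence=400, seed=0)
        assert basis.explained_variance[0] >= basis.explained_variance[1]
        for comp in basis.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_pc1_aligns_with_a_constructed_separation_axis(self):
        # two clouds differing by a fixed 3-helix block; small independent noise
        n = 24
        helix = ((1, 12), (2, 11), (3, 10))
        noise = ((16, 22),)
        cloud_a = [helix, helix + noise] * 100
        cloud_b = [(), noise] * 100
        sa = _fake_sample(cloud_a, n, sid="a")
        sb = _fake_sample(cloud_b, n, sid="b")
        basis = build_shared_basis([sa, sb], subsample_per_sequence=200, seed=1)
        axis = np.zeros(n)
        for i, j in helix:
            axis[i - 1] = axis[j - 1] = 1.0
        cos = abs(basis.components[0] @ axis) / np.linalg.norm(axis)
        assert cos > 0.99

    def test_unequal_lengths_rejected(self):
        sa = _fake_sample([()], n=10)
        sb = _fake_sample([()], n=12)
        with pytest.raises(ValueError, match="equal-length"):
            build_shared_basis([sa, sb])


class TestProjection:
    def test_identical_structures_project_identically(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=300, seed=6)
        basis = build_shared_basis([samp], subsample_per_sequence=300, seed=0)
        proj = project(samp, basis)
        bits = sample_matrix(samp)
        for i in range(0, 300, 30):
            same = np.all(bits == bits[i], axis=1)
            coords = proj.coordinates[same]
            assert np.allclose(coords, coords[0])

    def test_basis_subsample_projects_to_zero_mean(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=250, seed=7)
        basis = build_shared_basis([samp], subsample_per_sequence=250, seed=0)
        proj = project(samp, basis)  # subsample == full sample here
        assert np.abs(proj.coordinates.mean(axis=0)).max() <= 1e-9

    def test_projection_contracts_pairwise_distances(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=80, seed=8)
        basis = build_shared_basis([samp], subsample_per_sequence=80, seed=0)
        proj = project(samp, basis)
        bits = sample_matrix(samp).astype(float)
        for i in range(0, 80, 13):
            for j in range(i + 1, 80, 17):
                d_full = np.linalg.norm(bits[i] - bits[j])
                d_proj = np.linalg.norm(proj.coordinates[i] - proj.coordinates[j])
                assert d_proj <= d_full + 1e-9

    def test_dimension_mismatch_rejected(self, model):
        samp = sample_structures(RnaSequence("hp", "GGGAAACCC"), model, count=50, seed=9)
        basis = build_shared_basis([samp], subsample_per_sequence=50, seed=0)
        other = _fake_sample([()], n=12)
        with pytest.raises(ValueError, match="does not match basis dimension"):
            project(other, basis)


class TestClusterPopulations:
    def test_single_cluster_holds_everything(self):
        proj = PcaProjection("x", np.random.default_rng(0).random((40, 2)))
        summary = cluster_populations([proj], k=1, seed=0)
        assert summary.occupancy["x"].tolist() == [1.0]

    def test_well_separated_clouds_recover_exact_fractions(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.05, (300, 2))
        b = rng.normal(10, 0.05, (700, 2))
        proj = PcaProjection("x", np.vstack([a, b]))
        summary = cluster_populations([proj], k=2, seed=0)
        assert sorted(summary.occupancy["x"].tolist()) == [0.3, 0.7]

    def test_occupancies_sum_to_one_per_sequence(self, model):
        seqs = [RnaSequence("hp", "GGGAAACCC"), RnaSequence("hp2", "GGCAAACCC")]
        samples = [sample_structures(s, model, count=150, seed=10 + i) for i, s in enumerate(seqs)]
        basis = build_shared_basis(samples, subsample_per_sequence=100, seed=0)
        projections = [project(s, basis) for s in samples]
        summary = cluster_populations(projections, k=3, seed=0)
        for frac in summary.occupancy.values():
            assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_points_with_k2_rejected(self):
        proj = PcaProjection("x", np.zeros((30, 2)))
        with pytest.raises(DegenerateEnsembleError):
            cluster_populations([proj], k=2, seed=0)


class TestMeanAbsDeltaAccessibility:
    def test_single_mutation_equals_absolute_delta(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        from ribosnitch import partition_function, parse_mutation

        mut = parse_mutation("G2A", seq)
        wt = accessibility(partition_function(seq, model))
        mv = accessibility(partition_function(apply_mutation(seq, mut), model))
        delta = mean_abs_delta_accessibility(seq, [mut], model)
        assert np.allclose(delta, np.abs(mv - wt))

    def test_pair_free_mutation_set_gives_zero_vector(self, model):
        seq = RnaSequence("a", "AAAAAAAA")
        from ribosnitch import Mutation

        muts = [Mutation(2, "A", "C"), Mutation(5, "A", "G")]
        assert np.all(mean_abs_delta_accessibility(seq, muts, model) == 0.0)

    def test_empty_mutation_list_rejected(self, model):
        with pytest.raises(ValueError, match="at least one mutation"):
            mean_abs_delta_accessibility(RnaSequence("a", "AAAA"), [], model)

    def test_switch_delta_peaks_inside_the_helices(self, model, switch):
        delta = mean_abs_delta_accessibility(switch.sequence, [switch.toggling], model)
        helix_positions = {p for pair in switch.helix_a + switch.helix_b for p in pair}
        assert (int(np.argmax(delta)) + 1) in helix_positions


class TestMfeVsPartitionDistributions:
    def test_pair_free_sequence_gives_all_ones(self, model):
        part, mfe = mfe_vs_partition_distributions(RnaSequence("a", "AAAA"), model)
        assert np.all(part == 1.0) and np.all(mfe == 1.0)

    def test_mfe_branch_matches_oracle_bit_vectors(self, model):
        from ribosnitch import enumerate_structures, structure_energy

        seq = RnaSequence("hp", "GGGAAACCC")
        _, mfe_corrs = mfe_vs_partition_distributions(seq, model)
        scan = mutation_scan(seq, model)
        wt_bits = structure_to_vector(mfe_structure(seq, model)[0], 9).astype(float)
        for mut, r in zip(scan.mutations, mfe_corrs):
            mutant = apply_mutation(seq, mut)
            emin = min(e for _, e in enumerate_structures(mutant, model))
            s_dp, e_dp = mfe_structure(mutant, model)
            # the folded structure is energy-minimal under the oracle ...
            assert e_dp == pytest.approx(emin, abs=1e-9)
            assert structure_energy(mutant, s_dp, model) == pytest.approx(emin, abs=1e-9)
            # ... and the reported correlation is that of its bit vector
            mut_bits = structure_to_vector(s_dp, 9).astype(float)
            assert r == pytest.approx(pearson(wt_bits, mut_bits), abs=1e-12)
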