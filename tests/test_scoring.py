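"""SNP scoring: accessibility, correlation, mutation scan, empirical p-value."""

import numpy as np
import pytest

from ribosnitch import (
    BasePairProbabilityMatrix,
    Mutation,
    MutationScanResult,
    RnaSequence,
    SequenceError,
    accessibility,
    apply_mutation,
    empirical_p_value,
    enumerate_mutations,
    mutation_scan,
    oracle_pair_probabilities,
    structural_correlation,
)
from ribosnitch.scoring import ScanBudgetError, pearson


class TestApplyMutation:
    def test_substitutes_exactly_one_position(self):
        seq = RnaSequence("x", "GAAAC")
        out = apply_mutation(seq, Mutation(2, "A", "C"))
        assert out.residues == "GCAAC"
        diffs = [i for i, (a, b) in enumerate(zip(seq.residues, out.residues)) if a != b]
        assert diffs == [1]

    def test_wild_base_mismatch_names_expected_and_found(self):
        seq = RnaSequence("x", "GAAAC")
        with pytest.raises(SequenceError, match="expected C at position 2, found A"):
            apply_mutation(seq, Mutation(2, "C", "G"))

    def test_position_out_of_range(self):
        seq = RnaSequence("x", "GAAAC")
        with pytest.raises(SequenceError, match="out of range"):
            apply_mutation(seq, Mutation(9, "A", "C"))

    def test_hbb_like_position_33(self):
        rng = np.random.default_rng(0)
        residues = "".join(rng.choice(list("AGU"), 50))
        residues = residues[:32] + "C" + residues[33:]
        seq = RnaSequence("utr50", residues)
        out = apply_mutation(seq, Mutation(33, "C", "G"))
        assert out.residues[32] == "G"
        assert out.residues[:32] == seq.residues[:32]
        assert out.residues[33:] == seq.residues[33:]


class TestEnumerateMutations:
    def test_single_base_has_three_variants(self):
        muts = enumerate_mutations(RnaSequence("x", "A"))
        assert [m.label for m in muts] == ["A1C", "A1G", "A1U"]

    @pytest.mark.parametrize("n,total", [(50, 150), (533, 1599)])
    def test_three_n_mutations(self, n, total):
        rng = np.random.default_rng(n)
        seq = RnaSequence("x", "".join(rng.choice(list("ACGU"), n)))
        muts = enumerate_mutations(seq)
        assert len(muts) == total
        assert len(set(m.label for m in muts)) == total
        # deterministic order: position ascending, variant A<C<G<U
        keys = [(m.position, m.variant) for m in muts]
        assert keys == sorted(keys)


class TestAccessibility:
    def test_zero_matrix_gives_zero_vector(self):
        b = BasePairProbabilityMatrix(matrix=np.zeros((6, 6)), z=1.0, log_z=0.0)
        assert np.all(accessibility(b) == 0.0)

    def test_single_entry_marks_both_partners(self):
        m = np.zeros((8, 8))
        m[1, 6] = m[6, 1] = 0.8
        b = BasePairProbabilityMatrix(matrix=m, z=2.0, log_z=np.log(2.0))
        expect = np.array([0, 0.8, 0, 0, 0, 0, 0.8, 0])
        assert np.allclose(accessibility(b), expect)

    def test_matches_oracle_paired_probabilities(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        P, _ = oracle_pair_probabilities(seq, model)
        from ribosnitch import partition_function

        acc = accessibility(partition_function(seq, model))
        assert np.allclose(acc, P.sum(axis=0), atol=1e-9)


class TestPearsonConvention:
    def test_equal_constant_vectors_score_one(self):
        assert pearson(np.zeros(5), np.zeros(5)) == 1.0

    def test_unequal_constant_vectors_score_zero(self):
        assert pearson(np.zeros(5), np.full(5, 0.3)) == 0.0

    def test_one_constant_vector_scores_zero(self):
        assert pearson(np.zeros(5), np.arange(5.0)) == 0.0

    def test_matches_numpy_on_generic_input(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(20), rng.random(20)
        assert pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])


class TestStructuralCorrelation:
    def test_pair_free_sequence_is_perfectly_correlated(self, model):
        seq = RnaSequence("a", "AAAAAAAAAA")
        r = structural_correlation(seq, Mutation(5, "A", "C"), model)
        assert r == 1.0

    def test_scan_values_match_standalone_recomputation(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        scan = mutation_scan(seq, model)
        for mut in scan.mutations[::5]:
            assert structural_correlation(seq, mut, model) == scan.correlation_of(mut)


class TestMutationScan:
    def test_pair_free_sequence_scores_all_ones(self, model):
        scan = mutation_scan(RnaSequence("a", "AAAA"), model)
        assert len(scan.mutations) == 12
        # mutations that keep the sequence pair-free score exactly 1
        for mut, r in zip(scan.mutations, scan.correlations):
            mutated = apply_mutation(RnaSequence("a", "AAAA"), mut)
            if "U" not in mutated.residues:  # A/C/G only: nothing can pair
                assert r == 1.0

    def test_correlations_never_exceed_one(self, model):
        scan = mutation_scan(RnaSequence("hp", "GGGAAACCC"), model)
        assert scan.correlations.max() <= 1.0

    def test_each_score_matches_oracle_accessibility_correlation(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        P_wt, _ = oracle_pair_probabilities(seq, model)
        wt = P_wt.sum(axis=0)
        scan = mutation_scan(seq, model)
        assert len(scan.mutations) == 27
        for mut, r in zip(scan.mutations, scan.correlations):
            P_mut, _ = oracle_pair_probabilities(apply_mutation(seq, mut), model)
            assert r == pytest.approx(pearson(wt, P_mut.sum(axis=0)), abs=1e-9)

    def test_heat_map_flags_wild_type_cells(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        hm = mutation_scan(seq, model).heat_map()
        from ribosnitch.model import BASES

        for pos, base in enumerate(seq.residues):
            col = hm[:, pos]
            assert np.isnan(col[BASES.index(base)])
            assert np.sum(np.isnan(col)) == 1

    def test_budget_refusal_and_override(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        with pytest.raises(ScanBudgetError, match="budget"):
            mutation_scan(seq, model, max_length=5)
        scan = mutation_scan(seq, model, max_length=5, force=True)
        assert len(scan.mutations) == 27


def _synthetic_scan(n):
    """A scan with strictly increasing correlations: mutation k has rank k+1."""
    rng = np.random.default_rng(1)
    seq = RnaSequence("syn", "".join(rng.choice(list("ACGU"), n)))
    muts = tuple(enumerate_mutations(seq))
    corrs = np.linspace(0.2, 0.999, 3 * n)  # strictly increasing: tie-free
    return seq, MutationScanResult(
        sequence_id=seq.id, n=n, mutations=muts, correlations=corrs
    )


class TestEmpiricalPValue:
    def test_rank_six_of_150_gives_p_004(self):
        _, scan = _synthetic_scan(50)
        score = empirical_p_value(scan.mutations[5], scan)
        assert score.rank == 6 and score.total == 150
        assert score.p_value == pytest.approx(0.04)

    def test_rank_21_of_1599_gives_p_0013(self):
        _, scan = _synthetic_scan(533)
        score = empirical_p_value(scan.mutations[20], scan)
        assert score.rank == 21 and score.total == 1599
        assert round(score.p_value, 3) == 0.013

    def test_strict_minimum_has_smallest_possible_p(self):
        _, scan = _synthetic_scan(10)
        score = empirical_p_value(scan.mutations[0], scan)
        assert score.p_value == pytest.approx(1 / 30)

    def test_ties_are_counted_conservatively(self):
        n = 4
        rng = np.random.default_rng(2)
        seq = RnaSequence("t", "".join(rng.choice(list("ACGU"), n)))
        muts = tuple(enumerate_mutations(seq))
        corrs = np.array([0.5, 0.5, 0.5] + [0.9] * 9)
        scan = MutationScanResult(sequence_id="t", n=n, mutations=muts, correlations=corrs)
        for m in muts[:3]:  # all tied at the bottom share the largest rank
            assert empirical_p_value(m, scan).rank == 3

    def test_rank_is_monotone_in_correlation(self, model):
        seq = RnaSequence("hp", "GGGAAACCC")
        scan = mutation_scan(seq, model)
        scores = [empirical_p_value(m, scan) for m in scan.mutations]
        for a in scores:
            for b in scores:
                if a.correlation < b.correlation:
                    assert a.p_value <= b.p_value

    def test_unknown_target_raises(self, model):
        scan = mutation_scan(RnaSequence("a", "AAAA"), model)
        with pytest.raises(KeyError):
            empirical_p_value(Mutation(1, "C", "G"), scan)
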