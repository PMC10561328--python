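import numpy as np
import pytest

from biopetri import (
    Marking,
    PetriNetStructure,
    apply_firing_count,
    brute_force_invariants,
    coverage,
    fire_sequence,
    incidence_matrix,
    input_matrix,
    minimal_s_invariants,
    minimal_t_invariants,
    output_matrix,
    verify_invariant,
)
from biopetri.errors import DimensionError, EnumerationSizeError
from biopetri.structure import Invariant, write_matrix_tsv

from conftest import (
    DANA_A_DIGITS,
    DANA_A_MINUS_DIGITS,
    DANA_A_PLUS_DIGITS,
    DANA_Y1,
    DANA_Y2,
    parse_digit_matrix,
)


class TestMatrices:
    def test_dana_input_matrix_matches_published_digits(self, dana_net):
        expected = parse_digit_matrix(DANA_A_MINUS_DIGITS, 6, 8)
        assert input_matrix(dana_net).tolist() == expected

    def test_dana_output_matrix_matches_published_digits(self, dana_net):
        expected = parse_digit_matrix(DANA_A_PLUS_DIGITS, 6, 8)
        assert output_matrix(dana_net).tolist() == expected

    def test_dana_incidence_matches_published_digits(self, dana_net):
        expected = parse_digit_matrix(DANA_A_DIGITS, 6, 8)
        assert incidence_matrix(dana_net).a.tolist() == expected

    def test_no_arc_net_all_zero(self):
        net = PetriNetStructure(["p1", "p2"], ["t1"])
        assert not input_matrix(net).any()
        assert not output_matrix(net).any()

    def test_single_input_arc(self):
        net = PetriNetStructure(["s1"], ["t1"], pre={("t1", "s1"): 1})
        assert input_matrix(net).tolist() == [[1]]
        assert output_matrix(net).tolist() == [[0]]

    def test_single_output_arc(self):
        net = PetriNetStructure(["s1"], ["t1"], post={("t1", "s1"): 1})
        assert output_matrix(net).tolist() == [[1]]

    def test_incidence_identity(self, dana_net, cycle_net, self_loop_net):
        for net in (dana_net, cycle_net, self_loop_net):
            tri = incidence_matrix(net)
            assert np.array_equal(tri.a, tri.a_plus - tri.a_minus)

    def test_self_loop_cancels_in_a_only(self, self_loop_net):
        tri = incidence_matrix(self_loop_net)
        assert not tri.a.any()
        assert tri.a_minus.any() and tri.a_plus.any()

    def test_cycle_incidence(self, cycle_net):
        assert incidence_matrix(cycle_net).a.tolist() == [[-1, 1], [1, -1]]

    def test_tsv_export(self, dana_net, tmp_path):
        path = tmp_path / "a.tsv"
        write_matrix_tsv(dana_net, incidence_matrix(dana_net).a, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["id", *dana_net.places]
        assert lines[1].split("\t")[0] == "T0"
        assert len(lines) == 7


class TestApplyFiringCount:
    def test_matches_fire_sequence(self, dana_net, dana_m0):
        seq = ["T0", "T1", "T2", "T4", "T5"]
        counts = [seq.count(t) for t in dana_net.transitions]
        result = apply_firing_count(dana_net, dana_m0, counts)
        assert result == (0, 0, 0, 0, 0, 2, 0, 0)
        assert result == fire_sequence(dana_net, dana_m0, seq).final.counts

    def test_zero_vector_is_identity(self, dana_net, dana_m0):
        assert apply_firing_count(dana_net, dana_m0, [0] * 6) == dana_m0.counts

    def test_cycle(self, cycle_net):
        assert apply_firing_count(cycle_net, Marking([1, 0]), [1, 0]) == (0, 1)

    def test_negative_entries_allowed_in_result(self, dana_net):
        # unrealizable firing counts still evaluate the state equation
        zero = Marking([0] * 8)
        result = apply_firing_count(dana_net, zero, [1, 0, 0, 0, 0, 0])
        assert min(result) < 0


class TestSInvariants:
    def test_dana_reproduces_published_pair(self, dana_net):
        vectors = [inv.vector for inv in minimal_s_invariants(dana_net)]
        assert vectors == [DANA_Y2, DANA_Y1]  # lexicographic canonical order

    def test_all_returned_invariants_verify(self, dana_net):
        for inv in minimal_s_invariants(dana_net):
            assert verify_invariant(dana_net, inv)
            assert inv.normalized

    def test_cycle_conserves_tokens(self, cycle_net):
        assert [i.vector for i in minimal_s_invariants(cycle_net)] == [(1, 1)]

    def test_pure_sink_has_none(self):
        net = PetriNetStructure(["s1"], ["t1"], pre={("t1", "s1"): 1})
        assert minimal_s_invariants(net) == []

    def test_no_arc_net_yields_unit_vectors(self):
        net = PetriNetStructure(["a", "b"], ["t"])
        assert [i.vector for i in minimal_s_invariants(net)] == [(0, 1), (1, 0)]


class TestTInvariants:
    def test_dana_has_none(self, dana_net):
        assert minimal_t_invariants(dana_net) == []

    def test_cycle(self, cycle_net):
        assert [i.vector for i in minimal_t_invariants(cycle_net)] == [(1, 1)]

    def test_single_source_transition(self):
        net = PetriNetStructure(["p"], ["t"], post={("t", "p"): 1})
        assert minimal_t_invariants(net) == []


class TestVerifyInvariant:
    def test_published_vector_passes(self, dana_net):
        inv = Invariant.from_vector(dana_net, "S", DANA_Y1)
        assert verify_invariant(dana_net, inv)

    def test_non_invariant_fails(self, dana_net):
        inv = Invariant.from_vector(dana_net, "S", (1, 0, 0, 0, 0, 0, 0, 0))
        assert not verify_invariant(dana_net, inv)

    def test_scaling_preserves_validity(self, dana_net):
        doubled = Invariant.from_vector(dana_net, "S", tuple(2 * v for v in DANA_Y1))
        assert verify_invariant(dana_net, doubled)
        assert not doubled.normalized

    def test_length_mismatch(self, dana_net):
        inv = Invariant.from_vector(dana_net, "T", (1, 1, 1, 1, 1, 1))
        bad = Invariant(kind="S", vector=inv.vector, support=inv.support,
                        normalized=inv.normalized)
        with pytest.raises(DimensionError):
            verify_invariant(dana_net, bad)

    def test_support_matches_positive_entries(self, dana_net):
        inv = Invariant.from_vector(dana_net, "S", DANA_Y2)
        assert inv.support == {"P1", "P2", "P4", "P5", "P7"}


class TestCoverage:
    def test_dana_place_coverage(self, dana_net):
        covered, uncovered = coverage(dana_net, "S")
        assert not covered
        assert uncovered == {"P6"}

    def test_dana_transition_coverage(self, dana_net):
        covered, uncovered = coverage(dana_net, "T")
        assert not covered
        assert uncovered == set(dana_net.transitions)

    def test_cycle_fully_covered(self, cycle_net):
        assert coverage(cycle_net, "S") == (True, set())
        assert coverage(cycle_net, "T") == (True, set())


class TestBruteForce:
    def test_dana_s_agrees_with_elimination(self, dana_net):
        assert brute_force_invariants(dana_net, "S", 2) == minimal_s_invariants(
            dana_net
        )

    def test_dana_t_empty(self, dana_net):
        assert brute_force_invariants(dana_net, "T", 3) == []

    def test_cycle(self, cycle_net):
        assert [i.vector for i in brute_force_invariants(cycle_net, "S", 1)] == [
            (1, 1)
        ]

    def test_guard(self):
        net = PetriNetStructure(
            [f"p{i}" for i in range(20)], ["t"], pre={("t", "p0"): 1}
        )
        with pytest.raises(EnumerationSizeError):
            brute_force_invariants(net, "S", 3)
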