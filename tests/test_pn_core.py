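import pytest

from biopetri import (
    Marking,
    PetriNetStructure,
    enabled_set,
    fire,
    fire_sequence,
    is_dead,
    is_enabled,
    random_run,
)
from biopetri.errors import (
    DimensionError,
    NetDefinitionError,
    NotEnabledError,
    UnknownIdentifierError,
)


class TestPetriNetStructure:
    def test_disjoint_identifier_sets_required(self):
        with pytest.raises(NetDefinitionError):
            PetriNetStructure(places=["x"], transitions=["x"])

    def test_empty_net_rejected(self):
        with pytest.raises(NetDefinitionError):
            PetriNetStructure(places=[], transitions=[])

    def test_only_places_is_legal(self):
        net = PetriNetStructure(places=["p"], transitions=[])
        assert net.n_places == 1 and net.n_transitions == 0

    def test_arc_must_reference_declared_elements(self):
        with pytest.raises(UnknownIdentifierError):
            PetriNetStructure(["p"], ["t"], pre={("t", "q"): 1})
        with pytest.raises(UnknownIdentifierError):
            PetriNetStructure(["p"], ["t"], post={("u", "p"): 1})

    def test_weights_must_be_positive(self):
        with pytest.raises(NetDefinitionError):
            PetriNetStructure(["p"], ["t"], pre={("t", "p"): 0})

    def test_preset_postset(self, dana_net):
        assert dana_net.preset("T0") == ("P2", "P6")
        assert dana_net.postset("T0") == ("P0", "P1")

    def test_arcs_count(self, dana_net):
        assert len(dana_net.arcs()) == 18


class TestMarking:
    def test_negative_rejected(self):
        with pytest.raises(NetDefinitionError):
            Marking([1, -1])

    def test_length_checked_against_net(self, dana_net):
        with pytest.raises(DimensionError):
            enabled_set(dana_net, Marking([0, 0]))


class TestIsEnabled:
    def test_t0_enabled_at_initial(self, dana_net, dana_m0):
        assert is_enabled(dana_net, dana_m0, "T0")

    def test_t2_disabled_at_initial(self, dana_net, dana_m0):
        assert not is_enabled(dana_net, dana_m0, "T2")

    def test_zero_marking_enables_nothing_with_pre_arcs(self, dana_net):
        zero = Marking([0] * 8)
        assert not any(is_enabled(dana_net, zero, t) for t in dana_net.transitions)

    def test_unknown_transition(self, dana_net, dana_m0):
        with pytest.raises(UnknownIdentifierError):
            is_enabled(dana_net, dana_m0, "T9")


class TestEnabledSet:
    def test_initial_marking(self, dana_net, dana_m0):
        assert enabled_set(dana_net, dana_m0) == ["T0", "T5"]

    def test_dead_marking(self, dana_net):
        assert enabled_set(dana_net, Marking([0, 0, 0, 0, 0, 1, 1, 1])) == []

    def test_source_transition_always_enabled(self):
        net = PetriNetStructure(["p"], ["src"], post={("src", "p"): 1})
        assert enabled_set(net, Marking([0])) == ["src"]
        assert enabled_set(net, Marking([5])) == ["src"]


class TestFire:
    def test_fire_t0(self, dana_net, dana_m0):
        assert fire(dana_net, dana_m0, "T0") == Marking((1, 1, 0, 0, 0, 0, 0, 1))

    def test_fire_t5(self, dana_net, dana_m0):
        assert fire(dana_net, dana_m0, "T5") == Marking((0, 0, 0, 0, 0, 1, 1, 1))

    def test_self_loop_leaves_marking_unchanged(self, self_loop_net):
        m = Marking([1])
        assert fire(self_loop_net, m, "t") == m

    def test_disabled_fire_names_deficient_places(self, dana_net, dana_m0):
        with pytest.raises(NotEnabledError) as exc:
            fire(dana_net, dana_m0, "T2")
        assert exc.value.deficient_places == ("P1",)

    def test_untouched_places_unchanged_exhaustive(self, dana_net, dana_m0):
        # every place outside pre/post of the fired transition keeps its count
        from biopetri import reachability_graph

        graph = reachability_graph(dana_net, dana_m0)
        for src, t, dst in graph.edges:
            touched = set(dana_net.preset(t)) | set(dana_net.postset(t))
            for j, p in enumerate(dana_net.places):
                if p not in touched:
                    assert src[j] == dst[j]


class TestFireSequence:
    def test_full_run_to_dead_marking(self, dana_net, dana_m0):
        trace = fire_sequence(dana_net, dana_m0, ["T0", "T1", "T2", "T4", "T5"])
        assert trace.final == Marking((0, 0, 0, 0, 0, 2, 0, 0))
        assert trace.terminated_dead

    def test_empty_sequence(self, dana_net, dana_m0):
        trace = fire_sequence(dana_net, dana_m0, [])
        assert trace.final == dana_m0
        assert len(trace) == 0

    def test_infeasible_step_reports_index(self, dana_net, dana_m0):
        with pytest.raises(NotEnabledError) as exc:
            fire_sequence(dana_net, dana_m0, ["T2"])
        assert exc.value.step_index == 0

    def test_infeasible_later_step(self, dana_net, dana_m0):
        with pytest.raises(NotEnabledError) as exc:
            fire_sequence(dana_net, dana_m0, ["T0", "T0"])
        assert exc.value.step_index == 1

    def test_steps_chain_by_fire(self, dana_net, dana_m0):
        trace = fire_sequence(dana_net, dana_m0, ["T0", "T3", "T5"])
        m = dana_m0
        for t, m_next in trace.steps:
            assert fire(dana_net, m, t) == m_next
            m = m_next


class TestRandomRun:
    def test_zero_steps(self, dana_net, dana_m0):
        trace = random_run(dana_net, dana_m0, max_steps=0, seed=7)
        assert len(trace) == 0 and trace.initial == dana_m0

    def test_every_step_is_a_legal_firing(self, dana_net, dana_m0):
        trace = random_run(dana_net, dana_m0, max_steps=10, seed=42)
        assert len(trace) <= 5  # longest possible DANA firing sequence
        m = dana_m0
        for t, m_next in trace.steps:
            assert fire(dana_net, m, t) == m_next
            m = m_next
        assert trace.terminated_dead

    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_equal_seeds_equal_traces(self, dana_net, dana_m0, seed):
        a = random_run(dana_net, dana_m0, max_steps=10, seed=seed)
        b = random_run(dana_net, dana_m0, max_steps=10, seed=seed)
        assert a == b
        assert a.seed == seed

    def test_all_seeds_terminate_dead(self, dana_net, dana_m0):
        # DANA has no infinite runs; a generous cap always reaches a dead state
        for seed in range(25):
            trace = random_run(dana_net, dana_m0, max_steps=50, seed=seed)
            assert trace.terminated_dead


class TestIsDead:
    def test_dead_marking(self, dana_net):
        assert is_dead(dana_net, Marking([0, 0, 0, 0, 0, 2, 0, 0]))

    def test_initial_not_dead(self, dana_net, dana_m0):
        assert not is_dead(dana_net, dana_m0)

    def test_net_without_transitions(self):
        net = PetriNetStructure(["p"], [])
        assert is_dead(net, Marking([3]))
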