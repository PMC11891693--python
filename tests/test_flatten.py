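"""Flattening to the nondeterministic automaton and the equivalence oracle."""

import pytest

from guidechart import (
    AlphabetMismatchError,
    FlatAutomaton,
    StateSpaceOverflowError,
    build_statechart,
    flatten,
    language_equivalence,
    refinement_flat_chart,
    refinement_models,
)
from oracle import automaton_language, interpreter_language


def test_flatten_single_state_chart_has_one_state_no_transitions():
    chart = build_statechart(
        name="one",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B"], default_child="A"),
            dict(id="A"), dict(id="B"),
        ],
        events=[dict(id="x")],
        initial_state="A",
    )
    auto = flatten(chart)
    assert len(auto.states) == 1
    assert auto.transition_map == {}


@pytest.mark.parametrize("initial_x", [False, True])
@pytest.mark.parametrize("member", ["grouped", "orthogonal"])
def test_hierarchical_refinements_equivalent_to_flat_reference(initial_x, member):
    """The central refinement claim: grouping states into XOR superstates
    or orthogonal regions preserves the event language and marked
    reachability at either valuation of the side condition."""
    toys = refinement_models(initial_x=initial_x)
    chart = getattr(toys, member)
    ok, counterexample = language_equivalence(flatten(chart), toys.flat, horizon=8)
    assert ok, counterexample


def test_flat_chart_flattening_matches_reference_automaton():
    """Flattening the flat chart itself also reproduces the manual
    encoding (conditioned transition resolved by the baked-in valuation)."""
    for x in (False, True):
        toys = refinement_models(initial_x=x)
        chart = refinement_flat_chart(initial_x=x)
        ok, ce = language_equivalence(flatten(chart), toys.flat, horizon=8)
        assert ok, ce


def test_equivalence_reflexive(gestation_auto):
    assert language_equivalence(gestation_auto, gestation_auto, horizon=8) == (True, None)


def test_missing_return_transition_yields_counterexample_ending_in_d():
    """Removing the return transition from C distinguishes the automata
    with a shortest witness ending in the return event."""
    full = refinement_models(initial_x=False).flat
    pruned_map = {k: v for k, v in full.transition_map.items() if k != ("d", "C")}
    pruned = FlatAutomaton(
        events=full.events, states=dict(full.states), transition_map=pruned_map,
        initial=full.initial, marked=full.marked, name="pruned",
    )
    ok, ce = language_equivalence(full, pruned, horizon=8)
    assert not ok
    assert ce is not None and ce[-1] == "d"
    # a shortest distinguishing sequence must first reach C
    assert ce == ["g", "f", "d"]


def test_alphabet_mismatch_raises(gestation_auto):
    other = refinement_models().flat
    with pytest.raises(AlphabetMismatchError):
        language_equivalence(gestation_auto, other, horizon=4)


def test_state_space_cap_overflow():
    chart = refinement_models(initial_x=True).orthogonal
    with pytest.raises(StateSpaceOverflowError):
        flatten(chart, cap=2)


def test_flat_state_annotations_are_unique(ina):
    auto = flatten(ina)
    annotations = [s.annotation for s in auto.states.values()]
    assert len(annotations) == len(set(annotations))


def test_flatten_marks_states_whose_configuration_activates_a_marked_node(ina):
    auto = flatten(ina)
    for fid in auto.marked:
        active = auto.states[fid].annotation[0]
        assert any(ina.states[s].marked for s in active)
    for fid in set(auto.states) - set(auto.marked):
        active = auto.states[fid].annotation[0]
        assert not any(ina.states[s].marked for s in active)


def test_flat_chart_conversion_preserves_ids_and_marking(gestation, gestation_auto):
    assert set(gestation_auto.states) == {f"q{i}" for i in range(7)}
    assert gestation_auto.initial == "q0"
    assert gestation_auto.marked == {"q5", "q6"}
    assert gestation_auto.successors("q1", "e") == {"q3"}


@pytest.mark.parametrize("seed", range(12))
def test_flatten_agrees_with_interpreter_on_random_charts(seed):
    """Seed-pinned sample of the oracle property: the flattened
    automaton and a brute-force BFS over the interpreter accept exactly
    the same event sequences (with the same marked reachability) up to
    depth 6.  The full 100-seed corpus runs in the acceptance suite."""
    from guidechart import ChartGenParams, generate_chart

    chart = generate_chart(ChartGenParams(seed=seed, max_basic_states=10))
    auto = flatten(chart)
    assert interpreter_language(chart, 6) == automaton_language(auto, 6)
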