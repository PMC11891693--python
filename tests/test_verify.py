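"""Reachability, nondeterminism, monotonicity and coverage checks."""

import pytest

from guidechart import (
    Trace,
    build_statechart,
    check_monotone_condition,
    event_coverage,
    nondeterminism_report,
    reachability,
    refinement_flat_chart,
    run_trace,
)


def test_gestation_all_states_reachable_with_terminal_sinks(gestation):
    report = reachability(gestation)
    assert report.reachable == {f"q{i}" for i in range(7)}
    assert report.unreachable == frozenset()
    assert report.sink_states == {"q5", "q6"}


def test_orphan_state_reported_unreachable():
    chart = build_statechart(
        name="orphan",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B", "Z"], default_child="A"),
            dict(id="A"), dict(id="B"), dict(id="Z"),
        ],
        events=[dict(id="x")],
        transitions=[dict(id="t1", source="A", target="B", event="x")],
        initial_state="A",
    )
    report = reachability(chart)
    assert report.unreachable == {"Z"}


def test_ina_all_clamping_states_reachable(ina):
    report = reachability(ina)
    assert {"12", "13", "14", "15"} <= set(report.reachable)
    assert report.unreachable == frozenset()


def test_ina_marked_witnesses_replay_to_the_marked_state(ina):
    report = reachability(ina)
    assert report.marked_unreachable == frozenset()
    assert set(report.marked_reachable) == {"12", "13", "14", "15", "18", "19"}
    for marked_state, events in report.marked_reachable.items():
        path = run_trace(ina, Trace.from_events(events))
        assert marked_state in path[-1].configuration


def test_witnesses_are_shortest_with_lexicographic_tiebreak(gestation):
    report = reachability(gestation)
    # q5 via h (q0->q4) then f (q4->q5): length 2; the a/e/... routes are longer
    assert report.marked_reachable["q5"] == ["h", "f"]
    assert report.marked_reachable["q6"] == ["a", "e", "i"]


def test_reachability_is_deterministic(ina):
    r1, r2 = reachability(ina), reachability(ina)
    assert r1.marked_reachable == r2.marked_reachable
    assert r1.sink_states == r2.sink_states


def test_flat_conflict_detected_at_source_state():
    chart = refinement_flat_chart(initial_x=True)
    entries = nondeterminism_report(chart)
    assert len(entries) == 1
    entry = entries[0]
    assert entry.event == "g" and "{A}" in entry.state
    assert entry.transitions == ("t1", "t2")


def test_ina_has_no_reachable_nondeterminism(ina):
    assert nondeterminism_report(ina) == []


def test_deterministic_toy_has_no_nondeterminism(gestation):
    assert nondeterminism_report(gestation) == []


def test_nnc_is_strictly_monotone_in_ina(ina):
    report = check_monotone_condition(ina, "NNC", "true->false")
    assert report.monotone
    assert report.violations == [] and report.dynamic_violations == []


def test_action_reestablishing_condition_is_flagged():
    chart = build_statechart(
        name="relapse",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B"], default_child="A"),
            dict(id="A"), dict(id="B"),
        ],
        events=[dict(id="x"), dict(id="y")],
        conditions=[dict(id="NNC", initial_value=True)],
        transitions=[
            dict(id="t1", source="A", target="B", event="x",
                 actions=[dict(condition="NNC", value=False)]),
            dict(id="t2", source="B", target="A", event="y",
                 actions=[dict(condition="NNC", value=True)]),
        ],
        initial_state="A",
    )
    report = check_monotone_condition(chart, "NNC", "true->false")
    assert not report.monotone
    assert report.violations == ["t2"]
    assert report.dynamic_violations  # the violation is also reachable


def test_untouched_condition_is_vacuously_monotone():
    chart = build_statechart(
        name="vacuous",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B"], default_child="A"),
            dict(id="A"), dict(id="B"),
        ],
        events=[dict(id="x")],
        conditions=[dict(id="NNC", initial_value=True)],
        transitions=[dict(id="t1", source="A", target="B", event="x")],
        initial_state="A",
    )
    assert check_monotone_condition(chart, "NNC", "true->false").monotone


def test_unknown_condition_raises(ina):
    from guidechart import UnknownReferenceError

    with pytest.raises(UnknownReferenceError):
        check_monotone_condition(ina, "nope", "true->false")


def test_terminal_state_has_every_event_uncovered(gestation):
    report = event_coverage(gestation)
    assert report.gaps["q5"] == frozenset(gestation.events)
    assert report.gaps["q6"] == frozenset(gestation.events)
    assert report.everywhere_ignored == frozenset()


def test_total_transition_function_has_no_gaps():
    chart = build_statechart(
        name="total",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B"], default_child="A"),
            dict(id="A"), dict(id="B"),
        ],
        events=[dict(id="x")],
        transitions=[
            dict(id="t1", source="A", target="B", event="x"),
            dict(id="t2", source="B", target="A", event="x"),
        ],
        initial_state="A",
    )
    report = event_coverage(chart)
    assert all(not gaps for gaps in report.gaps.values())


def test_ina_event_coverage_is_generated(ina):
    report = event_coverage(ina)
    assert report.everywhere_ignored == frozenset()
    # the prenatal state only reacts to the two mode-of-birth indicators
    assert report.gaps["0"] == frozenset(ina.events) - {"e1", "e2"}
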