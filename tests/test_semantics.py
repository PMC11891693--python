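"""Interpreter semantics: entry rules, guarded steps, concurrency,
marked-state detection."""

import pytest

from guidechart import (
    NondeterminismError,
    Trace,
    build_statechart,
    enabled_transitions,
    initial_configuration,
    is_marked,
    refinement_flat_chart,
    run_trace,
    step,
    step_all,
)
from guidechart.semantics import check_configuration


def basic_set(chart, config):
    return set(config.basic_active(chart))


# -- initial configurations --------------------------------------------------

def test_initial_configuration_is_prenatal_evaluation_only(ina):
    config, env = initial_configuration(ina)
    assert basic_set(ina, config) == {"0"}
    assert env["NNC"] is True and env["A1"] is False
    assert is_marked(ina, config) == (False, frozenset())


def test_initial_configuration_single_state_chart():
    chart = build_statechart(
        name="one",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "B"], default_child="A"),
            dict(id="A"), dict(id="B"),
        ],
        initial_state="A",
    )
    config, _ = initial_configuration(chart)
    assert basic_set(chart, config) == {"A"}


def test_initial_state_inside_orthogonal_composite_activates_region_defaults():
    """Default entry through an AND composite starts every region at its
    default state."""
    chart = build_statechart(
        name="and-initial",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["S", "Z"], default_child="S"),
            dict(id="Z"),
            dict(id="S", kind="and_composite", children=["Q1", "Q2"]),
            dict(id="Q1", kind="xor_composite", children=["B", "C"], default_child="B"),
            dict(id="B"), dict(id="C"),
            dict(id="Q2", kind="xor_composite", children=["D", "E"], default_child="D"),
            dict(id="D"), dict(id="E"),
        ],
        initial_state="B",
    )
    config, _ = initial_configuration(chart)
    assert basic_set(chart, config) == {"B", "D"}


# -- enabledness and guards --------------------------------------------------

def test_conditioned_transition_needs_event_and_condition():
    chart = refinement_flat_chart(initial_x=False)
    config, env = initial_configuration(chart)
    enabled = enabled_transitions(chart, config, "g", env)
    assert [t.target for t in enabled] == ["B"]
    env["X"] = True
    enabled = enabled_transitions(chart, config, "g", env)
    assert sorted(t.target for t in enabled) == ["B", "D"]


def test_strict_mode_raises_on_flat_conflict():
    chart = refinement_flat_chart(initial_x=True)
    config, env = initial_configuration(chart)
    with pytest.raises(NondeterminismError):
        enabled_transitions(chart, config, "g", env, strict=True)
    with pytest.raises(NondeterminismError):
        step(chart, config, "g", env, strict=True)
    # non-strict: both alternatives are explorable
    outcomes = {basic_set(chart, r.configuration).pop() for r in step_all(chart, config, "g", env)}
    assert outcomes == {"B", "D"}


def test_event_with_no_enabled_transition_stutters(gestation):
    config, env = initial_configuration(gestation)
    result = step(gestation, config, "f", env)
    assert result.ignored and result.fired == []
    assert result.configuration == config and result.environment == env


# -- orthogonal concurrency (the refinement family) --------------------------

def test_event_advances_both_orthogonal_regions(toys_x):
    chart = toys_x.orthogonal
    config, env = initial_configuration(chart)
    config = step(chart, config, "g", env).configuration  # enter both regions
    assert basic_set(chart, config) == {"B", "D"}
    result = step(chart, config, "f", env)
    assert basic_set(chart, result.configuration) == {"C", "E"}


def test_single_superstate_transition_exits_all_regions(toys_x):
    chart = toys_x.orthogonal
    config, env = initial_configuration(chart)
    config = step(chart, config, "g", env).configuration
    result = step(chart, config, "d", env)
    assert basic_set(chart, result.configuration) == {"A"}
    assert result.fired == ["t5"]


def test_untargeted_region_stays_inactive(toys):
    """With X false only one g-transition fires, so only region Q1 is
    entered; the f step then advances just that region."""
    chart = toys.orthogonal
    config, env = initial_configuration(chart)
    config = step(chart, config, "g", env).configuration
    assert basic_set(chart, config) == {"B"}
    result = step(chart, config, "f", env)
    assert basic_set(chart, result.configuration) == {"C"}


# -- the INA guideline -------------------------------------------------------

def test_apgar_zero_moves_deficient_vitality_to_invasive_support(ina):
    path = run_trace(ina, Trace.from_events(["e1", "e3", "e5", "e11"]))
    assert basic_set(ina, path[-1].configuration) == {"6"}
    result = step(ina, path[-1].configuration, "e14", path[-1].environment)
    assert "16" in result.configuration


def test_clamping_entry_clears_nnc_regardless_of_path(ina):
    for events in (["e1", "e3", "e5", "e6"], ["e1", "e3", "e5", "e10", "e28"]):
        path = run_trace(ina, Trace.from_events(events))
        assert path[-1].environment["NNC"] is False
        assert is_marked(ina, path[-1].configuration)[0]


def test_habitual_clamping_requires_all_three_milestones(ina):
    prefix = ["e1", "e3", "e5", "e10", "e30", "e31"]
    path = run_trace(ina, Trace.from_events(prefix + ["e27"]))
    assert path[-1].ignored  # A3 still missing
    path = run_trace(ina, Trace.from_events(prefix + ["e32", "e27"]))
    assert basic_set(ina, path[-1].configuration) == {"14"}


def test_icc_transition_blocked_after_clamping(ina):
    """NNC-guarded transitions cannot re-fire once the cord is occluded."""
    path = run_trace(ina, Trace.from_events(["e1", "e3", "e5", "e10", "e24"]))
    config, env = path[-1].configuration, path[-1].environment
    assert env["NNC"] is False
    assert enabled_transitions(ina, config, "e27", env) == []


def test_transfer_state_is_marked(ina):
    path = run_trace(ina, Trace.from_events(["e2", "e4", "e5", "e11", "e14", "e23"]))
    flag, states = is_marked(ina, path[-1].configuration)
    assert flag and "19" in states


# -- traces ------------------------------------------------------------------

def test_gestation_trace_reaches_probable_gestation(gestation):
    path = run_trace(gestation, Trace.from_events(["a", "e"]))
    assert [basic_set(gestation, r.configuration) for r in path] == [{"q1"}, {"q3"}]


def test_empty_trace_gives_empty_path(gestation):
    assert run_trace(gestation, Trace()) == []


def test_trace_error_carries_failing_index(gestation):
    from guidechart import TraceError

    with pytest.raises(TraceError) as exc:
        run_trace(gestation, Trace.from_events(["a", "nope"]))
    assert exc.value.index == 1


def test_replay_is_pure(ina):
    trace = Trace.from_events(["e1", "e3", "e5", "e13", "e17", "e20", "e29"])
    p1 = run_trace(ina, trace)
    p2 = run_trace(ina, trace)
    assert [r.configuration for r in p1] == [r.configuration for r in p2]
    assert [r.environment for r in p1] == [r.environment for r in p2]


def test_configurations_stay_consistent_along_traces(ina):
    for events in (
        ["e1", "e3", "e5", "e11", "e15", "e20", "e21", "e36"],
        ["e2", "e4", "e5", "e13", "e17", "e19", "e22"],
    ):
        for r in run_trace(ina, Trace.from_events(events)):
            check_configuration(ina, r.configuration.active)
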