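"""Structural model construction and validation."""

import pytest

from guidechart import (
    CompositeArityError,
    Guard,
    StatechartError,
    TreeViolationError,
    UnknownReferenceError,
    build_statechart,
    validate,
)


def minimal_chart(**overrides):
    spec = dict(
        name="single",
        root="R",
        states=[
            dict(id="R", kind="xor_composite", children=["A", "Z"], default_child="A"),
            dict(id="A"),
            dict(id="Z"),
        ],
        events=[dict(id="x")],
        transitions=[dict(id="t1", source="A", target="Z", event="x")],
        initial_state="A",
    )
    spec.update(overrides)
    return build_statechart(**spec)


def grouped_chart():
    """Two XOR superstates over a shared alphabet (the grouped toy)."""
    return build_statechart(
        name="grouped",
        root="T",
        states=[
            dict(id="T", kind="xor_composite", children=["A", "Q1", "Q2"], default_child="A"),
            dict(id="A"),
            dict(id="Q1", kind="xor_composite", children=["B", "C"], default_child="B"),
            dict(id="B"), dict(id="C"),
            dict(id="Q2", kind="xor_composite", children=["D", "E"], default_child="D"),
            dict(id="D"), dict(id="E"),
        ],
        events=[dict(id="g"), dict(id="f"), dict(id="d")],
        conditions=[dict(id="X", initial_value=False)],
        transitions=[
            dict(id="t1", source="A", target="B", event="g"),
            dict(id="t2", source="A", target="D", event="g", guard={"X": True}),
            dict(id="t3", source="B", target="C", event="f"),
            dict(id="t4", source="D", target="E", event="f"),
            dict(id="t5", source="Q1", target="A", event="d"),
            dict(id="t6", source="Q2", target="A", event="d"),
        ],
        initial_state="A",
    )


def test_grouped_chart_builds_with_two_xor_composites():
    chart = grouped_chart()
    composites = [s for s in chart.states.values() if not s.is_basic and s.id != chart.root]
    assert sorted(c.id for c in composites) == ["Q1", "Q2"]
    assert validate(chart).ok


def test_minimal_chart_valid():
    chart = minimal_chart()
    assert chart.initial_state == "A"
    assert validate(chart).ok


def test_undeclared_child_raises_unknown_reference():
    with pytest.raises(UnknownReferenceError, match="B"):
        build_statechart(
            name="broken",
            root="R",
            states=[
                dict(id="R", kind="xor_composite", children=["Q1", "A"], default_child="A"),
                dict(id="A"),
                dict(id="Q1", kind="xor_composite", children=["B", "C"], default_child="B"),
                dict(id="C"),
            ],
            initial_state="A",
        )


def test_node_with_two_parents_raises_tree_violation():
    with pytest.raises(TreeViolationError, match="two parents"):
        build_statechart(
            name="dag",
            root="R",
            states=[
                dict(id="R", kind="xor_composite", children=["Q1", "Q2"], default_child="Q1"),
                dict(id="Q1", kind="xor_composite", children=["A", "B"], default_child="A"),
                dict(id="Q2", kind="xor_composite", children=["A", "C"], default_child="A"),
                dict(id="A"), dict(id="B"), dict(id="C"),
            ],
            initial_state="A",
        )


@pytest.mark.parametrize(
    "states, message",
    [
        (
            [
                dict(id="R", kind="xor_composite", children=["Q", "A"], default_child="A"),
                dict(id="A"),
                dict(id="Q", kind="xor_composite", children=["B"], default_child="B"),
                dict(id="B"),
            ],
            ">=2 children",
        ),
        (
            [
                dict(id="R", kind="xor_composite", children=["P", "A"], default_child="A"),
                dict(id="A"),
                dict(id="P", kind="and_composite", children=["B", "C"]),
                dict(id="B"), dict(id="C"),
            ],
            "must itself be composite",
        ),
    ],
)
def test_composite_arity_violations(states, message):
    with pytest.raises(CompositeArityError, match=message):
        build_statechart(name="bad", root="R", states=states, initial_state="A")


def test_validate_reports_composite_arity_as_finding():
    chart = minimal_chart(events=[], transitions=[])
    del chart.states["Z"]
    chart.states["R"].children = ["A"]
    report = validate(chart)
    assert not report.ok
    assert any(f.code == "composite-arity" for f in report.errors)


def test_unused_event_is_warning_not_error():
    chart = minimal_chart(events=[dict(id="x"), dict(id="y")])
    report = validate(chart)
    assert report.ok
    assert any(f.code == "unused-event" and "y" in f.ids for f in report.warnings)


def test_duplicate_transition_definition_is_error():
    chart = minimal_chart(
        transitions=[
            dict(id="t1", source="A", target="Z", event="x"),
            dict(id="t2", source="A", target="A", event="x"),
        ]
    )
    report = validate(chart)
    assert not report.ok
    assert any(f.code == "duplicate-transition" for f in report.errors)


def test_guard_with_contradictory_literals_rejected():
    with pytest.raises(StatechartError, match="both values"):
        Guard((("X", True), ("X", False)))


def test_guard_evaluation_is_conjunction():
    g = Guard.of(X=True, Y=False)
    assert g.satisfied({"X": True, "Y": False})
    assert not g.satisfied({"X": True, "Y": True})
    assert Guard().satisfied({})  # empty guard always true
    assert str(g) == "X & !Y"


def test_undeclared_guard_condition_rejected():
    with pytest.raises(UnknownReferenceError, match="X"):
        minimal_chart(
            transitions=[dict(id="t1", source="A", target="Z", event="x", guard={"X": True})]
        )


def test_event_and_condition_ids_must_be_disjoint():
    with pytest.raises(StatechartError, match="both event and condition"):
        minimal_chart(conditions=[dict(id="x")])


def test_bundled_models_all_validate(ina, gestation):
    from guidechart import load_bundled, BUNDLED_MODELS

    for name in BUNDLED_MODELS:
        report = validate(load_bundled(name))
        assert report.ok, (name, [f.message for f in report.errors])
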