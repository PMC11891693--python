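"""Programmatic definitions of the bundled guideline models.

This module is the authoring source of the ``models/*.chart.json`` data
files: each builder constructs the chart in memory, and the committed
JSON is the :func:`~guidechart.io_formats.write_model` rendering of it.
A regression test asserts the committed files still equal these
definitions, so edits must go through this module.

The immediate-neonatal-adaptation (INA) chart encodes the
physiologically-based cord-clamping guideline: prenatal evaluation,
mode of birth, vitality/ventilation diagnosis by Apgar and
Silverman–Andersen scores, the four clamping modalities (immediate,
early, habitual, deferred — each guarded by the not-yet-clamped
condition NNC, which entering any clamping state irreversibly clears),
minute-1/5/10 evaluations, and concurrent ventilatory/cardiovascular
assistance modeled as orthogonal regions.
"""

from __future__ import annotations

from .core_model import (
    ActionTiming,
    ConditionAction,
    Statechart,
    build_statechart,
)

__all__ = ["build_ina", "build_gestation", "build_refinement_flat",
           "build_refinement_grouped", "build_refinement_orthogonal", "BUILDERS"]


def _clamp_entry() -> list[ConditionAction]:
    # clamping is irreversible: any clamping state clears NNC on entry,
    # regardless of which transition led there
    return [ConditionAction("NNC", False, ActionTiming.ON_ENTRY)]


def build_ina() -> Statechart:
    """The INA guideline statechart: 20 basic states, 4 superstates
    (A, B, C, D), 38 events, 4 conditions."""
    NNC = {"NNC": True}
    states = [
        dict(id="INA", kind="xor_composite",
             children=["0", "1", "2", "3", "4", "5", "6", "7", "12", "C", "D", "18", "19"],
             default_child="0", clinical_label="Immediate Neonatal Adaptation"),
        dict(id="0", clinical_label="Prenatal evaluation"),
        dict(id="1", clinical_label="Vaginal birth attendance (habitual risk or increased "
                                    "risk without abdominal-birth indication)"),
        dict(id="2", clinical_label="Abdominal birth attendance (increased risk with "
                                    "abdominal-birth indication)",
             criticality="intervention"),
        dict(id="3", clinical_label="Birth completed"),
        dict(id="4", clinical_label="Diagnosis of vitality and ventilation at birth"),
        dict(id="5", clinical_label="Mild ventilation difficulty "
                                    "(Silverman-Andersen score 1-3)",
             criticality="intervention"),
        dict(id="6", clinical_label="Deficient vitality (low Apgar score)",
             criticality="intervention"),
        dict(id="7", clinical_label="Severe ventilation difficulty "
                                    "(Silverman-Andersen score >= 4)",
             criticality="intervention"),
        # superstate C: clamping type
        dict(id="C", kind="xor_composite", children=["11", "13", "14", "15"],
             default_child="11", clinical_label="Clamping Type"),
        dict(id="11", clinical_label="Diagnosis of adequate or normal ventilation"),
        dict(id="13", clinical_label="Early clamping of the umbilical cord (ECC)",
             criticality="positive", marked=True, entry_actions=_clamp_entry()),
        dict(id="14", clinical_label="Habitual clamping of the umbilical cord (HCC)",
             criticality="positive", marked=True, entry_actions=_clamp_entry()),
        dict(id="15", clinical_label="Deferred clamping of the umbilical cord (DCC)",
             criticality="positive", marked=True, entry_actions=_clamp_entry()),
        dict(id="12", clinical_label="Immediate clamping of the umbilical cord (ICC)",
             criticality="positive", marked=True, entry_actions=_clamp_entry()),
        # superstate D: orthogonal assistance + temporal diagnosis
        dict(id="D", kind="and_composite", children=["A", "B"],
             clinical_label="Vitality and Ventilation Medical Assistance"),
        dict(id="A", kind="xor_composite", children=["17", "16"], default_child="17",
             clinical_label="Ventilatory and Cardiovascular Assistance"),
        dict(id="17", clinical_label="Non-invasive ventilatory assistance",
             criticality="intervention"),
        dict(id="16", clinical_label="Invasive ventilatory, cardiac and "
                                     "hemodynamic assistance",
             criticality="critical"),
        dict(id="B", kind="xor_composite", children=["8", "9", "10"], default_child="8",
             clinical_label="Temporal Diagnosis of Vitality and Ventilation"),
        dict(id="8", clinical_label="Evaluation of vitality and ventilation at minute 1"),
        dict(id="9", clinical_label="Evaluation of vitality and ventilation at minute 5"),
        dict(id="10", clinical_label="Evaluation of vitality and ventilation at minute 10"),
        dict(id="18", clinical_label="Joint accommodation with the mother",
             criticality="positive", marked=True),
        dict(id="19", clinical_label="Transfer to neonatal care unit",
             criticality="intervention", marked=True),
    ]
    events = [
        ("e1", "Habitual risk or increased risk without indication of abdominal birth"),
        ("e2", "Increased risk with abdominal birth indication"),
        ("e3", "Vaginal birth occurs"),
        ("e4", "Abdominal birth performed"),
        ("e5", "Newborn presented for assessment"),
        ("e6", "Rupture of the umbilical cord (ICC indication)"),
        ("e7", "Placental detachment with bloodless umbilical vein (ICC indication)"),
        ("e8", "Bloodless umbilical vein (ICC indication)"),
        ("e9", "Catastrophic placental bleeding (ICC indication)"),
        ("e10", "Adequate vitality and ventilation at birth"),
        ("e11", "Deficient vitality detected (low Apgar score)"),
        ("e12", "Mild ventilation difficulty (Silverman-Andersen score 1-3)"),
        ("e13", "Severe ventilation difficulty (Silverman-Andersen score >= 4)"),
        ("e14", "Apgar evaluation of 0 confirmed"),
        ("e15", "Ventilatory support required for deficient vitality"),
        ("e16", "Ventilation difficulty persists, assistance required"),
        ("e17", "Respiratory deterioration, invasive support required"),
        ("e18", "Ventilation improves spontaneously"),
        ("e19", "Non-invasive assistance insufficient"),
        ("e20", "Fifth-minute evaluation performed"),
        ("e21", "Tenth-minute evaluation performed"),
        ("e22", "Vitality and ventilation recovered (Apgar and Silverman-Andersen normal)"),
        ("e23", "Indication of transfer to neonatal care unit"),
        ("e24", "Indication of ECC: maternal toxemia or diabetes (polycythemia risk)"),
        ("e25", "Indication of ECC: maternal RhD immunization, hemolytic disease risk"),
        ("e26", "Indication of ECC: maternal viral disease (HIV, CMV) or myasthenia gravis"),
        ("e27", "Indication of Habitual Cord Clamping (conditions A1-A3 present)"),
        ("e28", "Indication of DCC: cord prolapse or breech birth"),
        ("e29", "Indication of DCC: deficient vitality or ventilation persisting"),
        ("e30", "Condition A1 attained"),
        ("e31", "Condition A2 attained"),
        ("e32", "Condition A3 attained"),
        ("e33", "Newborn stable after clamping, ready for joint accommodation"),
        ("e34", "Post-clamping complication detected"),
        ("e35", "Apgar score >= 7 at fifth-minute evaluation"),
        ("e36", "Apgar score >= 7 at tenth-minute evaluation"),
        ("e37", "Apgar score <= 3 at tenth-minute evaluation"),
        ("e38", "Indication of DCC: prolonged membrane rupture, circulars, bands or "
                "funicular knots"),
    ]
    conditions = [
        dict(id="NNC", description="Neonate has not been clamped (umbilical cord "
                                   "not occluded)", initial_value=True),
        dict(id="A1", description="Physiological condition A1: effective pulmonary "
                                  "ventilation established", initial_value=False),
        dict(id="A2", description="Physiological condition A2: pulmonary-systemic "
                                  "perfusion transition completed", initial_value=False),
        dict(id="A3", description="Physiological condition A3: decline of umbilical "
                                  "cord flow", initial_value=False),
    ]
    transitions = [
        dict(id="t01", source="0", target="1", event="e1"),
        dict(id="t02", source="0", target="2", event="e2"),
        dict(id="t03", source="1", target="3", event="e3"),
        dict(id="t04", source="2", target="3", event="e4"),
        dict(id="t05", source="3", target="4", event="e5"),
        # immediate clamping: four clinical indications, all conditioned on NNC
        dict(id="t06", source="4", target="12", event="e6", guard=NNC),
        dict(id="t07", source="4", target="12", event="e7", guard=NNC),
        dict(id="t08", source="4", target="12", event="e8", guard=NNC),
        dict(id="t09", source="4", target="12", event="e9", guard=NNC),
        dict(id="t10", source="4", target="C", event="e10"),
        dict(id="t11", source="4", target="6", event="e11"),
        dict(id="t12", source="4", target="5", event="e12"),
        dict(id="t13", source="4", target="7", event="e13"),
        # entries into the orthogonal assistance superstate D: the same
        # indicator starts the assistance region and the minute-clock region
        dict(id="t14", source="6", target="16", event="e14"),
        dict(id="t15", source="6", target="8", event="e14"),
        dict(id="t16", source="6", target="17", event="e15"),
        dict(id="t17", source="6", target="8", event="e15"),
        dict(id="t18", source="5", target="17", event="e16"),
        dict(id="t19", source="5", target="8", event="e16"),
        dict(id="t20", source="7", target="16", event="e17"),
        dict(id="t21", source="7", target="8", event="e17"),
        dict(id="t22", source="5", target="C", event="e18"),
        dict(id="t23", source="17", target="16", event="e19"),
        dict(id="t24", source="8", target="9", event="e20"),
        dict(id="t25", source="9", target="10", event="e21"),
        dict(id="t26", source="D", target="C", event="e22"),
        dict(id="t27", source="D", target="19", event="e23"),
        # early / habitual / deferred clamping, conditioned on NNC
        dict(id="t28", source="11", target="13", event="e24", guard=NNC),
        dict(id="t29", source="11", target="13", event="e25", guard=NNC),
        dict(id="t30", source="11", target="13", event="e26", guard=NNC),
        dict(id="t31", source="11", target="14", event="e27",
             guard={"NNC": True, "A1": True, "A2": True, "A3": True}),
        dict(id="t32", source="11", target="15", event="e28", guard=NNC),
        dict(id="t33", source="11", target="15", event="e38", guard=NNC),
        dict(id="t34", source="D", target="15", event="e29", guard=NNC),
        # physiological milestones A1-A3 are recorded without leaving the
        # normal-ventilation diagnosis state
        dict(id="t35", source="11", target="11", event="e30",
             actions=[dict(condition="A1", value=True)]),
        dict(id="t36", source="11", target="11", event="e31",
             actions=[dict(condition="A2", value=True)]),
        dict(id="t37", source="11", target="11", event="e32",
             actions=[dict(condition="A3", value=True)]),
        # outcomes after clamping; guarded on the cord being occluded so
        # they cannot fire from the pre-clamping diagnosis state
        dict(id="t38", source="C", target="18", event="e33", guard={"NNC": False}),
        dict(id="t39", source="12", target="18", event="e33"),
        dict(id="t40", source="C", target="19", event="e34", guard={"NNC": False}),
        dict(id="t41", source="12", target="19", event="e34"),
        dict(id="t42", source="9", target="11", event="e35"),
        dict(id="t43", source="10", target="11", event="e36"),
        dict(id="t44", source="10", target="19", event="e37"),
    ]
    return build_statechart(
        name="ina",
        root="INA",
        states=states,
        events=[dict(id=i, description=d) for i, d in events],
        conditions=conditions,
        transitions=transitions,
        initial_state="0",
    )


def build_gestation() -> Statechart:
    """Gestation-risk screening automaton (flat chart): decides whether a
    diagnostic nuclear-medicine procedure may proceed given possible
    gestation; q5 (done) and q6 (postponed) are marked terminal states."""
    states = [
        dict(id="G", kind="xor_composite",
             children=["q0", "q1", "q2", "q3", "q4", "q5", "q6"], default_child="q0",
             clinical_label="Gestation risk evaluation"),
        dict(id="q0", clinical_label="start of the test"),
        dict(id="q1", clinical_label="established menstrual cycle"),
        dict(id="q2", clinical_label="uncertain menstrual cycle"),
        dict(id="q3", clinical_label="probable gestation", criticality="intervention"),
        dict(id="q4", clinical_label="improbable gestation"),
        dict(id="q5", clinical_label="the procedure is done", marked=True,
             criticality="positive"),
        dict(id="q6", clinical_label="the procedure is postponed", marked=True,
             criticality="intervention"),
    ]
    events = [
        ("a", "18 < Age < 55 years"),
        ("b", "12 < Age < 17 years"),
        ("c", "Presents menstruation"),
        ("d", "Patient rules out possible gestation"),
        ("e", "The patient does NOT rule out possible pregnancy"),
        ("f", "Last menstrual period (LMP) < 10 days"),
        ("g", "She did not start menstruation"),
        ("h", "Hysterectomy or Age > 50 years or Last Menstrual Period > 12 months"),
        ("i", "Last Menstrual Period (LMP) > 10 days"),
    ]
    transitions = [
        dict(id="t01", source="q0", target="q1", event="a"),
        dict(id="t02", source="q0", target="q2", event="b"),
        dict(id="t03", source="q0", target="q4", event="h"),
        dict(id="t04", source="q2", target="q1", event="c"),
        dict(id="t05", source="q2", target="q4", event="g"),
        dict(id="t06", source="q1", target="q4", event="d"),
        dict(id="t07", source="q1", target="q3", event="e"),
        dict(id="t08", source="q3", target="q5", event="f"),
        dict(id="t09", source="q3", target="q6", event="i"),
        dict(id="t10", source="q4", target="q5", event="f"),
    ]
    return build_statechart(
        name="gestation-risk",
        root="G",
        states=states,
        events=[dict(id=i, description=d) for i, d in events],
        transitions=transitions,
        initial_state="q0",
    )


_TOY_EVENTS = [
    dict(id="g", description="trigger from A"),
    dict(id="f", description="advance inner state"),
    dict(id="d", description="return to A"),
]
_TOY_CONDITION = [dict(id="X", description="side condition enabling the "
                                           "concurrent branch", initial_value=False)]


def build_refinement_flat() -> Statechart:
    """Flat five-state chart with one conditioned transition; the
    reference behavior for the two hierarchical refinements below."""
    states = [
        dict(id="T", kind="xor_composite", children=["A", "B", "C", "D", "E"],
             default_child="A"),
        dict(id="A"), dict(id="B"), dict(id="C"), dict(id="D"), dict(id="E"),
    ]
    transitions = [
        dict(id="t1", source="A", target="B", event="g"),
        dict(id="t2", source="A", target="D", event="g", guard={"X": True}),
        dict(id="t3", source="B", target="C", event="f"),
        dict(id="t4", source="D", target="E", event="f"),
        dict(id="t5", source="B", target="A", event="d"),
        dict(id="t6", source="C", target="A", event="d"),
        dict(id="t7", source="D", target="A", event="d"),
        dict(id="t8", source="E", target="A", event="d"),
    ]
    return build_statechart(
        name="refinement-flat", root="T", states=states, events=_TOY_EVENTS,
        conditions=_TOY_CONDITION, transitions=transitions, initial_state="A",
    )


def build_refinement_grouped() -> Statechart:
    """Same behavior with B/C and D/E grouped into XOR superstates, so
    the four return transitions collapse into two superstate-level ones."""
    states = [
        dict(id="T", kind="xor_composite", children=["A", "Q1", "Q2"], default_child="A"),
        dict(id="A"),
        dict(id="Q1", kind="xor_composite", children=["B", "C"], default_child="B"),
        dict(id="B"), dict(id="C"),
        dict(id="Q2", kind="xor_composite", children=["D", "E"], default_child="D"),
        dict(id="D"), dict(id="E"),
    ]
    transitions = [
        dict(id="t1", source="A", target="B", event="g"),
        dict(id="t2", source="A", target="D", event="g", guard={"X": True}),
        dict(id="t3", source="B", target="C", event="f"),
        dict(id="t4", source="D", target="E", event="f"),
        dict(id="t5", source="Q1", target="A", event="d"),
        dict(id="t6", source="Q2", target="A", event="d"),
    ]
    return build_statechart(
        name="refinement-grouped", root="T", states=states, events=_TOY_EVENTS,
        conditions=_TOY_CONDITION, transitions=transitions, initial_state="A",
    )


def build_refinement_orthogonal() -> Statechart:
    """Same behavior with Q1/Q2 as orthogonal regions of a superstate S:
    the two g-transitions may fire concurrently, and a single
    superstate-level d-transition returns to A."""
    states = [
        dict(id="T", kind="xor_composite", children=["A", "S"], default_child="A"),
        dict(id="A"),
        dict(id="S", kind="and_composite", children=["Q1", "Q2"]),
        dict(id="Q1", kind="xor_composite", children=["B", "C"], default_child="B"),
        dict(id="B"), dict(id="C"),
        dict(id="Q2", kind="xor_composite", children=["D", "E"], default_child="D"),
        dict(id="D"), dict(id="E"),
    ]
    transitions = [
        dict(id="t1", source="A", target="B", event="g"),
        dict(id="t2", source="A", target="D", event="g", guard={"X": True}),
        dict(id="t3", source="B", target="C", event="f"),
        dict(id="t4", source="D", target="E", event="f"),
        dict(id="t5", source="S", target="A", event="d"),
    ]
    return build_statechart(
        name="refinement-orthogonal", root="T", states=states, events=_TOY_EVENTS,
        conditions=_TOY_CONDITION, transitions=transitions, initial_state="A",
    )


BUILDERS = {
    "ina": build_ina,
    "gestation": build_gestation,
    "refinement-flat": build_refinement_flat,
    "refinement-grouped": build_refinement_grouped,
    "refinement-orthogonal": build_refinement_orthogonal,
}
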