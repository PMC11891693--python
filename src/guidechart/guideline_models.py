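"""Bundled guideline models, loaded from the packaged ``models/*.chart.json``
data files.

Three families ship with the package:

* ``ina`` — the immediate-neonatal-adaptation statechart (20 basic
  states, 4 superstates, 38 events): prenatal evaluation, mode of birth,
  vitality/ventilation diagnosis, the four physiologically-indicated
  cord-clamping modalities guarded by the not-yet-clamped condition NNC,
  minute-1/5/10 evaluations, and orthogonal ventilatory/cardiovascular
  assistance.
* ``gestation`` — the flat gestation-risk screening automaton (7 states,
  9 events) deciding whether a diagnostic procedure may proceed.
* the refinement family — one behavior encoded three ways (flat chart,
  XOR-grouped, orthogonal regions), used as the oracle for flattening.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import NamedTuple

from .core_model import Statechart, StateKind
from .flatten import FlatAutomaton, FlatState, flat_chart_to_automaton
from .io_formats import read_model

__all__ = [
    "StatisticsRecord",
    "BUNDLED_MODELS",
    "load_bundled",
    "ina_statechart",
    "gestation_risk_chart",
    "gestation_risk_automaton",
    "RefinementModels",
    "refinement_models",
    "refinement_flat_chart",
    "model_statistics",
]

BUNDLED_MODELS = (
    "ina",
    "gestation",
    "refinement-flat",
    "refinement-grouped",
    "refinement-orthogonal",
)

_FILES = {
    "ina": "ina.chart.json",
    "gestation": "gestation.chart.json",
    "refinement-flat": "refinement_flat.chart.json",
    "refinement-grouped": "refinement_grouped.chart.json",
    "refinement-orthogonal": "refinement_orthogonal.chart.json",
}


def load_bundled(name: str) -> Statechart:
    """Load a bundled model by short name (see :data:`BUNDLED_MODELS`)."""
    if name not in _FILES:
        raise KeyError(f"unknown bundled model {name!r}; choose from {BUNDLED_MODELS}")
    text = resources.files("guidechart").joinpath("models", _FILES[name]).read_text()
    return read_model(text)


def ina_statechart() -> Statechart:
    """The immediate-neonatal-adaptation guideline statechart."""
    return load_bundled("ina")


def gestation_risk_chart() -> Statechart:
    """The gestation-risk automaton as a (flat) statechart."""
    return load_bundled("gestation")


def gestation_risk_automaton() -> FlatAutomaton:
    """The gestation-risk automaton with its original state ids
    (q0..q6) and clinical labels; q5 and q6 are marked terminals."""
    return flat_chart_to_automaton(gestation_risk_chart())


class RefinementModels(NamedTuple):
    flat: FlatAutomaton
    grouped: Statechart
    orthogonal: Statechart


def _with_initial_x(chart: Statechart, initial_x: bool) -> Statechart:
    chart.conditions["X"] = replace(chart.conditions["X"], initial_value=initial_x)
    return chart


def refinement_flat_chart(initial_x: bool = False) -> Statechart:
    """The flat member of the refinement family as a chart (useful for
    nondeterminism analysis of the unrefined encoding)."""
    return _with_initial_x(load_bundled("refinement-flat"), initial_x)


def _manual_flat_automaton(initial_x: bool) -> FlatAutomaton:
    """Hand-encoded reference automaton for the refinement family at a
    fixed X valuation, independent of the flattening pipeline."""
    states = {s: FlatState(s, s) for s in "ABCDE"}
    tmap: dict[tuple[str, str], frozenset[str]] = {
        ("g", "A"): frozenset({"B", "D"}) if initial_x else frozenset({"B"}),
        ("f", "B"): frozenset({"C"}),
        ("f", "D"): frozenset({"E"}),
        ("d", "B"): frozenset({"A"}),
        ("d", "C"): frozenset({"A"}),
        ("d", "D"): frozenset({"A"}),
        ("d", "E"): frozenset({"A"}),
    }
    return FlatAutomaton(
        events=frozenset({"g", "f", "d"}),
        states=states,
        transition_map=tmap,
        initial="A",
        marked=frozenset(),
        name=f"refinement-reference(X={'1' if initial_x else '0'})",
    )


def refinement_models(initial_x: bool = False) -> RefinementModels:
    """One behavior, three encodings: the hand-encoded flat reference
    automaton, the XOR-grouped chart, and the orthogonal-regions chart.
    All three are finite-horizon trace equivalent at either X valuation."""
    return RefinementModels(
        flat=_manual_flat_automaton(initial_x),
        grouped=_with_initial_x(load_bundled("refinement-grouped"), initial_x),
        orthogonal=_with_initial_x(load_bundled("refinement-orthogonal"), initial_x),
    )


@dataclass(frozen=True)
class StatisticsRecord:
    """Structural model statistics; the synthetic root composite that
    wraps the top-level states is excluded from the counts."""

    basic_state_count: int
    superstate_count: int
    event_count: int
    condition_count: int
    transition_count: int
    marked_state_count: int

    def as_dict(self) -> dict[str, int]:
        return {
            "basic_states": self.basic_state_count,
            "superstates": self.superstate_count,
            "events": self.event_count,
            "conditions": self.condition_count,
            "transitions": self.transition_count,
            "marked_states": self.marked_state_count,
        }


def model_statistics(chart: Statechart) -> StatisticsRecord:
    basics = [s for s in chart.states.values() if s.kind is StateKind.BASIC]
    supers = [
        s for s in chart.states.values()
        if s.kind is not StateKind.BASIC and s.id != chart.root
    ]
    return StatisticsRecord(
        basic_state_count=len(basics),
        superstate_count=len(supers),
        event_count=len(chart.events),
        condition_count=len(chart.conditions),
        transition_count=len(chart.transitions),
        marked_state_count=sum(1 for s in chart.states.values() if s.marked),
    )
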