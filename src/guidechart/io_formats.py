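"""Readers and writers: the canonical model JSON dialect, JSON-lines
traces, and Graphviz DOT / SCXML exports.

The model dialect (``.chart.json``) mirrors the in-memory types
field-for-field; unknown fields are rejected with the offending path so
typos in hand-edited models surface immediately.  All writers emit
deterministic, byte-stable text (fixed key order, entries sorted by id)
so exports of the bundled guideline models can be kept under golden-file
regression tests.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .core_model import (
    ActionTiming,
    ConditionAction,
    ConditionSymbol,
    Criticality,
    EventSymbol,
    Guard,
    StateKind,
    StateNode,
    Statechart,
    StatechartError,
    Transition,
    build_statechart,
)
from .flatten import FlatAutomaton

__all__ = [
    "FORMAT_VERSION",
    "ParseError",
    "VersionMismatchError",
    "TraceBindError",
    "Trace",
    "TraceItem",
    "read_model",
    "write_model",
    "read_trace",
    "write_trace",
    "bind_trace",
    "export_dot",
    "export_scxml",
    "write_automaton",
]

FORMAT_VERSION = "1.0"


class ParseError(StatechartError):
    """Malformed document; the message names the offending path."""


class VersionMismatchError(ParseError):
    pass


class TraceBindError(StatechartError):
    """A trace references an id the model does not declare."""


# ---------------------------------------------------------------------------
# model dialect
# ---------------------------------------------------------------------------

_STATE_FIELDS = {
    "id", "clinical_label", "kind", "children", "default_child",
    "marked", "criticality", "entry_actions",
}
_EVENT_FIELDS = {"id", "description"}
_CONDITION_FIELDS = {"id", "description", "initial_value"}
_TRANSITION_FIELDS = {"id", "source", "target", "event", "guard", "actions"}
_TOP_FIELDS = {
    "format_version", "name", "root", "initial_state",
    "states", "events", "conditions", "transitions",
}


def _require(doc: Mapping, key: str, path: str):
    if key not in doc:
        raise ParseError(f"{path}: missing required field {key!r}")
    return doc[key]


def _reject_unknown(doc: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ParseError(f"{path}.{sorted(unknown)[0]}: unknown field")


def _parse_action(obj, path: str, timing: ActionTiming) -> ConditionAction:
    if not isinstance(obj, Mapping):
        raise ParseError(f"{path}: action must be an object")
    _reject_unknown(obj, {"condition", "value"}, path)
    return ConditionAction(
        condition=str(_require(obj, "condition", path)),
        value=bool(_require(obj, "value", path)),
        timing=timing,
    )


def read_model(text: str) -> Statechart:
    """Parse a model document into a validated :class:`Statechart`."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(doc, Mapping):
        raise ParseError("$: document must be a JSON object")
    _reject_unknown(doc, _TOP_FIELDS, "$")
    version = _require(doc, "format_version", "$")
    if version != FORMAT_VERSION:
        raise VersionMismatchError(
            f"$.format_version: expected {FORMAT_VERSION!r}, got {version!r}"
        )

    states = []
    for i, s in enumerate(doc.get("states", [])):
        path = f"$.states[{i}]"
        _reject_unknown(s, _STATE_FIELDS, path)
        states.append(
            StateNode(
                id=str(_require(s, "id", path)),
                clinical_label=str(s.get("clinical_label", "")),
                kind=StateKind(s.get("kind", "basic")),
                children=[str(c) for c in s.get("children", [])],
                default_child=s.get("default_child"),
                marked=bool(s.get("marked", False)),
                criticality=Criticality(s.get("criticality", "normal")),
                entry_actions=[
                    _parse_action(a, f"{path}.entry_actions[{j}]", ActionTiming.ON_ENTRY)
                    for j, a in enumerate(s.get("entry_actions", []))
                ],
            )
        )
    events = []
    for i, e in enumerate(doc.get("events", [])):
        path = f"$.events[{i}]"
        _reject_unknown(e, _EVENT_FIELDS, path)
        events.append(EventSymbol(str(_require(e, "id", path)), str(e.get("description", ""))))
    conditions = []
    for i, c in enumerate(doc.get("conditions", [])):
        path = f"$.conditions[{i}]"
        _reject_unknown(c, _CONDITION_FIELDS, path)
        conditions.append(
            ConditionSymbol(
                str(_require(c, "id", path)),
                str(c.get("description", "")),
                bool(c.get("initial_value", False)),
            )
        )
    transitions = []
    for i, t in enumerate(doc.get("transitions", [])):
        path = f"$.transitions[{i}]"
        _reject_unknown(t, _TRANSITION_FIELDS, path)
        guard = t.get("guard", {})
        if not isinstance(guard, Mapping):
            raise ParseError(f"{path}.guard: must be an object of condition: bool")
        transitions.append(
            Transition(
                id=str(_require(t, "id", path)),
                source=str(_require(t, "source", path)),
                target=str(_require(t, "target", path)),
                event=str(_require(t, "event", path)),
                guard=Guard(tuple(sorted((str(k), bool(v)) for k, v in guard.items()))),
                actions=[
                    _parse_action(a, f"{path}.actions[{j}]", ActionTiming.ON_FIRING)
                    for j, a in enumerate(t.get("actions", []))
                ],
            )
        )

    return build_statechart(
        name=str(_require(doc, "name", "$")),
        root=str(_require(doc, "root", "$")),
        states=states,
        events=events,
        conditions=conditions,
        transitions=transitions,
        initial_state=str(_require(doc, "initial_state", "$")),
    )


def write_model(chart: Statechart) -> str:
    """Serialize a chart to the canonical dialect: fixed key order,
    states/events/conditions/transitions sorted by id, 2-space indent."""

    def action_doc(a: ConditionAction) -> dict:
        return {"condition": a.condition, "value": a.value}

    def state_doc(s: StateNode) -> dict:
        d: dict = {"id": s.id}
        if s.clinical_label:
            d["clinical_label"] = s.clinical_label
        if s.kind is not StateKind.BASIC:
            d["kind"] = s.kind.value
            d["children"] = list(s.children)
        if s.default_child is not None:
            d["default_child"] = s.default_child
        if s.marked:
            d["marked"] = True
        if s.criticality is not Criticality.NORMAL:
            d["criticality"] = s.criticality.value
        if s.entry_actions:
            d["entry_actions"] = [action_doc(a) for a in s.entry_actions]
        return d

    def transition_doc(t: Transition) -> dict:
        d: dict = {"id": t.id, "source": t.source, "target": t.target, "event": t.event}
        if t.guard.literals:
            d["guard"] = {cid: val for cid, val in t.guard.literals}
        if t.actions:
            d["actions"] = [action_doc(a) for a in t.actions]
        return d

    doc = {
        "format_version": FORMAT_VERSION,
        "name": chart.name,
        "root": chart.root,
        "initial_state": chart.initial_state,
        "states": [state_doc(chart.states[k]) for k in sorted(chart.states)],
        "events": [
            {"id": e.id, **({"description": e.description} if e.description else {})}
            for e in (chart.events[k] for k in sorted(chart.events))
        ],
        "conditions": [
            {
                "id": c.id,
                **({"description": c.description} if c.description else {}),
                "initial_value": c.initial_value,
            }
            for c in (chart.conditions[k] for k in sorted(chart.conditions))
        ],
        "transitions": [transition_doc(chart.transitions[k]) for k in sorted(chart.transitions)],
    }
    return json.dumps(doc, indent=2) + "\n"


# ---------------------------------------------------------------------------
# traces (JSON-lines)
# ---------------------------------------------------------------------------

@dataclass
class TraceItem:
    event: str
    updates: dict[str, bool] = field(default_factory=dict)
    note: Optional[str] = None


@dataclass
class Trace:
    """An initial condition valuation override plus an ordered sequence
    of event occurrences with optional external condition updates."""

    model: Optional[str] = None
    initial_conditions: dict[str, bool] = field(default_factory=dict)
    items: list[TraceItem] = field(default_factory=list)

    @staticmethod
    def from_events(events, model: Optional[str] = None) -> "Trace":
        return Trace(model=model, items=[TraceItem(e) for e in events])

    @property
    def events(self) -> list[str]:
        return [item.event for item in self.items]


def read_trace(text: str, chart: Optional[Statechart] = None) -> Trace:
    """Parse a JSON-lines trace; one item per line, optionally preceded
    by a header line carrying the model name and initial condition
    overrides.  With ``chart`` given, ids are bound at load time."""
    trace = Trace()
    lines = [ln for ln in text.splitlines()]
    first_item = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as e:
            raise ParseError(f"line {lineno}: invalid JSON: {e.msg}") from e
        if not isinstance(obj, Mapping):
            raise ParseError(f"line {lineno}: expected an object")
        if first_item and "event" not in obj:
            _reject_unknown(obj, {"model", "initial_conditions"}, f"line {lineno}")
            trace.model = obj.get("model")
            trace.initial_conditions = {
                str(k): bool(v) for k, v in obj.get("initial_conditions", {}).items()
            }
            first_item = False
            continue
        first_item = False
        _reject_unknown(obj, {"event", "set", "note"}, f"line {lineno}")
        item = TraceItem(
            event=str(_require(obj, "event", f"line {lineno}")),
            updates={str(k): bool(v) for k, v in obj.get("set", {}).items()},
            note=obj.get("note"),
        )
        if chart is not None:
            _bind_item(item, chart, lineno)
        trace.items.append(item)
    if chart is not None:
        _bind_header(trace, chart)
    return trace


def _bind_item(item: TraceItem, chart: Statechart, lineno: int) -> None:
    if item.event not in chart.events:
        raise TraceBindError(f"line {lineno}: unknown event id {item.event!r}")
    for cid in item.updates:
        if cid not in chart.conditions:
            raise TraceBindError(f"line {lineno}: unknown condition id {cid!r}")


def _bind_header(trace: Trace, chart: Statechart) -> None:
    for cid in trace.initial_conditions:
        if cid not in chart.conditions:
            raise TraceBindError(f"header: unknown condition id {cid!r}")


def bind_trace(trace: Trace, chart: Statechart) -> Trace:
    """Check every id in ``trace`` against ``chart``; returns the trace."""
    _bind_header(trace, chart)
    for i, item in enumerate(trace.items, start=1):
        _bind_item(item, chart, i)
    return trace


def write_trace(trace: Trace) -> str:
    lines = []
    if trace.model is not None or trace.initial_conditions:
        header: dict = {}
        if trace.model is not None:
            header["model"] = trace.model
        if trace.initial_conditions:
            header["initial_conditions"] = dict(sorted(trace.initial_conditions.items()))
        lines.append(json.dumps(header))
    for item in trace.items:
        obj: dict = {"event": item.event}
        if item.updates:
            obj["set"] = dict(sorted(item.updates.items()))
        if item.note:
            obj["note"] = item.note
        lines.append(json.dumps(obj))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Graphviz DOT export
# ---------------------------------------------------------------------------

_FILL = {
    Criticality.NORMAL: "lightgray",
    Criticality.INTERVENTION: "orange",
    Criticality.CRITICAL: "magenta",
    Criticality.POSITIVE: "palegreen",
}


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _edge_label(t: Transition) -> str:
    label = t.event
    if t.guard.literals:
        label += f" [{t.guard}]"
    if t.actions:
        label += " / " + "; ".join(
            f"{a.condition}:={'1' if a.value else '0'}" for a in t.actions
        )
    return label


def export_dot(obj: Union[Statechart, FlatAutomaton]) -> str:
    """Render a chart (superstates as clusters, orthogonal regions as
    dashed clusters, marked states double-bordered, criticality classes
    as fill colors) or a flat automaton as Graphviz DOT text."""
    if isinstance(obj, FlatAutomaton):
        return _export_dot_automaton(obj)
    return _export_dot_chart(obj)


def _export_dot_chart(chart: Statechart) -> str:
    out: list[str] = []
    out.append(f'digraph "{_dot_escape(chart.name)}" {{')
    out.append("  compound=true;")
    out.append("  rankdir=TB;")
    out.append('  node [shape=box, style="rounded,filled"];')

    def emit(sid: str, indent: str) -> None:
        node = chart.states[sid]
        if node.is_basic:
            attrs = [f'label="{_dot_escape(node.clinical_label or sid)}"']
            attrs.append(f'fillcolor="{_FILL[node.criticality]}"')
            if node.marked:
                attrs.append("peripheries=2")
            out.append(f'{indent}"{sid}" [{", ".join(attrs)}];')
        else:
            parent = chart.parent(sid)
            dashed = parent is not None and chart.states[parent].kind is StateKind.AND
            out.append(f'{indent}subgraph "cluster_{sid}" {{')
            out.append(f'{indent}  label="{_dot_escape(node.clinical_label or sid)}";')
            out.append(f'{indent}  style={"dashed" if dashed else "solid"};')
            for c in node.children:
                emit(c, indent + "  ")
            out.append(f"{indent}}}")

    for c in chart.states[chart.root].children:
        emit(c, "  ")

    def anchor(sid: str) -> str:
        """Representative basic node for composite edge endpoints."""
        node = chart.states[sid]
        while node.is_composite:
            nxt = node.default_child or node.children[0]
            node = chart.states[nxt]
        return node.id

    out.append(f'  "__initial" [shape=point, label=""];')
    out.append(f'  "__initial" -> "{chart.initial_state}";')
    for tid in sorted(chart.transitions):
        t = chart.transitions[tid]
        attrs = [f'label="{_dot_escape(_edge_label(t))}"']
        if chart.states[t.source].is_composite:
            attrs.append(f'ltail="cluster_{t.source}"')
        if chart.states[t.target].is_composite:
            attrs.append(f'lhead="cluster_{t.target}"')
        out.append(f'  "{anchor(t.source)}" -> "{anchor(t.target)}" [{", ".join(attrs)}];')
    out.append("}")
    return "\n".join(out) + "\n"


def _export_dot_automaton(auto: FlatAutomaton) -> str:
    out: list[str] = []
    out.append(f'digraph "{_dot_escape(auto.name)}" {{')
    out.append("  rankdir=LR;")
    out.append("  node [shape=circle];")
    for sid in sorted(auto.states):
        fs = auto.states[sid]
        attrs = [f'label="{_dot_escape(fs.label or sid)}"']
        if fs.marked:
            attrs.append("shape=doublecircle")
        out.append(f'  "{sid}" [{", ".join(attrs)}];')
    out.append('  "__initial" [shape=point, label=""];')
    out.append(f'  "__initial" -> "{auto.initial}";')
    for (e, src) in sorted(auto.transition_map):
        for dst in sorted(auto.transition_map[(e, src)]):
            out.append(f'  "{src}" -> "{dst}" [label="{_dot_escape(e)}"];')
    out.append("}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# SCXML export
# ---------------------------------------------------------------------------

_SCXML_NS = "http://www.w3.org/2005/07/scxml"


def _cond_expr(guard: Guard) -> str:
    return " && ".join(cid if val else f"!{cid}" for cid, val in guard.literals)


def export_scxml(chart: Statechart) -> str:
    """Export to SCXML: XOR composites become nested ``<state>`` elements
    with an ``initial`` attribute, AND composites become ``<parallel>``,
    guards become ``cond`` expressions, condition actions become
    ``<assign>`` in ``<onentry>`` or inside the transition."""
    root_node = chart.states[chart.root]
    scxml = ET.Element(
        "scxml",
        {
            "xmlns": _SCXML_NS,
            "version": "1.0",
            "datamodel": "ecmascript",
            "initial": root_node.default_child or chart.initial_state,
        },
    )
    if chart.conditions:
        dm = ET.SubElement(scxml, "datamodel")
        for cid in sorted(chart.conditions):
            c = chart.conditions[cid]
            ET.SubElement(dm, "data", {"id": cid, "expr": "true" if c.initial_value else "false"})

    transitions_by_source: dict[str, list[Transition]] = {}
    for tid in sorted(chart.transitions):
        t = chart.transitions[tid]
        transitions_by_source.setdefault(t.source, []).append(t)

    def emit(parent: ET.Element, sid: str) -> None:
        node = chart.states[sid]
        if node.kind is StateKind.AND:
            el = ET.SubElement(parent, "parallel", {"id": sid})
        else:
            attrs = {"id": sid}
            if node.kind is StateKind.XOR and node.default_child:
                attrs["initial"] = node.default_child
            el = ET.SubElement(parent, "state", attrs)
        if node.entry_actions:
            onentry = ET.SubElement(el, "onentry")
            for a in node.entry_actions:
                ET.SubElement(
                    onentry,
                    "assign",
                    {"location": a.condition, "expr": "true" if a.value else "false"},
                )
        for t in transitions_by_source.get(sid, []):
            attrs = {"event": t.event}
            if t.guard.literals:
                attrs["cond"] = _cond_expr(t.guard)
            attrs["target"] = t.target
            tr = ET.SubElement(el, "transition", attrs)
            for a in t.actions:
                ET.SubElement(
                    tr,
                    "assign",
                    {"location": a.condition, "expr": "true" if a.value else "false"},
                )
        for c in node.children:
            emit(el, c)

    for c in root_node.children:
        emit(scxml, c)

    ET.indent(scxml, space="  ")
    body = ET.tostring(scxml, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


# ---------------------------------------------------------------------------
# flat automaton JSON
# ---------------------------------------------------------------------------

def write_automaton(auto: FlatAutomaton) -> str:
    """Serialize a flat automaton (states annotated with the
    configuration/valuation they denote, when produced by flattening)."""
    doc = {
        "name": auto.name,
        "events": sorted(auto.events),
        "initial": auto.initial,
        "marked": sorted(auto.marked),
        "states": [
            {
                "id": sid,
                "label": auto.states[sid].label,
                "marked": auto.states[sid].marked,
            }
            for sid in sorted(auto.states)
        ],
        "transitions": [
            {"from": src, "event": e, "to": sorted(auto.transition_map[(e, src)])}
            for (e, src) in sorted(auto.transition_map)
        ],
    }
    return json.dumps(doc, indent=2) + "\n"
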