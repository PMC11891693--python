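"""Statechart data model and structural validation.

A statechart here is a hierarchical nondeterministic automaton in the
Harel tradition, restricted to the constructs clinical-guideline models
actually use: basic states, XOR superstates (exactly one child active),
AND superstates (orthogonal regions active concurrently), boolean
condition symbols, and transitions guarded by conjunctions of condition
literals.  Events are clinical indicators (a vital sign, symptom or
patient characteristic observed by a professional); conditions carry
persistent facts such as "the neonate has not been clamped".

Everything downstream (interpretation, flattening, verification,
serialization) works against the types defined in this module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Criticality",
    "ActionTiming",
    "EventSymbol",
    "ConditionSymbol",
    "Guard",
    "ConditionAction",
    "StateKind",
    "StateNode",
    "Transition",
    "Statechart",
    "Finding",
    "ValidationReport",
    "StatechartError",
    "UnknownReferenceError",
    "TreeViolationError",
    "CompositeArityError",
    "build_statechart",
    "validate",
]


class StatechartError(ValueError):
    """Base class for structural model errors."""


class UnknownReferenceError(StatechartError):
    """An id is referenced but never declared."""


class TreeViolationError(StatechartError):
    """The state hierarchy is not a tree (e.g. a node with two parents)."""


class CompositeArityError(StatechartError):
    """A composite state violates its arity rules."""


class Criticality(str, enum.Enum):
    """Clinical severity classes rendered as fill colors.

    ``normal`` (gray) — normal condition or diagnosis; ``intervention``
    (orange) — requires medical intervention or careful monitoring;
    ``critical`` (magenta) — critical situation (invasive support);
    ``positive`` (green) — positive adaptation, clamping may proceed.
    """

    NORMAL = "normal"
    INTERVENTION = "intervention"
    CRITICAL = "critical"
    POSITIVE = "positive"


class StateKind(str, enum.Enum):
    BASIC = "basic"
    XOR = "xor_composite"
    AND = "and_composite"


class ActionTiming(str, enum.Enum):
    ON_ENTRY = "on_entry"
    ON_FIRING = "on_firing"


@dataclass(frozen=True)
class EventSymbol:
    """One symbol of the event alphabet; ``id`` is a stable machine label,
    ``description`` the clinical-indicator text."""

    id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise StatechartError(f"event id must be nonempty without whitespace: {self.id!r}")


@dataclass(frozen=True)
class ConditionSymbol:
    """A boolean condition (e.g. NNC = neonate not clamped) with its
    declared initial value."""

    id: str
    description: str = ""
    initial_value: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise StatechartError(f"condition id must be nonempty without whitespace: {self.id!r}")


@dataclass(frozen=True)
class Guard:
    """Conjunction of condition literals; the empty guard is always true.

    ``literals`` maps condition id -> required boolean value.
    """

    literals: tuple[tuple[str, bool], ...] = ()

    @staticmethod
    def of(**required: bool) -> "Guard":
        return Guard(tuple(sorted(required.items())))

    def __post_init__(self) -> None:
        seen: dict[str, bool] = {}
        for cid, val in self.literals:
            if cid in seen and seen[cid] != val:
                raise StatechartError(f"guard requires condition {cid!r} with both values")
            seen[cid] = val
        # canonical order so equal guards compare equal
        object.__setattr__(self, "literals", tuple(sorted(set(self.literals))))

    @property
    def condition_ids(self) -> frozenset[str]:
        return frozenset(cid for cid, _ in self.literals)

    def satisfied(self, env: Mapping[str, bool]) -> bool:
        return all(env[cid] == val for cid, val in self.literals)

    def __str__(self) -> str:  # e.g. "NNC & !A1"
        if not self.literals:
            return "true"
        return " & ".join(cid if val else f"!{cid}" for cid, val in self.literals)


@dataclass(frozen=True)
class ConditionAction:
    """Assignment of a boolean value to a condition, either when a state
    is entered or when a transition fires."""

    condition: str
    value: bool
    timing: ActionTiming = ActionTiming.ON_FIRING


@dataclass
class StateNode:
    """One node of the state hierarchy.

    ``id`` is a short stable key; ``clinical_label`` holds the prose
    description so reports are self-documenting.  ``children`` is the
    ordered list of child ids (empty iff basic); an XOR composite names
    its ``default_child``; AND composites' children are the orthogonal
    regions (themselves composite).
    """

    id: str
    clinical_label: str = ""
    kind: StateKind = StateKind.BASIC
    children: list[str] = field(default_factory=list)
    default_child: Optional[str] = None
    marked: bool = False
    criticality: Criticality = Criticality.NORMAL
    entry_actions: list[ConditionAction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise StatechartError(f"state id must be nonempty without whitespace: {self.id!r}")
        self.kind = StateKind(self.kind)
        self.criticality = Criticality(self.criticality)

    @property
    def is_basic(self) -> bool:
        return self.kind is StateKind.BASIC

    @property
    def is_composite(self) -> bool:
        return self.kind is not StateKind.BASIC


@dataclass
class Transition:
    """A guarded transition.  Source and target may be basic states or
    composites (a composite source means "from any active descendant")."""

    id: str
    source: str
    target: str
    event: str
    guard: Guard = Guard()
    actions: list[ConditionAction] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.actions:
            if a.timing is not ActionTiming.ON_FIRING:
                raise StatechartError(
                    f"transition {self.id!r}: transition actions must have on_firing timing"
                )


@dataclass
class Statechart:
    """The full hierarchical model: state tree, alphabet, conditions,
    guarded transitions and the initial basic state."""

    name: str
    root: str
    states: dict[str, StateNode]
    events: dict[str, EventSymbol]
    conditions: dict[str, ConditionSymbol]
    transitions: dict[str, Transition]
    initial_state: str
    _parent: dict[str, Optional[str]] = field(default_factory=dict, repr=False, compare=False)

    # -- hierarchy helpers used throughout semantics/flatten/verify --

    def parent(self, sid: str) -> Optional[str]:
        return self._parent[sid]

    def ancestors(self, sid: str) -> list[str]:
        """Strict ancestors, nearest first."""
        out = []
        p = self._parent[sid]
        while p is not None:
            out.append(p)
            p = self._parent[p]
        return out

    def path_from_root(self, sid: str) -> list[str]:
        return list(reversed(self.ancestors(sid))) + [sid]

    def descendants(self, sid: str) -> set[str]:
        """Strict descendants."""
        out: set[str] = set()
        stack = list(self.states[sid].children)
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self.states[c].children)
        return out

    def subtree(self, sid: str) -> set[str]:
        return {sid} | self.descendants(sid)

    def lca(self, a: str, b: str) -> str:
        pa = self.path_from_root(a)
        pb = set(self.path_from_root(b))
        last = self.root
        for node in pa:
            if node in pb:
                last = node
            else:
                break
        return last

    def is_ancestor(self, anc: str, sid: str) -> bool:
        """True iff ``anc`` is a strict ancestor of ``sid``."""
        return anc in self.ancestors(sid)

    def basic_states(self) -> list[str]:
        return [sid for sid, s in self.states.items() if s.is_basic]

    def composite_states(self, include_root: bool = False) -> list[str]:
        out = [sid for sid, s in self.states.items() if s.is_composite]
        if not include_root:
            out = [sid for sid in out if sid != self.root]
        return out

    def default_completion_path(self) -> list[str]:
        """Chain of default children from the root (XOR defaults only)."""
        path = [self.root]
        node = self.states[self.root]
        while node.kind is StateKind.XOR:
            nxt = node.default_child
            assert nxt is not None
            path.append(nxt)
            node = self.states[nxt]
        return path


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    ids: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _as_state(obj) -> StateNode:
    if isinstance(obj, StateNode):
        return obj
    return StateNode(**obj)


def _as_event(obj) -> EventSymbol:
    if isinstance(obj, EventSymbol):
        return obj
    return EventSymbol(**obj)


def _as_condition(obj) -> ConditionSymbol:
    if isinstance(obj, ConditionSymbol):
        return obj
    return ConditionSymbol(**obj)


def _as_transition(obj) -> Transition:
    if isinstance(obj, Transition):
        return obj
    obj = dict(obj)
    guard = obj.get("guard", Guard())
    if isinstance(guard, Mapping):
        guard = Guard(tuple(sorted((k, bool(v)) for k, v in guard.items())))
    obj["guard"] = guard
    actions = [
        a if isinstance(a, ConditionAction) else ConditionAction(**a)
        for a in obj.get("actions", [])
    ]
    obj["actions"] = actions
    return Transition(**obj)


def build_statechart(
    *,
    name: str,
    root: str,
    states: Iterable,
    events: Iterable = (),
    conditions: Iterable = (),
    transitions: Iterable = (),
    initial_state: str,
) -> Statechart:
    """Construct and structurally check a :class:`Statechart`.

    Accepts :class:`StateNode`/... instances or plain mappings with the
    same fields.  Raises :class:`UnknownReferenceError`,
    :class:`TreeViolationError` or :class:`CompositeArityError` on
    structural violations; softer issues are reported by :func:`validate`.
    """
    state_list = [_as_state(s) for s in states]
    state_map: dict[str, StateNode] = {}
    for s in state_list:
        if s.id in state_map:
            raise TreeViolationError(f"duplicate state id {s.id!r}")
        state_map[s.id] = s

    chart = Statechart(
        name=name,
        root=root,
        states=state_map,
        events={e.id: e for e in map(_as_event, events)},
        conditions={c.id: c for c in map(_as_condition, conditions)},
        transitions={t.id: t for t in map(_as_transition, transitions)},
        initial_state=initial_state,
    )
    _check_structure(chart)
    return chart


def _check_structure(chart: Statechart) -> None:
    """Hard structural invariants; raises on violation and fills the
    parent index as a side effect."""
    states = chart.states
    if chart.root not in states:
        raise UnknownReferenceError(f"root state {chart.root!r} is not declared")

    # alphabet disjointness
    clash = set(chart.events) & set(chart.conditions)
    if clash:
        raise StatechartError(f"ids used as both event and condition: {sorted(clash)}")

    # parent index + tree check
    parent: dict[str, Optional[str]] = {sid: None for sid in states}
    for sid, s in states.items():
        for c in s.children:
            if c not in states:
                raise UnknownReferenceError(f"state {sid!r} lists undeclared child {c!r}")
            if parent[c] is not None:
                raise TreeViolationError(f"state {c!r} has two parents: {parent[c]!r} and {sid!r}")
            if c == chart.root:
                raise TreeViolationError("root cannot be a child")
            parent[c] = sid
    orphans = [sid for sid, p in parent.items() if p is None and sid != chart.root]
    if orphans:
        raise TreeViolationError(f"states not connected to root: {sorted(orphans)}")
    chart._parent = parent

    # composite arity + defaults
    for sid, s in states.items():
        if s.kind is StateKind.BASIC:
            if s.children:
                raise CompositeArityError(f"basic state {sid!r} has children")
            if s.default_child is not None:
                raise CompositeArityError(f"basic state {sid!r} has a default child")
        elif s.kind is StateKind.XOR:
            if len(s.children) < 2:
                raise CompositeArityError(f"xor composite {sid!r} needs >=2 children")
            if s.default_child not in s.children:
                raise CompositeArityError(
                    f"xor composite {sid!r}: default child {s.default_child!r} not among children"
                )
        else:  # AND
            if len(s.children) < 2:
                raise CompositeArityError(f"and composite {sid!r} needs >=2 regions")
            for c in s.children:
                if not states[c].is_composite:
                    raise CompositeArityError(
                        f"and composite {sid!r}: region {c!r} must itself be composite"
                    )

    # cross references
    if chart.initial_state not in states:
        raise UnknownReferenceError(f"initial state {chart.initial_state!r} is not declared")
    if not states[chart.initial_state].is_basic:
        raise CompositeArityError(f"initial state {chart.initial_state!r} must be basic")
    for t in chart.transitions.values():
        for endpoint, role in ((t.source, "source"), (t.target, "target")):
            if endpoint not in states:
                raise UnknownReferenceError(
                    f"transition {t.id!r}: {role} {endpoint!r} is not declared"
                )
        if t.event not in chart.events:
            raise UnknownReferenceError(f"transition {t.id!r}: event {t.event!r} is not declared")
        for cid in t.guard.condition_ids:
            if cid not in chart.conditions:
                raise UnknownReferenceError(
                    f"transition {t.id!r}: guard condition {cid!r} is not declared"
                )
        for a in t.actions:
            if a.condition not in chart.conditions:
                raise UnknownReferenceError(
                    f"transition {t.id!r}: action condition {a.condition!r} is not declared"
                )
    for sid, s in states.items():
        for a in s.entry_actions:
            if a.condition not in chart.conditions:
                raise UnknownReferenceError(
                    f"state {sid!r}: entry action condition {a.condition!r} is not declared"
                )
            if a.timing is not ActionTiming.ON_ENTRY:
                raise StatechartError(f"state {sid!r}: entry actions must have on_entry timing")


# ---------------------------------------------------------------------------
# validation (soft: returns a report, never raises)
# ---------------------------------------------------------------------------

def validate(chart: Statechart) -> ValidationReport:
    """Full invariant audit of an already-constructed chart.

    Errors mirror the constructor's checks (so charts mutated after
    construction are re-checkable); warnings cover stylistic issues such
    as declared-but-unused symbols.
    """
    report = ValidationReport()

    def err(code: str, msg: str, *ids: str) -> None:
        report.findings.append(Finding("error", code, msg, tuple(ids)))

    def warn(code: str, msg: str, *ids: str) -> None:
        report.findings.append(Finding("warning", code, msg, tuple(ids)))

    try:
        _check_structure(chart)
    except CompositeArityError as e:
        err("composite-arity", str(e))
        return report
    except TreeViolationError as e:
        err("tree-violation", str(e))
        return report
    except UnknownReferenceError as e:
        err("unknown-reference", str(e))
        return report
    except StatechartError as e:
        err("structural", str(e))
        return report

    # initial state reachable along default children from the root
    path = chart.default_completion_path()
    if path[-1] != chart.initial_state and chart.initial_state not in path:
        err(
            "initial-not-default",
            f"initial state {chart.initial_state!r} is not on the default-child chain from root",
            chart.initial_state,
        )

    # duplicate transition definitions; transitions sharing (source,
    # event, guard) are legitimate only as concurrent entry into
    # distinct orthogonal regions of the same AND composite
    def region_pairs(sid: str) -> set[tuple[str, str]]:
        path = chart.path_from_root(sid)
        return {
            (path[i], path[i + 1])
            for i in range(len(path) - 1)
            if chart.states[path[i]].kind is StateKind.AND
        }

    def concurrent_entry_pair(a: Transition, b: Transition) -> bool:
        if a.target == b.target:
            return False
        ra, rb = region_pairs(a.target), region_pairs(b.target)
        return any(
            p1 == p2 and r1 != r2 for p1, r1 in ra for p2, r2 in rb
        )

    seen: dict[tuple, list[Transition]] = {}
    for t in chart.transitions.values():
        seen.setdefault((t.source, t.event, t.guard.literals), []).append(t)
    for group in seen.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if not concurrent_entry_pair(a, b):
                    err(
                        "duplicate-transition",
                        f"transitions {a.id!r} and {b.id!r} share (source, event, guard)",
                        a.id,
                        b.id,
                    )

    used_events = {t.event for t in chart.transitions.values()}
    for eid in chart.events:
        if eid not in used_events:
            warn("unused-event", f"event {eid!r} declared but never used", eid)
    used_conditions = {cid for t in chart.transitions.values() for cid in t.guard.condition_ids}
    used_conditions |= {a.condition for t in chart.transitions.values() for a in t.actions}
    used_conditions |= {a.condition for s in chart.states.values() for a in s.entry_actions}
    for cid in chart.conditions:
        if cid not in used_conditions:
            warn("unused-condition", f"condition {cid!r} declared but never used", cid)

    return report
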