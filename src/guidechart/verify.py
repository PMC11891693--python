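"""Model-quality checks for clinical statecharts.

These operationalize the soundness properties a guideline encoding
should have: every clinically meaningful state is reachable, critical
junctures (marked states) have replayable witness scenarios, no
unintended nondeterminism lurks in the reachable space, and
irreversible facts (like cord clamping) are monotone.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .core_model import Statechart, UnknownReferenceError
from .flatten import DEFAULT_STATE_CAP, FlatAutomaton, flatten
from .semantics import Configuration, fire_sets

__all__ = [
    "ReachabilityReport",
    "NondeterminismEntry",
    "MonotoneConditionReport",
    "EventCoverageReport",
    "reachability",
    "nondeterminism_report",
    "check_monotone_condition",
    "event_coverage",
]

_DIRECTIONS = {"true->false": (True, False), "false->true": (False, True)}


@dataclass
class ReachabilityReport:
    reachable: frozenset[str]
    unreachable: frozenset[str]
    sink_states: frozenset[str]
    marked_reachable: dict[str, list[str]]  # marked state id -> shortest witness events
    marked_unreachable: frozenset[str] = frozenset()

    def witness(self, sid: str) -> Optional[list[str]]:
        return self.marked_reachable.get(sid)


@dataclass(frozen=True)
class NondeterminismEntry:
    state: str  # readable flat-state label
    event: str
    transitions: tuple[str, ...]  # conflicting transition ids


@dataclass
class MonotoneConditionReport:
    condition: str
    direction: str
    monotone: bool
    violations: list[str] = field(default_factory=list)  # transition/state ids (static scan)
    dynamic_violations: list[tuple[str, str]] = field(default_factory=list)  # (state label, event)


@dataclass
class EventCoverageReport:
    gaps: dict[str, frozenset[str]]  # reachable basic state -> events never firable there
    everywhere_ignored: frozenset[str]  # events with no firable occurrence anywhere


def _shortest_witnesses(chart: Statechart, auto: FlatAutomaton) -> dict[str, list[str]]:
    """BFS over the flat automaton with events in sorted order
    (lexicographic tie-break), returning for each flat state the first
    event sequence reaching it."""
    seq: dict[str, list[str]] = {auto.initial: []}
    queue = deque([auto.initial])
    while queue:
        q = queue.popleft()
        for e in auto.defined_events(q):
            for nxt in sorted(auto.successors(q, e)):
                if nxt not in seq:
                    seq[nxt] = seq[q] + [e]
                    queue.append(nxt)
    return seq


def reachability(chart: Statechart, cap: int = DEFAULT_STATE_CAP) -> ReachabilityReport:
    """Reachable/unreachable basic states, sinks, and shortest witness
    event sequences for every reachable marked state node.

    Witnesses replay through the interpreter (``semantics.run_trace``)
    to a configuration activating the marked state.
    """
    auto = flatten(chart, cap=cap)
    witnesses = _shortest_witnesses(chart, auto)

    def actives(fid: str) -> frozenset[str]:
        ann = auto.states[fid].annotation
        assert ann is not None
        return ann[0]

    basics = set(chart.basic_states())
    reachable: set[str] = set()
    containing: dict[str, list[str]] = {}
    for fid in auto.states:
        for sid in actives(fid):
            if sid in basics:
                reachable.add(sid)
                containing.setdefault(sid, []).append(fid)

    dead_flat = {fid for fid in auto.states if not auto.defined_events(fid)}
    sinks = frozenset(
        s for s in reachable if all(fid in dead_flat for fid in containing[s])
    )

    marked_nodes = {sid for sid, s in chart.states.items() if s.marked}
    marked_reachable: dict[str, list[str]] = {}
    for m in sorted(marked_nodes):
        best: Optional[list[str]] = None
        for fid in auto.states:
            if m in actives(fid):
                w = witnesses[fid]
                if best is None or (len(w), w) < (len(best), best):
                    best = w
        if best is not None:
            marked_reachable[m] = best

    return ReachabilityReport(
        reachable=frozenset(reachable),
        unreachable=frozenset(basics - reachable),
        sink_states=sinks,
        marked_reachable=marked_reachable,
        marked_unreachable=frozenset(marked_nodes - set(marked_reachable)),
    )


def nondeterminism_report(
    chart: Statechart, cap: int = DEFAULT_STATE_CAP
) -> list[NondeterminismEntry]:
    """Reachable (flat state, event) pairs where two or more enabled
    transitions conflict (alternative fire-sets exist)."""
    auto = flatten(chart, cap=cap)
    entries: list[NondeterminismEntry] = []
    for fid in sorted(auto.states, key=lambda s: int(s[1:]) if s[1:].isdigit() else 0):
        ann = auto.states[fid].annotation
        assert ann is not None
        config = Configuration(ann[0])
        env = dict(ann[1])
        for e in sorted(chart.events):
            sets = fire_sets(chart, config, e, env)
            if len(sets) > 1:
                conflicting = tuple(sorted({tid for s in sets for tid in s}))
                entries.append(NondeterminismEntry(auto.states[fid].label, e, conflicting))
    return entries


def check_monotone_condition(
    chart: Statechart,
    condition: str,
    direction: str = "true->false",
    cap: int = DEFAULT_STATE_CAP,
) -> MonotoneConditionReport:
    """Is ``condition`` monotone in ``direction``?

    Static scan: any transition or entry action assigning the condition
    against the direction is a violation (even if unreachable — a latent
    encoding error).  Dynamic confirmation: no edge of the reachable
    flat space moves the condition's value against the direction.
    Monotone iff both scans are clean.
    """
    if condition not in chart.conditions:
        raise UnknownReferenceError(f"condition {condition!r} is not declared")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")
    _, allowed_target = _DIRECTIONS[direction]
    forbidden_value = not allowed_target

    violations: list[str] = []
    for t in sorted(chart.transitions.values(), key=lambda t: t.id):
        for a in t.actions:
            if a.condition == condition and a.value == forbidden_value:
                violations.append(t.id)
    for sid in sorted(chart.states):
        for a in chart.states[sid].entry_actions:
            if a.condition == condition and a.value == forbidden_value:
                violations.append(sid)

    dynamic: list[tuple[str, str]] = []
    auto = flatten(chart, cap=cap)

    def value_at(fid: str) -> bool:
        ann = auto.states[fid].annotation
        assert ann is not None
        return dict(ann[1])[condition]

    for (e, src), targets in sorted(auto.transition_map.items()):
        for dst in sorted(targets):
            if value_at(src) != value_at(dst) and value_at(dst) == forbidden_value:
                dynamic.append((auto.states[src].label, e))
                break

    return MonotoneConditionReport(
        condition=condition,
        direction=direction,
        monotone=not violations and not dynamic,
        violations=violations,
        dynamic_violations=dynamic,
    )


def event_coverage(chart: Statechart, cap: int = DEFAULT_STATE_CAP) -> EventCoverageReport:
    """For each reachable basic state, the events that can never fire
    while it is active; events everywhere-ignored are flagged chart-wide
    (a completeness audit for guideline review)."""
    auto = flatten(chart, cap=cap)
    basics = set(chart.basic_states())
    firable: dict[str, set[str]] = {}
    present: set[str] = set()
    for fid, fs in auto.states.items():
        ann = fs.annotation
        assert ann is not None
        defined = set(auto.defined_events(fid))
        for sid in ann[0]:
            if sid in basics:
                present.add(sid)
                firable.setdefault(sid, set()).update(defined)
    alphabet = set(chart.events)
    gaps = {
        sid: frozenset(alphabet - firable.get(sid, set()))
        for sid in sorted(present)
    }
    fired_anywhere = {e for (e, _q) in auto.transition_map}
    return EventCoverageReport(
        gaps=gaps, everywhere_ignored=frozenset(alphabet - fired_anywhere)
    )
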