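"""Execution semantics for hierarchical statecharts.

A *configuration* is the set of simultaneously active states (basic
states plus all their ancestors).  One external event produces one
macro-step: the set of enabled transitions is resolved into *fire-sets*
(maximal sets of pairwise-compatible transitions), the sources' subtrees
are exited, the targets entered via default completion, and condition
actions applied.  There is no internal event broadcasting — clinical
indicators arrive one at a time from outside.

Concurrency and nondeterminism
------------------------------
Two enabled transitions may fire together when they are *orthogonal*
(their exited subtrees are disjoint and their targets do not compete for
the same XOR region) or when they realize the concurrent-entry idiom:
same source, targets in distinct regions of the same AND composite.
Any other overlap is a genuine nondeterministic conflict: ``step``
resolves it deterministically (lexicographically smallest fire-set) or
raises in strict mode, while ``step_all`` enumerates every alternative
(this is what flattening and verification explore).

Entering an AND composite activates only the regions that fired
transitions target; untargeted regions stay inactive until explicitly
entered.  Entry that targets the composite itself (including initial
entry) activates every region at its defaults, which guarantees the
activation of at least one inner state in all cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx

from .core_model import (
    StateKind,
    Statechart,
    StatechartError,
    Transition,
    UnknownReferenceError,
)

__all__ = [
    "Configuration",
    "StepResult",
    "NondeterminismError",
    "TraceError",
    "initial_environment",
    "initial_configuration",
    "enabled_transitions",
    "fire_sets",
    "step",
    "step_all",
    "run_trace",
    "is_marked",
    "check_configuration",
]

logger = logging.getLogger(__name__)


class NondeterminismError(StatechartError):
    """Raised in strict mode when conflicting transitions are enabled."""

    def __init__(self, message: str, conflicting: Sequence[str] = ()):
        super().__init__(message)
        self.conflicting = tuple(conflicting)


class TraceError(StatechartError):
    """A trace item failed; carries the zero-based failing index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"trace item {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class Configuration:
    """Set of simultaneously active state ids, closed under ancestry."""

    active: frozenset[str]

    def __contains__(self, sid: str) -> bool:
        return sid in self.active

    def basic_active(self, chart: Statechart) -> frozenset[str]:
        return frozenset(s for s in self.active if chart.states[s].is_basic)

    def label(self, chart: Statechart) -> str:
        return "{" + ",".join(sorted(self.basic_active(chart))) + "}"


@dataclass
class StepResult:
    configuration: Configuration
    environment: dict[str, bool]
    fired: list[str] = field(default_factory=list)
    ignored: bool = False


def initial_environment(
    chart: Statechart, overrides: Optional[Mapping[str, bool]] = None
) -> dict[str, bool]:
    env = {cid: c.initial_value for cid, c in chart.conditions.items()}
    for cid, val in (overrides or {}).items():
        if cid not in env:
            raise UnknownReferenceError(f"condition {cid!r} is not declared")
        env[cid] = bool(val)
    return env


def check_configuration(chart: Statechart, active: frozenset[str]) -> None:
    """Raise if ``active`` violates XOR/AND consistency."""
    if chart.root not in active:
        raise StatechartError("root is not active")
    for sid in active:
        node = chart.states[sid]
        p = chart.parent(sid)
        if p is not None and p not in active:
            raise StatechartError(f"active state {sid!r} has inactive parent {p!r}")
        if node.kind is StateKind.XOR:
            n = sum(1 for c in node.children if c in active)
            if n != 1:
                raise StatechartError(
                    f"xor composite {sid!r} is active with {n} active children"
                )
        elif node.kind is StateKind.AND:
            n = sum(1 for c in node.children if c in active)
            if n < 1:
                raise StatechartError(f"and composite {sid!r} is active with no active region")


# ---------------------------------------------------------------------------
# entry / exit machinery
# ---------------------------------------------------------------------------

def _complete_down(chart: Statechart, active: set[str], sid: str, entered: list[str]) -> None:
    """Default completion below an explicitly entered node: XOR picks its
    default child, AND (direct entry) activates every region."""
    node = chart.states[sid]
    if node.kind is StateKind.XOR:
        if not any(c in active for c in node.children):
            c = node.default_child
            assert c is not None
            active.add(c)
            entered.append(c)
            _complete_down(chart, active, c, entered)
    elif node.kind is StateKind.AND:
        for c in node.children:
            if c not in active:
                active.add(c)
                entered.append(c)
                _complete_down(chart, active, c, entered)


def _enter_target(chart: Statechart, active: set[str], target: str, entered: list[str]) -> None:
    """Activate ``target`` and its inactive ancestors, then complete
    downward.  Newly activated AND ancestors get only the region on the
    path (region-targeted entry); XOR ancestors get only the path child.
    An already-active XOR ancestor holding a different child (e.g. a
    cross-region transition) has that child's subtree exited first."""
    path = chart.path_from_root(target)
    for i, node in enumerate(path):
        if node in active:
            nxt = path[i + 1] if i + 1 < len(path) else None
            state = chart.states[node]
            if nxt is not None and state.kind is StateKind.XOR:
                for c in state.children:
                    if c != nxt and c in active:
                        active.difference_update(chart.subtree(c))
        else:
            active.add(node)
            entered.append(node)
    _complete_down(chart, active, target, entered)


def _exit_root(chart: Statechart, t: Transition) -> str:
    """Highest state exited when ``t`` fires: the child of the
    source/target LCA on the source side (the whole source subtree for
    self-loops and transitions into the source's own subtree)."""
    if t.source == t.target:
        return t.source
    l = chart.lca(t.source, t.target)
    if l == t.source:
        return t.source
    path = chart.path_from_root(t.source)
    return path[path.index(l) + 1]


def initial_configuration(chart: Statechart) -> tuple[Configuration, dict[str, bool]]:
    """Default entry from the root.

    Follows default children through XOR composites and activates every
    region of AND composites, applying entry actions of entered states to
    the declared initial condition values.  The chart's declared
    ``initial_state`` is contained in the result for valid charts.
    """
    active: set[str] = {chart.root}
    entered: list[str] = [chart.root]
    _complete_down(chart, active, chart.root, entered)
    env = initial_environment(chart)
    for sid in entered:
        for a in chart.states[sid].entry_actions:
            env[a.condition] = a.value
    config = Configuration(frozenset(active))
    check_configuration(chart, config.active)
    return config, env


# ---------------------------------------------------------------------------
# enabledness, conflicts and fire-sets
# ---------------------------------------------------------------------------

def enabled_transitions(
    chart: Statechart,
    config: Configuration,
    event: str,
    env: Mapping[str, bool],
    strict: bool = False,
) -> list[Transition]:
    """Transitions enabled for ``event`` in ``config`` under ``env``,
    after inner-priority resolution (a descendant-level transition
    pre-empts a conflicting ancestor-level one).

    In strict mode raises :class:`NondeterminismError` if the surviving
    set still contains a same-region conflict.
    """
    if event not in chart.events:
        raise UnknownReferenceError(f"event {event!r} is not declared")
    raw = [
        t
        for t in chart.transitions.values()
        if t.event == event and t.source in config.active and t.guard.satisfied(env)
    ]
    survivors = []
    for t in raw:
        preempted = any(
            t2 is not t
            and chart.is_ancestor(t.source, t2.source)
            and not _compatible(chart, t, t2)
            for t2 in raw
        )
        if not preempted:
            survivors.append(t)
    if strict:
        sets = _maximal_fire_sets(chart, survivors)
        if len(sets) > 1:
            conflicting = sorted({t.id for s in sets for t in s})
            raise NondeterminismError(
                f"conflicting transitions enabled on event {event!r}: {conflicting}",
                conflicting,
            )
    return sorted(survivors, key=lambda t: t.id)


def _and_region_of(chart: Statechart, sid: str) -> list[tuple[str, str]]:
    """(AND composite, region) pairs such that ``sid`` lies inside that
    region, innermost first."""
    out = []
    path = chart.path_from_root(sid)
    for i in range(len(path) - 1):
        if chart.states[path[i]].kind is StateKind.AND:
            out.append((path[i], path[i + 1]))
    return list(reversed(out))


def _entry_compatible(chart: Statechart, t1: Transition, t2: Transition) -> bool:
    """Targets may be activated together: their root-paths either nest or
    diverge below an AND composite (distinct orthogonal regions)."""
    p1 = chart.path_from_root(t1.target)
    p2 = chart.path_from_root(t2.target)
    for a, b in zip(p1, p2):
        if a != b:
            # diverged; the common prefix ends at the parent of a/b
            parent = chart.parent(a)
            assert parent == chart.parent(b)
            return chart.states[parent].kind is StateKind.AND
    return True  # one path is a prefix of the other


def _compatible(chart: Statechart, t1: Transition, t2: Transition) -> bool:
    """May ``t1`` and ``t2`` fire in the same macro-step?"""
    e1 = chart.subtree(_exit_root(chart, t1))
    e2 = chart.subtree(_exit_root(chart, t2))
    if e1.isdisjoint(e2):
        return _entry_compatible(chart, t1, t2)
    # concurrent-entry idiom: same source, targets in distinct regions of
    # the same AND composite (e.g. one indicator starting ventilatory
    # assistance and the minute-evaluation clock at once)
    if t1.source == t2.source and _entry_compatible(chart, t1, t2):
        r1 = {(p, r) for p, r in _and_region_of(chart, t1.target)}
        r2 = {(p, r) for p, r in _and_region_of(chart, t2.target)}
        for p, r in r1:
            if any(p2 == p and rr != r for p2, rr in r2):
                return True
    return False


def _maximal_fire_sets(
    chart: Statechart, enabled: Sequence[Transition]
) -> list[tuple[Transition, ...]]:
    """Maximal sets of pairwise-compatible enabled transitions, sorted
    lexicographically by transition ids (deterministic)."""
    if not enabled:
        return []
    g = nx.Graph()
    g.add_nodes_from(t.id for t in enabled)
    by_id = {t.id: t for t in enabled}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if _compatible(chart, by_id[a], by_id[b]):
                g.add_edge(a, b)
    cliques = sorted({tuple(sorted(c)) for c in nx.find_cliques(g)})
    return [tuple(by_id[i] for i in c) for c in cliques]


def fire_sets(
    chart: Statechart,
    config: Configuration,
    event: str,
    env: Mapping[str, bool],
) -> list[tuple[str, ...]]:
    """All alternative maximal fire-sets (tuples of transition ids) for
    one event; more than one element signals nondeterministic conflict."""
    enabled = enabled_transitions(chart, config, event, env)
    return [tuple(t.id for t in s) for s in _maximal_fire_sets(chart, enabled)]


def _fire(
    chart: Statechart,
    config: Configuration,
    env: Mapping[str, bool],
    transitions: Sequence[Transition],
) -> StepResult:
    """Execute one fire-set: exit sources, apply transition actions (in
    transition-id order), enter targets, apply entry actions."""
    exits: set[str] = set()
    for t in transitions:
        exits |= chart.subtree(_exit_root(chart, t))
    active = set(config.active) - exits
    new_env = dict(env)
    ordered = sorted(transitions, key=lambda t: t.id)
    for t in ordered:
        for a in t.actions:
            new_env[a.condition] = a.value
    entered: list[str] = []
    for t in ordered:
        _enter_target(chart, active, t.target, entered)
    for sid in entered:
        for a in chart.states[sid].entry_actions:
            new_env[a.condition] = a.value
    result = Configuration(frozenset(active))
    check_configuration(chart, result.active)
    return StepResult(result, new_env, [t.id for t in ordered], ignored=False)


def step_all(
    chart: Statechart,
    config: Configuration,
    event: str,
    env: Mapping[str, bool],
) -> list[StepResult]:
    """Every alternative macro-step for ``event`` (one per maximal
    fire-set, duplicates by outcome removed).  A single ``ignored``
    result is returned when nothing is enabled."""
    enabled = enabled_transitions(chart, config, event, env)
    sets = _maximal_fire_sets(chart, enabled)
    if not sets:
        return [StepResult(config, dict(env), [], ignored=True)]
    results: list[StepResult] = []
    seen: set[tuple] = set()
    for s in sets:
        r = _fire(chart, config, env, s)
        key = (r.configuration.active, tuple(sorted(r.environment.items())))
        if key not in seen:
            seen.add(key)
            results.append(r)
    return results


def step(
    chart: Statechart,
    config: Configuration,
    event: str,
    env: Mapping[str, bool],
    strict: bool = False,
) -> StepResult:
    """One macro-step.  Ignores events with no enabled transition
    (returning the unchanged configuration); resolves nondeterministic
    conflicts by the lexicographically smallest fire-set, or raises
    :class:`NondeterminismError` in strict mode."""
    enabled = enabled_transitions(chart, config, event, env)
    sets = _maximal_fire_sets(chart, enabled)
    if not sets:
        logger.warning("event %r ignored in %s", event, config.label(chart))
        return StepResult(config, dict(env), [], ignored=True)
    if len(sets) > 1:
        conflicting = sorted({t.id for s in sets for t in s})
        if strict:
            raise NondeterminismError(
                f"conflicting transitions enabled on event {event!r}: {conflicting}",
                conflicting,
            )
        logger.warning(
            "nondeterministic conflict on event %r (%s); firing %s",
            event,
            conflicting,
            list(sets[0]),
        )
    return _fire(chart, config, env, sets[0])


def run_trace(chart: Statechart, trace, strict: bool = False) -> list[StepResult]:
    """Replay a :class:`~guidechart.io_formats.Trace`: apply each item's
    external condition updates, then its event; returns the full path."""
    config, env = initial_configuration(chart)
    for cid, val in getattr(trace, "initial_conditions", {}).items():
        if cid not in env:
            raise UnknownReferenceError(f"condition {cid!r} is not declared")
        env[cid] = bool(val)
    path: list[StepResult] = []
    for i, item in enumerate(trace.items):
        try:
            for cid, val in item.updates.items():
                if cid not in env:
                    raise UnknownReferenceError(f"condition {cid!r} is not declared")
                env[cid] = bool(val)
            result = step(chart, config, item.event, env, strict=strict)
        except StatechartError as e:
            raise TraceError(str(e), i) from e
        path.append(result)
        config, env = result.configuration, result.environment
    return path


def is_marked(chart: Statechart, config: Configuration) -> tuple[bool, frozenset[str]]:
    """Whether some active state is marked (a critical juncture /
    terminal outcome), with the set of active marked states."""
    marked = frozenset(s for s in config.active if chart.states[s].marked)
    return bool(marked), marked
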