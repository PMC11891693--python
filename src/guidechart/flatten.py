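"""Compilation of a hierarchical statechart into a flat nondeterministic
automaton, and a finite-horizon trace-equivalence oracle.

The flat automaton is the quintuple (events, states, transition map,
initial state, marked states).  Flat states are the *reachable*
(configuration, condition valuation) pairs of the interpreter: condition
values are baked into states, so the resulting transition function is
guard-free, partial and set-valued.  An event is defined at a flat state
only if it actually fires a transition there (stuttering occurrences are
not part of the automaton's language).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .core_model import Statechart, StatechartError
from .semantics import Configuration, initial_configuration, is_marked, step_all

__all__ = [
    "FlatState",
    "FlatAutomaton",
    "StateSpaceOverflowError",
    "AlphabetMismatchError",
    "flatten",
    "flat_chart_to_automaton",
    "language_equivalence",
]

DEFAULT_STATE_CAP = 10_000


class StateSpaceOverflowError(StatechartError):
    """The reachable flat state space exceeded the configured cap."""


class AlphabetMismatchError(StatechartError):
    """Two automata compared over different event alphabets."""


@dataclass(frozen=True)
class FlatState:
    """One flat automaton state.  When produced by flattening,
    ``annotation`` is the (active state ids, condition valuation) pair it
    denotes and ``label`` a readable rendering of it."""

    id: str
    label: str = ""
    marked: bool = False
    annotation: Optional[tuple[frozenset[str], tuple[tuple[str, bool], ...]]] = None


@dataclass
class FlatAutomaton:
    """Nondeterministic flat automaton with a partial, set-valued
    transition map ``(event, state) -> set of states``."""

    events: frozenset[str]
    states: dict[str, FlatState]
    transition_map: dict[tuple[str, str], frozenset[str]]
    initial: str
    marked: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        if self.initial not in self.states:
            raise StatechartError(f"initial flat state {self.initial!r} undeclared")
        for q in self.marked:
            if q not in self.states:
                raise StatechartError(f"marked flat state {q!r} undeclared")
        for (e, q), targets in self.transition_map.items():
            if e not in self.events:
                raise StatechartError(f"transition on undeclared event {e!r}")
            if q not in self.states or not targets <= set(self.states):
                raise StatechartError(f"transition endpoint undeclared at ({e!r}, {q!r})")

    def successors(self, state: str, event: str) -> frozenset[str]:
        return self.transition_map.get((event, state), frozenset())

    def defined_events(self, state: str) -> list[str]:
        return sorted(e for (e, q) in self.transition_map if q == state)


def flatten(chart: Statechart, cap: int = DEFAULT_STATE_CAP) -> FlatAutomaton:
    """Breadth-first construction of the reachable flat automaton.

    States are discovered in BFS order with events explored in sorted
    order, so ids ("f0", "f1", ...) are deterministic for a given chart.
    Raises :class:`StateSpaceOverflowError` beyond ``cap`` states.
    """
    config0, env0 = initial_configuration(chart)

    def key(config: Configuration, env: dict[str, bool]):
        return (config.active, tuple(sorted(env.items())))

    def label(config: Configuration, env: dict[str, bool]) -> str:
        basics = config.label(chart)
        if env:
            vals = ",".join(f"{c}={'1' if v else '0'}" for c, v in sorted(env.items()))
            return f"{basics}|{vals}"
        return basics

    ids: dict[tuple, str] = {}
    states: dict[str, FlatState] = {}
    marked: set[str] = set()
    tmap: dict[tuple[str, str], set[str]] = {}
    queue: deque[tuple[Configuration, dict[str, bool]]] = deque()

    def intern(config: Configuration, env: dict[str, bool]) -> str:
        k = key(config, env)
        if k in ids:
            return ids[k]
        if len(ids) >= cap:
            raise StateSpaceOverflowError(
                f"flat state space exceeds cap of {cap} states"
            )
        fid = f"f{len(ids)}"
        ids[k] = fid
        m, _ = is_marked(chart, config)
        states[fid] = FlatState(fid, label(config, env), m, (config.active, k[1]))
        if m:
            marked.add(fid)
        queue.append((config, env))
        return fid

    initial_id = intern(config0, env0)
    events = sorted(chart.events)
    while queue:
        config, env = queue.popleft()
        src = ids[key(config, env)]
        for event in events:
            for result in step_all(chart, config, event, env):
                if result.ignored:
                    continue
                dst = intern(result.configuration, result.environment)
                tmap.setdefault((event, src), set()).add(dst)

    return FlatAutomaton(
        events=frozenset(chart.events),
        states=states,
        transition_map={k: frozenset(v) for k, v in tmap.items()},
        initial=initial_id,
        marked=frozenset(marked),
        name=chart.name,
    )


def flat_chart_to_automaton(chart: Statechart) -> FlatAutomaton:
    """Direct conversion of an already-flat, condition-free chart
    (all states basic under the root) preserving state ids and labels.

    Useful for models authored directly as automata; general charts go
    through :func:`flatten`.
    """
    if chart.conditions:
        raise StatechartError("flat conversion requires a condition-free chart")
    for sid, s in chart.states.items():
        if sid != chart.root and not s.is_basic:
            raise StatechartError("flat conversion requires all non-root states basic")
    states = {
        sid: FlatState(sid, s.clinical_label or sid, s.marked, (frozenset({chart.root, sid}), ()))
        for sid, s in chart.states.items()
        if s.is_basic
    }
    tmap: dict[tuple[str, str], set[str]] = {}
    for t in chart.transitions.values():
        tmap.setdefault((t.event, t.source), set()).add(t.target)
    return FlatAutomaton(
        events=frozenset(chart.events),
        states=states,
        transition_map={k: frozenset(v) for k, v in tmap.items()},
        initial=chart.initial_state,
        marked=frozenset(sid for sid, s in states.items() if s.marked),
        name=chart.name,
    )


def language_equivalence(
    a: FlatAutomaton, b: FlatAutomaton, horizon: int = 8
) -> tuple[bool, Optional[list[str]]]:
    """Finite-horizon trace equivalence with marked agreement.

    True iff the sets of event sequences of length <= ``horizon``
    executable from the initial states coincide and, after every common
    sequence, the two reachable state sets agree on whether a marked
    state has been reached.  On failure returns a shortest
    distinguishing sequence (subset-construction BFS).
    """
    if a.events != b.events:
        raise AlphabetMismatchError(
            f"alphabets differ: {sorted(a.events ^ b.events)}"
        )
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")

    def any_marked(auto: FlatAutomaton, qs: frozenset[str]) -> bool:
        return any(q in auto.marked for q in qs)

    start = (frozenset({a.initial}), frozenset({b.initial}))
    if any_marked(a, start[0]) != any_marked(b, start[1]):
        return False, []
    seen: dict[tuple[frozenset[str], frozenset[str]], int] = {start: 0}
    queue: deque[tuple[frozenset[str], frozenset[str], list[str]]] = deque(
        [(start[0], start[1], [])]
    )
    events = sorted(a.events)
    while queue:
        qa, qb, seq = queue.popleft()
        if len(seq) >= horizon:
            continue
        for e in events:
            sa = frozenset().union(*(a.successors(q, e) for q in qa)) if qa else frozenset()
            sb = frozenset().union(*(b.successors(q, e) for q in qb)) if qb else frozenset()
            if not sa and not sb:
                continue
            if bool(sa) != bool(sb):
                return False, seq + [e]
            if any_marked(a, sa) != any_marked(b, sb):
                return False, seq + [e]
            pair = (sa, sb)
            depth = len(seq) + 1
            if pair in seen and seen[pair] <= depth:
                continue
            seen[pair] = depth
            queue.append((sa, sb, seq + [e]))
    return True, None
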