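"""Scenario execution, seeded random exploration, and the random-chart
generator used by the property-test and flattening-oracle harnesses.

Scenarios are executable documentation of the bundled guideline models:
each one is a clinical narrative (a spontaneous, conducted or induced
adaptation course) stored as a trace file with a YAML header recording
the expected final configuration.  Expected results are stored, not
recomputed, so behavioral regressions are visible as scenario failures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

from .core_model import Statechart, build_statechart, validate
from .io_formats import ParseError, Trace, read_trace
from .semantics import StepResult, is_marked, run_trace

__all__ = [
    "ScenarioSpec",
    "ScenarioReport",
    "ChartGenParams",
    "list_scenarios",
    "load_scenario",
    "run_scenario",
    "random_trace",
    "generate_chart",
]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    name: str
    description: str
    model: str
    trace: Trace
    expected_final: frozenset[str]  # expected active basic states at the end
    expected_marked: bool


@dataclass
class ScenarioReport:
    name: str
    ok: bool
    steps: list[StepResult]
    final_basic: frozenset[str]
    marked: bool
    divergence_index: Optional[int] = None
    message: str = ""

    def log(self, chart: Statechart) -> list[str]:
        """Annotated step log (one line per trace item)."""
        lines = []
        for i, s in enumerate(self.steps):
            fired = ",".join(s.fired) if s.fired else "(ignored)"
            lines.append(f"{i:3d}  {fired:24s} -> {s.configuration.label(chart)}")
        return lines


def _scenario_dir():
    return resources.files("guidechart").joinpath("models", "scenarios")


def list_scenarios() -> list[str]:
    return sorted(
        p.name[: -len(".scenario")]
        for p in _scenario_dir().iterdir()
        if p.name.endswith(".scenario")
    )


def load_scenario(name: str) -> ScenarioSpec:
    """Parse a ``.scenario`` file: a YAML header between ``---`` markers
    followed by JSON-lines trace items."""
    path = _scenario_dir().joinpath(f"{name}.scenario")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown scenario {name!r}; available: {list_scenarios()}") from None
    lines = text.splitlines()
    if not lines or lines[0].strip() != "---":
        raise ParseError(f"{name}: scenario must start with a '---' YAML header")
    try:
        end = next(i for i in range(1, len(lines)) if lines[i].strip() == "---")
    except StopIteration:
        raise ParseError(f"{name}: unterminated YAML header") from None
    header = yaml.safe_load("\n".join(lines[1:end])) or {}
    body = "\n".join(lines[end + 1:])
    trace = read_trace(body)
    trace.model = header.get("model")
    trace.initial_conditions = {
        str(k): bool(v) for k, v in (header.get("initial_conditions") or {}).items()
    }
    return ScenarioSpec(
        name=str(header.get("name", name)),
        description=str(header.get("description", "")),
        model=str(header["model"]),
        trace=trace,
        expected_final=frozenset(str(s) for s in header["expected_final"]),
        expected_marked=bool(header["expected_marked"]),
    )


def run_scenario(name: str, strict: bool = True) -> ScenarioReport:
    """Replay a registered scenario against its model and check the
    stored expectations (final basic configuration and markedness)."""
    from .guideline_models import load_bundled
    from .semantics import TraceError

    spec = load_scenario(name)
    chart = load_bundled(spec.model)
    try:
        steps = run_trace(chart, spec.trace, strict=strict)
    except TraceError as e:
        return ScenarioReport(
            name=spec.name, ok=False, steps=[], final_basic=frozenset(),
            marked=False, divergence_index=e.index, message=str(e),
        )
    if steps:
        final_config = steps[-1].configuration
    else:
        from .semantics import initial_configuration

        final_config, _ = initial_configuration(chart)
    final_basic = final_config.basic_active(chart)
    marked, _ = is_marked(chart, final_config)
    ok = final_basic == spec.expected_final and marked == spec.expected_marked
    message = ""
    divergence = None
    if not ok:
        divergence = len(steps) - 1 if steps else 0
        message = (
            f"expected final {sorted(spec.expected_final)} "
            f"(marked={spec.expected_marked}), got {sorted(final_basic)} "
            f"(marked={marked})"
        )
    return ScenarioReport(
        name=spec.name, ok=ok, steps=steps, final_basic=final_basic,
        marked=marked, divergence_index=divergence, message=message,
    )


# ---------------------------------------------------------------------------
# random exploration
# ---------------------------------------------------------------------------

def random_trace(chart: Statechart, seed: int, length: int) -> Trace:
    """A seeded random event trace of ``length`` items.

    Sampling is biased toward events enabled in the current
    configuration (uniform among them); when nothing is enabled a
    uniform alphabet event is emitted, which stutters.  Identical seeds
    yield identical traces.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    from .semantics import initial_configuration, enabled_transitions, step

    rng = random.Random(seed)
    alphabet = sorted(chart.events)
    config, env = initial_configuration(chart)
    items = []
    for _ in range(length):
        enabled_events = [
            e for e in alphabet if enabled_transitions(chart, config, e, env)
        ]
        event = rng.choice(enabled_events) if enabled_events else rng.choice(alphabet)
        items.append(event)
        result = step(chart, config, event, env)
        config, env = result.configuration, result.environment
    return Trace.from_events(items, model=chart.name)


# ---------------------------------------------------------------------------
# random chart generation (fixture generator for the oracle harness)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChartGenParams:
    """Bounds for the random statechart generator.  ``max_basic_states``
    caps the basic-state count so oracle corpora stay desk-sized."""

    max_depth: int = 3
    max_children: int = 3
    orthogonal_probability: float = 0.3
    event_count: int = 4
    condition_count: int = 2
    guard_probability: float = 0.4
    seed: int = 0
    max_basic_states: int = 12
    transition_factor: float = 1.5  # transitions per basic state

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.max_children < 2:
            raise ValueError("max_depth must be >= 1 and max_children >= 2")
        if not (0.0 <= self.orthogonal_probability <= 1.0):
            raise ValueError("orthogonal_probability must be in [0, 1]")
        if not (0.0 <= self.guard_probability <= 1.0):
            raise ValueError("guard_probability must be in [0, 1]")
        if self.event_count < 1 or self.condition_count < 0:
            raise ValueError("event_count >= 1 and condition_count >= 0 required")
        if self.max_basic_states < 2:
            raise ValueError("max_basic_states must be >= 2")


def generate_chart(params: ChartGenParams) -> Statechart:
    """A validate-clean random chart within the stated bounds; the same
    seed always yields the identical chart."""
    rng = random.Random(params.seed)
    counter = {"n": 0}
    basics_left = {"n": params.max_basic_states}
    states: list[dict] = []

    def fresh(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix}{counter['n']}"

    def make_basic() -> str:
        sid = fresh("s")
        basics_left["n"] -= 1
        states.append(dict(id=sid))
        return sid

    def make_node(depth: int, allow_and: bool) -> str:
        """A basic state or a composite subtree, within budget."""
        if depth >= params.max_depth or basics_left["n"] < 4:
            return make_basic()
        if allow_and and basics_left["n"] >= 6 and rng.random() < params.orthogonal_probability:
            return make_and(depth)
        if rng.random() < 0.5:
            return make_xor(depth)
        return make_basic()

    def make_xor(depth: int) -> str:
        sid = fresh("Q")
        k = rng.randint(2, params.max_children)
        children = [make_node(depth + 1, allow_and=True) for _ in range(2)]
        for _ in range(k - 2):
            if basics_left["n"] <= 0:
                break
            children.append(make_node(depth + 1, allow_and=True))
        states.append(dict(id=sid, kind="xor_composite", children=children,
                           default_child=children[0]))
        return sid

    def make_and(depth: int) -> str:
        sid = fresh("P")
        k = min(2 + (rng.random() < 0.2), params.max_children)
        regions = [make_xor(depth + 1) for _ in range(k)]
        states.append(dict(id=sid, kind="and_composite", children=regions))
        return sid

    # top level: first child is basic so the default chain starts simple
    top = [make_basic()]
    while basics_left["n"] > 0 and len(top) < params.max_children + 1:
        top.append(make_node(1, allow_and=True))
    if len(top) < 2:
        top.append(make_basic())
    root_id = "root"
    states.append(dict(id=root_id, kind="xor_composite", children=top,
                       default_child=top[0]))

    events = [dict(id=f"e{i+1}") for i in range(params.event_count)]
    conditions = [
        dict(id=f"c{i+1}", initial_value=bool(rng.getrandbits(1)))
        for i in range(params.condition_count)
    ]

    all_ids = [s["id"] for s in states if s["id"] != root_id]
    n_transitions = max(1, int(params.transition_factor * params.max_basic_states))
    transitions: list[dict] = []
    seen_keys: set[tuple] = set()
    for i in range(n_transitions):
        for _attempt in range(10):
            source = rng.choice(all_ids)
            target = rng.choice(all_ids)
            event = rng.choice(events)["id"]
            guard: dict[str, bool] = {}
            if conditions and rng.random() < params.guard_probability:
                c = rng.choice(conditions)["id"]
                guard[c] = bool(rng.getrandbits(1))
            key = (source, event, tuple(sorted(guard.items())))
            if key in seen_keys:
                continue
            seen_keys.add(key)
            actions = []
            if conditions and rng.random() < 0.2:
                c = rng.choice(conditions)["id"]
                actions.append(dict(condition=c, value=bool(rng.getrandbits(1))))
            transitions.append(dict(
                id=f"t{len(transitions)+1:02d}", source=source, target=target,
                event=event, guard=guard, actions=actions,
            ))
            break

    chart = build_statechart(
        name=f"random-{params.seed}",
        root=root_id,
        states=states,
        events=events,
        conditions=conditions,
        transitions=transitions,
        initial_state=top[0],
    )
    report = validate(chart)
    assert report.ok, [f.message for f in report.errors]
    return chart
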