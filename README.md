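# guidechart

Executable Harel statecharts for computable clinical guidelines.

Clinical protocols are usually published as flowcharts. Flowcharts have no
formal semantics: they cannot be executed, checked for unreachable or
conflicting recommendations, or compared against a simpler reference
version. `guidechart` encodes a protocol as a *statechart* — a hierarchical
nondeterministic finite automaton

```
G = (Σ, Q, f, q0, Qm)
```

with Σ the event alphabet (clinical indicators: a vital sign, a symptom, a
patient characteristic), Q the states (diagnostic steps and procedural
actions), f : Σ × Q → 2^Q the partial, set-valued transition function,
q0 the initial state, and Qm ⊆ Q the *marked* states denoting critical
junctures or terminal outcomes. On top of the flat formalism the package
supports the three statechart constructs clinical models need:

* **XOR superstates** — exactly one child active while the group is active;
* **orthogonal (AND) regions** — concurrently active subprocesses, e.g.
  ventilatory assistance running while minute-wise vitality evaluations
  continue;
* **conditioned transitions** — a transition fires only when its event
  occurs *and* its boolean guard holds, e.g. cord-clamping transitions
  guarded by the condition NNC ("neonate not clamped"), which every
  clamping state irreversibly clears on entry.

The package provides the data model and validator, an interpreter
(configurations, guarded macro-steps, concurrency), a **flattener** that
compiles a hierarchical chart into the guard-free quintuple above over
(configuration × condition-valuation) states, a finite-horizon
trace-equivalence oracle, verification reports (reachability with witness
traces, nondeterminism detection, monotone-condition checks, event
coverage), JSON/DOT/SCXML serialization, a scenario runner, a seeded
random-chart generator, and a CLI.

Two clinical models ship as first-class, tested encodings:

* **`ina`** — the Immediate Neonatal Adaptation guideline
  (physiologically-based umbilical cord clamping): 20 basic states,
  4 superstates, 38 events, 4 conditions. It covers prenatal evaluation,
  mode of birth, Apgar / Silverman–Andersen diagnosis, the four clamping
  modalities (immediate, early, habitual, deferred), minute-1/5/10
  evaluations, and orthogonal ventilatory/cardiovascular assistance.
* **`gestation`** — a flat 7-state, 9-event automaton screening for
  possible gestation before a diagnostic nuclear-medicine procedure.

A third bundled family (`refinement-flat` / `refinement-grouped` /
`refinement-orthogonal`) encodes one behavior three ways and pins the
central refinement claim: grouping states into superstates or orthogonal
regions preserves the event language.

## Worked example

```sh
$ guidechart stats ina
basic states    20
superstates     4
events          38
conditions      4
transitions     44
marked states   6
```

The counts are the structure of the neonatal-adaptation chart (the
synthetic root wrapper is excluded). Simulating the gestation screening
with the events `a` (age 18–55) then `e` (pregnancy not ruled out):

```sh
$ guidechart simulate gestation --trace a,e
  0  t01                      -> {q1}
  1  t07                      -> {q3}
final: {q3} marked=False
```

i.e. f(q1, e) = q3 — an established menstrual cycle plus an unexcluded
pregnancy yields the *probable gestation* diagnosis. A full clinical
scenario (induced adaptation with invasive support):

```sh
$ guidechart simulate --scenario critical_support
  0  t02                      -> {2}
  1  t04                      -> {3}
  2  t05                      -> {4}
  3  t11                      -> {6}
  4  t14,t15                  -> {16,8}
  5  t27                      -> {19}
final: {19} marked=True ok=True
```

Step 4 shows orthogonal concurrency: the confirmed Apgar-0 indicator
(`e14`) simultaneously enters invasive assistance (state 16) and the
minute-1 evaluation (state 8); the run ends in the marked
transfer-to-neonatal-care state. Verification of the whole model:

```sh
$ guidechart verify ina --monotone NNC:true->false
reachable basic states: 20; unreachable: none
...
no reachable nondeterminism
condition NNC true->false: monotone
```

Every marked state is reported with a shortest replayable witness trace,
and the irreversibility of cord clamping (NNC can only go true→false) is
confirmed both statically and over the reachable flat state space.

From Python the same objects are available directly:

```python
from guidechart import ina_statechart, flatten, model_statistics
chart = ina_statechart()
print(model_statistics(chart).basic_state_count)  # 20
print(len(flatten(chart).states))                 # 57 reachable flat states
```

## Layout

```
src/guidechart/
  core_model.py        data model + structural validation
  semantics.py         interpreter (configurations, macro-steps)
  flatten.py           hierarchical -> flat compilation, equivalence oracle
  verify.py            reachability / nondeterminism / monotonicity / coverage
  guideline_models.py  bundled model constructors and statistics
  io_formats.py        model JSON dialect, traces, DOT and SCXML export
  simulator.py         scenarios, random walks, random-chart generator
  cli.py               command-line interface
  models/              committed .chart.json encodings + .scenario files
docs/methods.md        modeling and semantics notes
```

See `docs/methods.md` for the semantics (macro-step rules, AND-region
entry policy, conflict resolution), the transcription notes for the
bundled models, and known limitations.
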