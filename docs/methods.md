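# Methods

## The formalism

A statechart here is a tree of states over a finite event alphabet and a
finite set of boolean conditions. Leaves are *basic* states; internal
nodes are *XOR composites* (exactly one child active whenever the node is
active) or *AND composites* (children are orthogonal regions, themselves
composite, of which at least one is active). A *configuration* is the set
of simultaneously active states, closed under ancestry and consistent
with the XOR/AND rules. Transitions connect any two states (basic or
composite), are labeled with one event, a guard (a conjunction of
condition literals; empty = true), and condition assignments; states may
additionally carry entry assignments. A distinguished subset of states is
*marked*, denoting critical junctures or terminal outcomes of the
protocol. The synthetic root is an XOR composite wrapping the top-level
states; it gives the entry rules a uniform base case and is excluded from
all reported statistics.

Flattening compiles a chart to the quintuple (Σ, Q, f, q0, Qm): Q is the
set of *reachable* (configuration, condition-valuation) pairs, so guards
disappear into the states and f is a guard-free partial set-valued map.
An event is defined at a flat state only if it fires at least one
transition there; ignored (stuttering) occurrences are not part of the
automaton's language. The construction is breadth-first with events in
sorted order, so flat-state ids are deterministic; a configurable cap
(default 10 000 states) turns runaway products into an explicit overflow
error rather than an unbounded computation.

## Macro-step semantics

One external event produces one macro-step; there is no internal event
raising or broadcast (clinical indicators arrive one at a time from the
outside world). The step pipeline:

1. **Enabledness.** A transition is enabled if its source state is in the
   current configuration (a composite source means "while this group is
   active"), its event matches, and its guard holds in the *pre-step*
   environment.
2. **Inner priority.** If an enabled descendant-level transition
   conflicts with an enabled ancestor-level one, the descendant wins.
   The bundled models contain no such conflicts; the rule exists so
   randomly generated charts behave sanely.
3. **Fire-sets.** Two enabled transitions are *compatible* when their
   exited subtrees are disjoint and their targets do not compete for the
   same XOR region, or when they form the concurrent-entry idiom: same
   source, targets in distinct regions of the same AND composite. The
   step fires a maximal set of pairwise-compatible transitions (computed
   as maximal cliques of the compatibility graph via networkx). More
   than one maximal set means genuine nondeterminism: `step` picks the
   lexicographically smallest fire-set (or raises in strict mode), while
   `step_all` — used by flattening and verification — explores every
   alternative.
4. **Execution.** Exited subtrees are removed; transition assignments
   are applied in transition-id order, then targets are entered (default
   completion), then entry assignments of newly entered states are
   applied. Guards having been evaluated before any assignment, the
   outcome is independent of ordering *within* the fired set except for
   the documented id-order tie-break when two assignments touch the same
   condition.

**AND-region entry.** Entering an orthogonal composite through a
transition that targets a particular region (or a state inside it)
activates *only* that region; untargeted regions stay inactive until
explicitly entered. This guarantees the activation of at least one inner
state, not of all of them, and is what makes the orthogonal refinement
equivalent to its flat reference: with the side condition false, only one
g-transition fires and only one region starts. It deviates from classic
statechart semantics, where entry activates every region; the deviation
is pinned by tests (`test_untargeted_region_stays_inactive`). Entry that
targets the AND composite itself — including default entry at
initialization — activates every region at its default, which matches
the classic rule for that case.

**Stuttering.** An event with no enabled transition is ignored with a
logged warning, never an error: clinical indicators routinely occur in
states where they are irrelevant (e.g. a second clamping indication after
the cord is already occluded).

## Equivalence checking

`language_equivalence(a, b, horizon)` compares two flat automata by
subset-construction BFS: it checks that the same event sequences of
length ≤ horizon are executable from the initial states and that after
every common sequence the two reachable sets agree on whether a marked
state has been reached. On failure it returns a shortest distinguishing
sequence. Finite-horizon trace equality (default horizon 8) was chosen
over full bisimulation because it is cheap, returns actionable
counterexamples, and suffices for the short, acyclicity-dominated charts
clinical guidelines produce. Note that trace equivalence deliberately
identifies nondeterministic branching with concurrent activation — the
grouped encoding reaches {B} *or* {D} while the orthogonal one reaches
{B, D} — which is exactly the sense in which the three refinement
encodings are "the same behavior".

## Verification reports

*Reachability* projects the flat space back to basic states and produces,
for every marked state, a shortest witness event sequence (BFS with
lexicographic tie-break on event ids, so witnesses are reproducible
fixtures); every witness replays through the interpreter.
*Nondeterminism* enumerates reachable (flat state, event) pairs with more
than one maximal fire-set. *Monotonicity* of a condition (e.g. NNC may
only go true→false, encoding that cord clamping is irreversible) is
checked twice: a static scan of all assignments — which also catches
latent violations on unreachable transitions — and a dynamic pass over
the edges of the reachable flat space; both must be clean. *Event
coverage* lists, per reachable basic state, the events that can never
fire there, an audit artifact for guideline review.

## The bundled models

The neonatal-adaptation chart was transcribed from the guideline's prose
description rather than from a machine-readable source, under these
fixed anchors: 20 basic states and 4 superstates; the initial state is
the prenatal evaluation; states 6 and 16 are deficient vitality and
invasive (ventilatory/cardiac/hemodynamic) assistance, with the
confirmed-Apgar-0 indicator linking them; superstate C groups the
normal-ventilation diagnosis with early/habitual/deferred clamping;
superstates A (assistance) and B (minute-1/5/10 evaluations) are
orthogonal regions of D; the four clamping states and the two outcome
states (joint accommodation, transfer to neonatal care) are marked; all
clamping transitions are guarded by NNC and habitual clamping
additionally requires the physiological milestones A1∧A2∧A3. Where the
prose names several clinical indications for one clamping modality
(four for immediate, three groups for early, two groups for deferred),
each indication is its own event on a parallel transition — this is the
"one transition label standing for several events" convention of the
original figure, and it is how our transcription arrives at **38**
events. The guideline's own documentation prints both 36 and 38 for the
event count (an internal inconsistency it does not resolve); the
package asserts the count its transcription actually realizes, 38, and
records the discrepancy here rather than choosing silently.

Timing ("2–3 minutes, up to 5–6") is represented only through the
minute-marker events of region B — there are no clocks; real-time
semantics is out of scope. The criticality classes (normal /
intervention / critical / positive) form a closed enumeration mapped to
the gray/orange/magenta/green shading of the original figure.

The gestation-risk automaton's transition structure was likewise
reconstructed from its flowchart logic, constrained by the published
state/event tables, the worked value f(q1, e) = q3, and the requirement
that the two marked terminals (procedure done / postponed) be reachable
sinks. Both transcriptions live in `_authoring.py`; the committed
`.chart.json` files are their exact serialization, and a regression test
fails if data and code ever drift apart.

## The random-chart generator

`generate_chart` exists to exercise the semantics on structures the
hand-built models do not contain (deep nesting, cross-region
transitions, conflicting targets). Its defaults mirror the oracle-corpus
conditions: depth ≤ 3, ≤ 3 children per composite, orthogonal
probability 0.3, 4 events, 2 conditions, guard probability 0.4, and a
basic-state budget of 10–12 so the brute-force interpreter BFS stays
desk-sized. It emulates structural variety, not clinical plausibility:
generated charts have no meaningful labels, no monotone conditions and
no marked-state discipline, so passing the oracle suite demonstrates
semantic correctness of the engine, not medical validity of any
particular encoding. The generator is seed-deterministic; the
100-chart oracle corpus compares, per chart, the flattened automaton
against an independent brute-force BFS over `step_all` for every
executable event sequence to depth 6 (including marked reachability).
Depth 6 and 100 charts keep the whole comparison under a few seconds
while covering every construct the generator can produce.

## Numerical and procedural choices

* Ties anywhere (fire-set choice, witness search, serialization order)
  are broken lexicographically by id, making every output byte-stable
  and golden-file-testable.
* The duplicate-definition validator treats two transitions sharing
  (source, event, guard) as an error *unless* they form the
  concurrent-entry idiom into distinct orthogonal regions, which the
  neonatal model uses deliberately.
* Degenerate inputs: a chart with a single basic state flattens to one
  state and an empty map; an empty trace replays to the initial
  configuration; an empty guard is true; horizon 0 equivalence compares
  only initial markedness.

## Known limitations

* No history states, no timed triggers or clock variables, no internal
  event broadcasting, and no action language beyond boolean condition
  assignment — the guideline encodings need none of these.
* Equivalence is finite-horizon trace equivalence, not bisimulation;
  charts that differ only beyond the horizon or only in branching
  structure are not distinguished.
* SCXML export is structural interchange (states, parallels, initial
  attributes, cond expressions, assigns); marked-state status has no
  SCXML counterpart and is not exported. Import is intentionally not
  supported.
* The flattener bakes conditions into states; charts with many
  conditions can grow exponentially — the cap makes this an explicit
  error, and monotone conditions (like NNC) keep the bundled models
  small (the neonatal chart has 57 reachable flat states).
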