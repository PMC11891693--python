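---
name: induced_deferred
description: >
  Induced adaptation with deferred clamping: severe ventilation
  difficulty starts invasive assistance with concurrent minute
  evaluations; persistence of the deficit indicates deferred clamping
  (the cord is still unclamped), after which the newborn stabilizes.
model: ina
expected_final: ["18"]
expected_marked: true
---
{"event": "e1", "note": "habitual risk"}
{"event": "e3", "note": "vaginal birth"}
{"event": "e5", "note": "newborn presented for assessment"}
{"event": "e13", "note": "severe ventilation difficulty (Silverman-Andersen >= 4)"}
{"event": "e17", "note": "invasive support; minute evaluations run concurrently"}
{"event": "e20", "note": "fifth-minute evaluation"}
{"event": "e29", "note": "deficit persists -> deferred clamping (NNC holds)"}
{"event": "e33", "note": "stable after clamping; joint accommodation"}
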