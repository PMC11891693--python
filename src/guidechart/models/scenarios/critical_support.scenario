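---
name: critical_support
description: >
  Induced adaptation: after an abdominal birth the newborn shows
  deficient vitality, a confirmed Apgar of 0 starts invasive
  ventilatory, cardiac and hemodynamic assistance (with the minute
  evaluations running concurrently), and the neonate is transferred to a
  neonatal care unit.
model: ina
expected_final: ["19"]
expected_marked: true
---
{"event": "e2", "note": "increased risk with abdominal-birth indication"}
{"event": "e4", "note": "abdominal birth performed"}
{"event": "e5", "note": "newborn presented for assessment"}
{"event": "e11", "note": "deficient vitality (low Apgar)"}
{"event": "e14", "note": "Apgar evaluation of 0 confirmed -> invasive assistance"}
{"event": "e23", "note": "transfer to neonatal care unit indicated"}
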