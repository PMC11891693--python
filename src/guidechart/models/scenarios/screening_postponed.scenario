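---
name: screening_postponed
description: >
  Gestation-risk screening: an adult patient with an established cycle
  cannot rule out pregnancy and her last menstrual period is more than
  ten days ago, so the diagnostic procedure is postponed.
model: gestation
expected_final: ["q6"]
expected_marked: true
---
{"event": "a", "note": "age 18-55"}
{"event": "e", "note": "does not rule out pregnancy"}
{"event": "i", "note": "LMP > 10 days"}
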