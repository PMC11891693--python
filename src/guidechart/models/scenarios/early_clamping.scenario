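---
name: early_clamping
description: >
  Conducted adaptation with early clamping: normal ventilation is
  diagnosed but maternal RhD immunization indicates early clamping to
  limit antibody transmission; the newborn then joins the mother.
model: ina
expected_final: ["18"]
expected_marked: true
---
{"event": "e1", "note": "habitual risk"}
{"event": "e3", "note": "vaginal birth"}
{"event": "e5", "note": "newborn presented for assessment"}
{"event": "e10", "note": "adequate vitality and ventilation"}
{"event": "e25", "note": "maternal immunization -> early clamping"}
{"event": "e33", "note": "stable; joint accommodation"}
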