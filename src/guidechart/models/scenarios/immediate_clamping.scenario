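---
name: immediate_clamping
description: >
  Immediate cord clamping at birth: catastrophic cord rupture while the
  cord is still unclamped (NNC holds) forces ICC; a second ICC
  indication afterwards is ignored because clamping is irreversible.
model: ina
expected_final: ["12"]
expected_marked: true
---
{"event": "e1", "note": "habitual risk"}
{"event": "e3", "note": "vaginal birth"}
{"event": "e5", "note": "newborn presented for assessment"}
{"event": "e6", "note": "rupture of the umbilical cord; NNC holds -> ICC"}
{"event": "e7", "note": "further ICC indication: ignored, cord already occluded"}
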