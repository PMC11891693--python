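---
name: spontaneous_habitual
description: >
  Spontaneous adaptation after a vaginal birth: vitality and ventilation
  are adequate at birth, the physiological milestones A1-A3 appear within
  the usual window, habitual cord clamping is performed and the newborn
  joins the mother.
model: ina
expected_final: ["18"]
expected_marked: true
---
{"event": "e1", "note": "habitual risk, no abdominal-birth indication"}
{"event": "e3", "note": "vaginal birth"}
{"event": "e5", "note": "newborn presented for assessment"}
{"event": "e10", "note": "adequate vitality and ventilation"}
{"event": "e30", "note": "A1: effective pulmonary ventilation"}
{"event": "e31", "note": "A2: perfusion transition completed"}
{"event": "e32", "note": "A3: umbilical flow declined"}
{"event": "e27", "note": "habitual clamping indicated (A1-A3 present)"}
{"event": "e33", "note": "stable; joint accommodation"}
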