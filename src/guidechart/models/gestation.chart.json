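{
  "format_version": "1.0",
  "name": "gestation-risk",
  "root": "G",
  "initial_state": "q0",
  "states": [
    {
      "id": "G",
      "clinical_label": "Gestation risk evaluation",
      "kind": "xor_composite",
      "children": [
        "q0",
        "q1",
        "q2",
        "q3",
        "q4",
        "q5",
        "q6"
      ],
      "default_child": "q0"
    },
    {
      "id": "q0",
      "clinical_label": "start of the test"
    },
    {
      "id": "q1",
      "clinical_label": "established menstrual cycle"
    },
    {
      "id": "q2",
      "clinical_label": "uncertain menstrual cycle"
    },
    {
      "id": "q3",
      "clinical_label": "probable gestation",
      "criticality": "intervention"
    },
    {
      "id": "q4",
      "clinical_label": "improbable gestation"
    },
    {
      "id": "q5",
      "clinical_label": "the procedure is done",
      "marked": true,
      "criticality": "positive"
    },
    {
      "id": "q6",
      "clinical_label": "the procedure is postponed",
      "marked": true,
      "criticality": "intervention"
    }
  ],
  "events": [
    {
      "id": "a",
      "description": "18 < Age < 55 years"
    },
    {
      "id": "b",
      "description": "12 < Age < 17 years"
    },
    {
      "id": "c",
      "description": "Presents menstruation"
    },
    {
      "id": "d",
      "description": "Patient rules out possible gestation"
    },
    {
      "id": "e",
      "description": "The patient does NOT rule out possible pregnancy"
    },
    {
      "id": "f",
      "description": "Last menstrual period (LMP) < 10 days"
    },
    {
      "id": "g",
      "description": "She did not start menstruation"
    },
    {
      "id": "h",
      "description": "Hysterectomy or Age > 50 years or Last Menstrual Period > 12 months"
    },
    {
      "id": "i",
      "description": "Last Menstrual Period (LMP) > 10 days"
    }
  ],
  "conditions": [],
  "transitions": [
    {
      "id": "t01",
      "source": "q0",
      "target": "q1",
      "event": "a"
    },
    {
      "id": "t02",
      "source": "q0",
      "target": "q2",
      "event": "b"
    },
    {
      "id": "t03",
      "source": "q0",
      "target": "q4",
      "event": "h"
    },
    {
      "id": "t04",
      "source": "q2",
      "target": "q1",
      "event": "c"
    },
    {
      "id": "t05",
      "source": "q2",
      "target": "q4",
      "event": "g"
    },
    {
      "id": "t06",
      "source": "q1",
      "target": "q4",
      "event": "d"
    },
    {
      "id": "t07",
      "source": "q1",
      "target": "q3",
      "event": "e"
    },
    {
      "id": "t08",
      "source": "q3",
      "target": "q5",
      "event": "f"
    },
    {
      "id": "t09",
      "source": "q3",
      "target": "q6",
      "event": "i"
    },
    {
      "id": "t10",
      "source": "q4",
      "target": "q5",
      "event": "f"
    }
  ]
}
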