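{
  "format_version": "1.0",
  "name": "refinement-orthogonal",
  "root": "T",
  "initial_state": "A",
  "states": [
    {
      "id": "A"
    },
    {
      "id": "B"
    },
    {
      "id": "C"
    },
    {
      "id": "D"
    },
    {
      "id": "E"
    },
    {
      "id": "Q1",
      "kind": "xor_composite",
      "children": [
        "B",
        "C"
      ],
      "default_child": "B"
    },
    {
      "id": "Q2",
      "kind": "xor_composite",
      "children": [
        "D",
        "E"
      ],
      "default_child": "D"
    },
    {
      "id": "S",
      "kind": "and_composite",
      "children": [
        "Q1",
        "Q2"
      ]
    },
    {
      "id": "T",
      "kind": "xor_composite",
      "children": [
        "A",
        "S"
      ],
      "default_child": "A"
    }
  ],
  "events": [
    {
      "id": "d",
      "description": "return to A"
    },
    {
      "id": "f",
      "description": "advance inner state"
    },
    {
      "id": "g",
      "description": "trigger from A"
    }
  ],
  "conditions": [
    {
      "id": "X",
      "description": "side condition enabling the concurrent branch",
      "initial_value": false
    }
  ],
  "transitions": [
    {
      "id": "t1",
      "source": "A",
      "target": "B",
      "event": "g"
    },
    {
      "id": "t2",
      "source": "A",
      "target": "D",
      "event": "g",
      "guard": {
        "X": true
      }
    },
    {
      "id": "t3",
      "source": "B",
      "target": "C",
      "event": "f"
    },
    {
      "id": "t4",
      "source": "D",
      "target": "E",
      "event": "f"
    },
    {
      "id": "t5",
      "source": "S",
      "target": "A",
      "event": "d"
    }
  ]
}
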