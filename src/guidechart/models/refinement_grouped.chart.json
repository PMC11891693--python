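{
  "format_version": "1.0",
  "name": "refinement-grouped",
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
      "id": "T",
      "kind": "xor_composite",
      "children": [
        "A",
        "Q1",
        "Q2"
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
      "source": "Q1",
      "target": "A",
      "event": "d"
    },
    {
      "id": "t6",
      "source": "Q2",
      "target": "A",
      "event": "d"
    }
  ]
}
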