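digraph "refinement-flat" {
  compound=true;
  rankdir=TB;
  node [shape=box, style="rounded,filled"];
  "A" [label="A", fillcolor="lightgray"];
  "B" [label="B", fillcolor="lightgray"];
  "C" [label="C", fillcolor="lightgray"];
  "D" [label="D", fillcolor="lightgray"];
  "E" [label="E", fillcolor="lightgray"];
  "__initial" [shape=point, label=""];
  "__initial" -> "A";
  "A" -> "B" [label="g"];
  "A" -> "D" [label="g [X]"];
  "B" -> "C" [label="f"];
  "D" -> "E" [label="f"];
  "B" -> "A" [label="d"];
  "C" -> "A" [label="d"];
  "D" -> "A" [label="d"];
  "E" -> "A" [label="d"];
}
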