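digraph "gestation-risk" {
  compound=true;
  rankdir=TB;
  node [shape=box, style="rounded,filled"];
  "q0" [label="start of the test", fillcolor="lightgray"];
  "q1" [label="established menstrual cycle", fillcolor="lightgray"];
  "q2" [label="uncertain menstrual cycle", fillcolor="lightgray"];
  "q3" [label="probable gestation", fillcolor="orange"];
  "q4" [label="improbable gestation", fillcolor="lightgray"];
  "q5" [label="the procedure is done", fillcolor="palegreen", peripheries=2];
  "q6" [label="the procedure is postponed", fillcolor="orange", peripheries=2];
  "__initial" [shape=point, label=""];
  "__initial" -> "q0";
  "q0" -> "q1" [label="a"];
  "q0" -> "q2" [label="b"];
  "q0" -> "q4" [label="h"];
  "q2" -> "q1" [label="c"];
  "q2" -> "q4" [label="g"];
  "q1" -> "q4" [label="d"];
  "q1" -> "q3" [label="e"];
  "q3" -> "q5" [label="f"];
  "q3" -> "q6" [label="i"];
  "q4" -> "q5" [label="f"];
}
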