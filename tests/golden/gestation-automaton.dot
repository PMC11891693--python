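digraph "gestation-risk" {
  rankdir=LR;
  node [shape=circle];
  "q0" [label="start of the test"];
  "q1" [label="established menstrual cycle"];
  "q2" [label="uncertain menstrual cycle"];
  "q3" [label="probable gestation"];
  "q4" [label="improbable gestation"];
  "q5" [label="the procedure is done", shape=doublecircle];
  "q6" [label="the procedure is postponed", shape=doublecircle];
  "__initial" [shape=point, label=""];
  "__initial" -> "q0";
  "q0" -> "q1" [label="a"];
  "q0" -> "q2" [label="b"];
  "q2" -> "q1" [label="c"];
  "q1" -> "q4" [label="d"];
  "q1" -> "q3" [label="e"];
  "q3" -> "q5" [label="f"];
  "q4" -> "q5" [label="f"];
  "q2" -> "q4" [label="g"];
  "q0" -> "q4" [label="h"];
  "q3" -> "q6" [label="i"];
}
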