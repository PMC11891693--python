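digraph "ina" {
  compound=true;
  rankdir=TB;
  node [shape=box, style="rounded,filled"];
  "0" [label="Prenatal evaluation", fillcolor="lightgray"];
  "1" [label="Vaginal birth attendance (habitual risk or increased risk without abdominal-birth indication)", fillcolor="lightgray"];
  "2" [label="Abdominal birth attendance (increased risk with abdominal-birth indication)", fillcolor="orange"];
  "3" [label="Birth completed", fillcolor="lightgray"];
  "4" [label="Diagnosis of vitality and ventilation at birth", fillcolor="lightgray"];
  "5" [label="Mild ventilation difficulty (Silverman-Andersen score 1-3)", fillcolor="orange"];
  "6" [label="Deficient vitality (low Apgar score)", fillcolor="orange"];
  "7" [label="Severe ventilation difficulty (Silverman-Andersen score >= 4)", fillcolor="orange"];
  "12" [label="Immediate clamping of the umbilical cord (ICC)", fillcolor="palegreen", peripheries=2];
  subgraph "cluster_C" {
    label="Clamping Type";
    style=solid;
    "11" [label="Diagnosis of adequate or normal ventilation", fillcolor="lightgray"];
    "13" [label="Early clamping of the umbilical cord (ECC)", fillcolor="palegreen", peripheries=2];
    "14" [label="Habitual clamping of the umbilical cord (HCC)", fillcolor="palegreen", peripheries=2];
    "15" [label="Deferred clamping of the umbilical cord (DCC)", fillcolor="palegreen", peripheries=2];
  }
  subgraph "cluster_D" {
    label="Vitality and Ventilation Medical Assistance";
    style=solid;
    subgraph "cluster_A" {
      label="Ventilatory and Cardiovascular Assistance";
      style=dashed;
      "17" [label="Non-invasive ventilatory assistance", fillcolor="orange"];
      "16" [label="Invasive ventilatory, cardiac and hemodynamic assistance", fillcolor="magenta"];
    }
    subgraph "cluster_B" {
      label="Temporal Diagnosis of Vitality and Ventilation";
      style=dashed;
      "8" [label="Evaluation of vitality and ventilation at minute 1", fillcolor="lightgray"];
      "9" [label="Evaluation of vitality and ventilation at minute 5", fillcolor="lightgray"];
      "10" [label="Evaluation of vitality and ventilation at minute 10", fillcolor="lightgray"];
    }
  }
  "18" [label="Joint accommodation with the mother", fillcolor="palegreen", peripheries=2];
  "19" [label="Transfer to neonatal care unit", fillcolor="orange", peripheries=2];
  "__initial" [shape=point, label=""];
  "__initial" -> "0";
  "0" -> "1" [label="e1"];
  "0" -> "2" [label="e2"];
  "1" -> "3" [label="e3"];
  "2" -> "3" [label="e4"];
  "3" -> "4" [label="e5"];
  "4" -> "12" [label="e6 [NNC]"];
  "4" -> "12" [label="e7 [NNC]"];
  "4" -> "12" [label="e8 [NNC]"];
  "4" -> "12" [label="e9 [NNC]"];
  "4" -> "11" [label="e10", lhead="cluster_C"];
  "4" -> "6" [label="e11"];
  "4" -> "5" [label="e12"];
  "4" -> "7" [label="e13"];
  "6" -> "16" [label="e14"];
  "6" -> "8" [label="e14"];
  "6" -> "17" [label="e15"];
  "6" -> "8" [label="e15"];
  "5" -> "17" [label="e16"];
  "5" -> "8" [label="e16"];
  "7" -> "16" [label="e17"];
  "7" -> "8" [label="e17"];
  "5" -> "11" [label="e18", lhead="cluster_C"];
  "17" -> "16" [label="e19"];
  "8" -> "9" [label="e20"];
  "9" -> "10" [label="e21"];
  "17" -> "11" [label="e22", ltail="cluster_D", lhead="cluster_C"];
  "17" -> "19" [label="e23", ltail="cluster_D"];
  "11" -> "13" [label="e24 [NNC]"];
  "11" -> "13" [label="e25 [NNC]"];
  "11" -> "13" [label="e26 [NNC]"];
  "11" -> "14" [label="e27 [A1 & A2 & A3 & NNC]"];
  "11" -> "15" [label="e28 [NNC]"];
  "11" -> "15" [label="e38 [NNC]"];
  "17" -> "15" [label="e29 [NNC]", ltail="cluster_D"];
  "11" -> "11" [label="e30 / A1:=1"];
  "11" -> "11" [label="e31 / A2:=1"];
  "11" -> "11" [label="e32 / A3:=1"];
  "11" -> "18" [label="e33 [!NNC]", ltail="cluster_C"];
  "12" -> "18" [label="e33"];
  "11" -> "19" [label="e34 [!NNC]", ltail="cluster_C"];
  "12" -> "19" [label="e34"];
  "9" -> "11" [label="e35"];
  "10" -> "11" [label="e36"];
  "10" -> "19" [label="e37"];
}
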