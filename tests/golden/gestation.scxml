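<?xml version="1.0" encoding="UTF-8"?>
<scxml xmlns="http://www.w3.org/2005/07/scxml" version="1.0" datamodel="ecmascript" initial="q0">
  <state id="q0">
    <transition event="a" target="q1" />
    <transition event="b" target="q2" />
    <transition event="h" target="q4" />
  </state>
  <state id="q1">
    <transition event="d" target="q4" />
    <transition event="e" target="q3" />
  </state>
  <state id="q2">
    <transition event="c" target="q1" />
    <transition event="g" target="q4" />
  </state>
  <state id="q3">
    <transition event="f" target="q5" />
    <transition event="i" target="q6" />
  </state>
  <state id="q4">
    <transition event="f" target="q5" />
  </state>
  <state id="q5" />
  <state id="q6" />
</scxml>
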