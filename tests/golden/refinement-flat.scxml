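<?xml version="1.0" encoding="UTF-8"?>
<scxml xmlns="http://www.w3.org/2005/07/scxml" version="1.0" datamodel="ecmascript" initial="A">
  <datamodel>
    <data id="X" expr="false" />
  </datamodel>
  <state id="A">
    <transition event="g" target="B" />
    <transition event="g" cond="X" target="D" />
  </state>
  <state id="B">
    <transition event="f" target="C" />
    <transition event="d" target="A" />
  </state>
  <state id="C">
    <transition event="d" target="A" />
  </state>
  <state id="D">
    <transition event="f" target="E" />
    <transition event="d" target="A" />
  </state>
  <state id="E">
    <transition event="d" target="A" />
  </state>
</scxml>
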