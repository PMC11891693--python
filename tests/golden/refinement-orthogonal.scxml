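<?xml version="1.0" encoding="UTF-8"?>
<scxml xmlns="http://www.w3.org/2005/07/scxml" version="1.0" datamodel="ecmascript" initial="A">
  <datamodel>
    <data id="X" expr="false" />
  </datamodel>
  <state id="A">
    <transition event="g" target="B" />
    <transition event="g" cond="X" target="D" />
  </state>
  <parallel id="S">
    <transition event="d" target="A" />
    <state id="Q1" initial="B">
      <state id="B">
        <transition event="f" target="C" />
      </state>
      <state id="C" />
    </state>
    <state id="Q2" initial="D">
      <state id="D">
        <transition event="f" target="E" />
      </state>
      <state id="E" />
    </state>
  </parallel>
</scxml>
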