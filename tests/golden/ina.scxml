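<?xml version="1.0" encoding="UTF-8"?>
<scxml xmlns="http://www.w3.org/2005/07/scxml" version="1.0" datamodel="ecmascript" initial="0">
  <datamodel>
    <data id="A1" expr="false" />
    <data id="A2" expr="false" />
    <data id="A3" expr="false" />
    <data id="NNC" expr="true" />
  </datamodel>
  <state id="0">
    <transition event="e1" target="1" />
    <transition event="e2" target="2" />
  </state>
  <state id="1">
    <transition event="e3" target="3" />
  </state>
  <state id="2">
    <transition event="e4" target="3" />
  </state>
  <state id="3">
    <transition event="e5" target="4" />
  </state>
  <state id="4">
    <transition event="e6" cond="NNC" target="12" />
    <transition event="e7" cond="NNC" target="12" />
    <transition event="e8" cond="NNC" target="12" />
    <transition event="e9" cond="NNC" target="12" />
    <transition event="e10" target="C" />
    <transition event="e11" target="6" />
    <transition event="e12" target="5" />
    <transition event="e13" target="7" />
  </state>
  <state id="5">
    <transition event="e16" target="17" />
    <transition event="e16" target="8" />
    <transition event="e18" target="C" />
  </state>
  <state id="6">
    <transition event="e14" target="16" />
    <transition event="e14" target="8" />
    <transition event="e15" target="17" />
    <transition event="e15" target="8" />
  </state>
  <state id="7">
    <transition event="e17" target="16" />
    <transition event="e17" target="8" />
  </state>
  <state id="12">
    <onentry>
      <assign location="NNC" expr="false" />
    </onentry>
    <transition event="e33" target="18" />
    <transition event="e34" target="19" />
  </state>
  <state id="C" initial="11">
    <transition event="e33" cond="!NNC" target="18" />
    <transition event="e34" cond="!NNC" target="19" />
    <state id="11">
      <transition event="e24" cond="NNC" target="13" />
      <transition event="e25" cond="NNC" target="13" />
      <transition event="e26" cond="NNC" target="13" />
      <transition event="e27" cond="A1 &amp;&amp; A2 &amp;&amp; A3 &amp;&amp; NNC" target="14" />
      <transition event="e28" cond="NNC" target="15" />
      <transition event="e38" cond="NNC" target="15" />
      <transition event="e30" target="11">
        <assign location="A1" expr="true" />
      </transition>
      <transition event="e31" target="11">
        <assign location="A2" expr="true" />
      </transition>
      <transition event="e32" target="11">
        <assign location="A3" expr="true" />
      </transition>
    </state>
    <state id="13">
      <onentry>
        <assign location="NNC" expr="false" />
      </onentry>
    </state>
    <state id="14">
      <onentry>
        <assign location="NNC" expr="false" />
      </onentry>
    </state>
    <state id="15">
      <onentry>
        <assign location="NNC" expr="false" />
      </onentry>
    </state>
  </state>
  <parallel id="D">
    <transition event="e22" target="C" />
    <transition event="e23" target="19" />
    <transition event="e29" cond="NNC" target="15" />
    <state id="A" initial="17">
      <state id="17">
        <transition event="e19" target="16" />
      </state>
      <state id="16" />
    </state>
    <state id="B" initial="8">
      <state id="8">
        <transition event="e20" target="9" />
      </state>
      <state id="9">
        <transition event="e21" target="10" />
        <transition event="e35" target="11" />
      </state>
      <state id="10">
        <transition event="e36" target="11" />
        <transition event="e37" target="19" />
      </state>
    </state>
  </parallel>
  <state id="18" />
  <state id="19" />
</scxml>
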