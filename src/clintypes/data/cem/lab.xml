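<cetype kind="statement" name="LabAssert" xmlns="">
  <key code="Assertion_KEY_ECID" />
  <data domain="LabType_VALUESET_ECID" type="pq" />
  <qual card="0-1" name="labValue" type="LabValue" />
  <qual card="0-1" name="deltaFlag" type="LabDeltaFlag" />
  <qual card="0-1" name="referenceRangeNarrative" type="LabReferenceRange" />
  <mod card="0-1" name="subject" type="Subject" />
  <mod card="0-1" name="negationInd" type="NegationInd" />
  <mod card="0-1" name="uncertainty" type="Uncertainty" />
  <att card="0-1" name="observed" type="Observed" />
  <att card="0-1" name="reportedReceived" type="ReportedReceived" />
  <att card="0-1" name="verified" type="Verified" />
</cetype>
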