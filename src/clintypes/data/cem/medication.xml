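<cetype kind="statement" name="MedicationAssert" xmlns="">
  <key code="Assertion_KEY_ECID" />
  <data domain="MedicationType_VALUESET_ECID" type="cwe" />
  <qual card="0-1" name="medicationStrength" type="MedicationStrength" />
  <qual card="0-1" name="medicationDosage" type="MedicationDosage" />
  <qual card="0-1" name="medicationDuration" type="MedicationDuration" />
  <qual card="0-1" name="medicationForm" type="MedicationForm" />
  <qual card="0-1" name="medicationFrequency" type="MedicationFrequency" />
  <qual card="0-1" name="medicationRoute" type="MedicationRoute" />
  <qual card="0-1" name="medicationStatusChange" type="MedicationStatusChange" />
  <mod card="0-1" name="subject" type="Subject" />
  <mod card="0-1" name="negationInd" type="NegationInd" />
  <mod card="0-1" name="uncertainty" type="Uncertainty" />
  <att card="0-1" name="observed" type="Observed" />
  <att card="0-1" name="reportedReceived" type="ReportedReceived" />
  <att card="0-1" name="verified" type="Verified" />
</cetype>
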