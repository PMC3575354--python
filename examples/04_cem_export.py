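"""Parse and write the cetype XML dialect, and export a resolved element
as a CEM instance."""

import clintypes as ct

# The shipped sign/symptom model (the CoughAssert pattern):
model = ct.default_models()["refsem.SignSymptom"]
print(f"model {model.name}: key={model.key_code}, "
      f"data {model.data_domain} ({model.data_type})")
print("qualifiers:", [(s.name, s.card) for s in model.quals])
print("modifiers:", [s.name for s in model.mods])
print("attributions:", [s.name for s in model.atts])
# Qualifiers refine the value without changing its meaning; modifiers
# (negationInd, uncertainty) change it; attributions give action context.

print("\nwrite∘parse is the identity:",
      ct.parse_cetype_xml(ct.write_cetype_xml(model)) == model)

# Resolve the worked example and export the cough element:
store = ct.resolve_document(ct.worked_example_store())
cough = ct.resolved_elements(store)[0]
instance = ct.element_to_cem(cough, store)
print("\n" + ct.write_cem_instance_xml(instance))
# The concept code is the data value; the attached severity becomes a
# qualifier; an affirmed element carries no negationInd modifier.
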