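"""Build a per-document annotation store, query it through the
subsumption-aware indices, and round-trip it through canonical JSON."""

import clintypes as ct

registry = ct.default_registry()
store = ct.DocumentStore(registry, text="Patient reports chest pain today.")

# Spanned mention with a ranked concept hypothesis (pain, C0030193/T184):
concept = store.add("refsem.UMLSConcept", features={
    "code": "C0030193", "codingScheme": "UMLS",
    "cui": "C0030193", "tui": "T184"})
pain = store.add("textsem.EventMention", span=(22, 26), features={
    "typeID": 3, "polarity": 1,
    "ontologyConceptArr": [ct.Ref(concept)]})
store.add("textspan.Sentence", span=(0, 33), features={"sentenceNumber": 0})

print("covered text:", store.covered_text(pain))

# Querying a supertype returns subtype instances too — the mention is
# indexed under EventMention, IdentifiedAnnotation and the span root:
for type_name in ("textsem.EventMention", "textsem.IdentifiedAnnotation"):
    print(type_name, "->",
          [store.covered_text(i) for i in store.get_by_type(type_name)])

# Window queries are by full containment over half-open offsets:
inside = store.select_covered("textsem.IdentifiedAnnotation", 0, 33)
print("mentions inside the sentence:", [store.covered_text(i) for i in inside])

# Serialization is canonical: equal stores give byte-identical JSON.
text = store.serialize()
clone = ct.DocumentStore.deserialize(text, registry)
print("round trip is identity:", clone == store)
print("byte-stable:", clone.serialize() == text)
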