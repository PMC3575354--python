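"""Run the mention-to-element bridge over the packaged worked example and
walk the resulting referential-semantics layer."""

import clintypes as ct

store = ct.worked_example_store()
print(repr(store.text))

chains = ct.build_coref_chains(store)
print("coreference chains:",
      [[store.covered_text(m) for m in c.mention_ids] for c in chains])
# The two cough mentions share one chain; fever and expectoration are
# singletons.

ct.resolve_document(store)

for element in ct.resolved_elements(store):
    mentions = [store.covered_text(store.deref(r))
                for r in element.features["mention"]]
    concept = store.deref(element.features.get("ontologyConcept"))
    print(f"\n{element.type_name}  mentions={mentions}")
    print(f"  polarity={element.features['polarity']}  "
          f"cui={concept.features['cui'] if concept else None}")
    severity = store.deref(element.features.get("severity"))
    if severity is not None:
        print(f"  severity={severity.features['value']}")
    start = store.deref(element.features.get("startTime"))
    if start is not None:
        print(f"  startTime={start.features['normalizedForm']}")
# The cough element aggregates both mentions: severity from the "severe"
# modifier, start time from "2 days ago" anchored to the 2006-09-03
# document date.

for rel in store.get_by_type("relation.ManifestationOf"):
    a, b = (store.deref(rel.features[s]) for s in ("arg1", "arg2"))
    print(f"\n{rel.type_name}: {a.type_name} -> {b.type_name} "
          f"polarity={rel.features['polarity']}")
# polarity -1: the cough is explicitly NOT manifesting with expectoration.
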