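"""Generate synthetic annotated documents and check the pipeline algebra
that holds on them."""

import clintypes as ct

spec = ct.FixtureSpec(seed=11, n_sentences=4, coref_rate=0.6,
                      negation_rate=0.3, relative_date_rate=0.4)
store = ct.generate(spec)
print(store.text)
print(f"{len(store)} annotations, violations: {len(store.validate())}")

# Generation is a pure function of the spec:
print("deterministic:",
      store.serialize() == ct.generate(spec).serialize())

chains = ct.build_coref_chains(store)
ct.resolve_document(store)
elements = ct.resolved_elements(store)
print(f"chains={len(chains)}  elements={len(elements)}")
# One element per chain: the partition property of resolution.

negated = sum(e.features["polarity"] == -1 for e in elements)
print(f"negated elements: {negated}/{len(elements)}")
# With negation_rate=1.0 every mention, and hence every element, would be
# negated; at 0.3 roughly a third of the singleton chains are.
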