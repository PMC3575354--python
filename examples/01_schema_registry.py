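"""Inspect the shipped type inventory: the namespace matrix and the
inheritance tree behind it."""

import clintypes as ct

registry = ct.default_registry()

print(registry.schema_stats().as_table())
print(f"features per type: {registry.schema_stats().features_per_type}")
# 100 types / 207 declared features across the 7 namespaces.

print("\ncore CEM types:", ", ".join(registry.core_cems()))

# Subsumption answers "is an X also a Y?" over the single-inheritance tree:
for ancestor, descendant in [
        ("textsem.IdentifiedAnnotation", "textsem.EventMention"),
        ("refsem.Element", "refsem.SignSymptom"),
        ("refsem.Entity", "refsem.Event")]:
    print(f"{ancestor} subsumes {descendant}: "
          f"{registry.subsumes(ancestor, descendant)}")
# Entity does not subsume Event: they are sibling subtypes of Element
# (non-temporal vs temporal real-world referents).

# Validation returns violations rather than raising:
bad = ct.AnnotationInstance("refsem.Course", features={"value": "oscillating"})
print("\nviolations for Course='oscillating':")
for violation in registry.validate_instance(bad):
    print(" -", violation)
print("allowed:", sorted(ct.allowed_values("refsem.Course")))
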