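"""Per-document annotation container with subsumption-aware indices.

A :class:`DocumentStore` plays the role UIMA's Common Analysis Structure
plays in a pipeline: it holds the document text, typed annotation instances,
and per-type indices that include subtypes, so that querying for a supertype
(say ``textsem.IdentifiedAnnotation``) returns every mention subtype as
well. Stores are build-once: instances can be added and their features
updated, but never deleted, and ids are never reused.

Offsets are 0-based, half-open, counted over Unicode code points.
Serialization is canonical — sorted keys, instances ordered by id — so two
equal stores produce byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

from .errors import StoreError
from .schema import SchemaRegistry
from .values import Ref, decode_value, encode_value


@dataclass
class AnnotationInstance:
    """One typed object in a document: an optional text span, a feature map,
    and a document-unique id (None until added to a store)."""

    type_name: str
    begin: Optional[int] = None
    end: Optional[int] = None
    features: dict[str, Any] = field(default_factory=dict)
    id: Optional[int] = None

    @property
    def span(self) -> Optional[tuple[int, int]]:
        if self.begin is None:
            return None
        return (self.begin, self.end)


class DocumentStore:
    """Document text plus typed instances and type-subsumption indices."""

    def __init__(self, registry: SchemaRegistry, text: str = "",
                 metadata: Optional[dict] = None):
        self.registry = registry
        self.text = text
        self.metadata: dict[str, Any] = dict(metadata or {})
        self._instances: dict[int, AnnotationInstance] = {}
        self._index: dict[str, list[tuple]] = {}
        self._next_id = 1

    # -------------------------------------------------------------- helpers
    def __len__(self) -> int:
        return len(self._instances)

    def __iter__(self) -> Iterator[AnnotationInstance]:
        return iter(sorted(self._instances.values(), key=lambda i: i.id))

    def __contains__(self, inst_id: int) -> bool:
        return inst_id in self._instances

    def get(self, inst_id: int) -> AnnotationInstance:
        try:
            return self._instances[inst_id]
        except KeyError:
            raise StoreError(f"no instance with id {inst_id}") from None

    def covered_text(self, instance_or_id) -> str:
        inst = (instance_or_id if isinstance(instance_or_id, AnnotationInstance)
                else self.get(instance_or_id))
        if inst.begin is None:
            raise StoreError(f"instance {inst.id} ({inst.type_name}) has no span")
        return self.text[inst.begin:inst.end]

    def deref(self, value):
        """Follow a Ref (or return None for None)."""
        if value is None:
            return None
        if not isinstance(value, Ref):
            raise StoreError(f"not a reference: {value!r}")
        return self.get(value.id)

    def _resolver(self, inst_id: int) -> Optional[str]:
        inst = self._instances.get(inst_id)
        return None if inst is None else inst.type_name

    # ------------------------------------------------------------ mutation
    def add(self, type_name: str, span: Optional[tuple[int, int]] = None,
            features: Optional[dict[str, Any]] = None) -> int:
        """Validate and add an instance; returns its new id. The instance is
        indexed under its own type and every ancestor type."""
        begin, end = (span if span is not None else (None, None))
        inst = AnnotationInstance(type_name=type_name, begin=begin, end=end,
                                  features=dict(features or {}))
        violations = self.registry.validate_instance(
            inst, text_length=len(self.text), resolver=self._resolver)
        if violations:
            raise StoreError(
                f"cannot add {type_name}: {'; '.join(violations)}",
                violations=violations)
        inst.id = self._next_id
        self._next_id += 1
        self._instances[inst.id] = inst
        key = ((inst.begin, inst.end, inst.id)
               if self.registry.lookup(type_name).spanned else (inst.id,))
        for ancestor in self.registry.ancestors(type_name):
            self._index.setdefault(ancestor, []).append(key)
        return inst.id

    def set_feature(self, inst_id: int, name: str, value: Any) -> None:
        """Update one feature on an existing instance, re-validating it."""
        inst = self.get(inst_id)
        old = inst.features.get(name)
        inst.features[name] = value
        violations = self.registry.validate_instance(
            inst, text_length=len(self.text), resolver=self._resolver)
        if violations:
            if old is None:
                inst.features.pop(name, None)
            else:
                inst.features[name] = old
            raise StoreError(
                f"cannot set {inst.type_name}:{name}: {'; '.join(violations)}",
                violations=violations)

    # -------------------------------------------------------------- queries
    def get_by_type(self, type_name: str,
                    include_subtypes: bool = True) -> list[AnnotationInstance]:
        """Instances of a type (optionally restricted to the exact type).
        Spanned results are ordered by (begin, end, id); unspanned by id."""
        self.registry.lookup(type_name)
        if include_subtypes:
            keys = sorted(self._index.get(type_name, ()))
            return [self._instances[k[-1]] for k in keys]
        out = [i for i in self._instances.values() if i.type_name == type_name]
        if self.registry.lookup(type_name).spanned:
            out.sort(key=lambda i: (i.begin, i.end, i.id))
        else:
            out.sort(key=lambda i: i.id)
        return out

    def select_covered(self, type_name: str, begin: int,
                       end: int) -> list[AnnotationInstance]:
        """Spanned instances of the (subsumed) type lying fully inside the
        half-open window [begin, end)."""
        if not (0 <= begin <= end <= len(self.text)):
            raise StoreError(f"window [{begin},{end}) out of range for "
                             f"document of length {len(self.text)}")
        if not self.registry.lookup(type_name).spanned:
            raise StoreError(f"{type_name} is unspanned; select_covered "
                             f"applies to spanned types")
        return [inst for inst in self.get_by_type(type_name)
                if inst.begin >= begin and inst.end <= end]

    # -------------------------------------------------------- serialization
    def serialize(self) -> str:
        """Canonical JSON for the whole store (byte-stable for equal stores)."""
        annotations = []
        for inst in self:
            obj: dict[str, Any] = {"id": inst.id, "type": inst.type_name}
            if inst.begin is not None:
                obj["begin"] = inst.begin
                obj["end"] = inst.end
            obj["features"] = {k: encode_value(v)
                               for k, v in sorted(inst.features.items())
                               if v is not None}
            annotations.append(obj)
        doc = {"text": self.text, "metadata": self.metadata,
               "annotations": annotations}
        return json.dumps(doc, sort_keys=True, indent=2) + "\n"

    @classmethod
    def deserialize(cls, text: str, registry: SchemaRegistry) -> "DocumentStore":
        """Parse the document JSON dialect, re-validating every instance and
        every reference."""
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise StoreError(f"malformed document JSON: {exc}") from None
        if not isinstance(doc, dict) or "text" not in doc:
            raise StoreError("document JSON must be an object with a "
                             "'text' key")
        store = cls(registry, text=doc["text"],
                    metadata=doc.get("metadata", {}))
        annotations = doc.get("annotations", [])
        for obj in annotations:
            try:
                inst = AnnotationInstance(
                    type_name=obj["type"], begin=obj.get("begin"),
                    end=obj.get("end"),
                    features={k: decode_value(v)
                              for k, v in obj.get("features", {}).items()},
                    id=int(obj["id"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise StoreError(f"malformed annotation object: {exc}") from None
            if inst.id in store._instances:
                raise StoreError(f"duplicate annotation id {inst.id}")
            store._instances[inst.id] = inst
        # validate after all ids are present so forward references resolve
        for inst in store._instances.values():
            violations = registry.validate_instance(
                inst, text_length=len(store.text), resolver=store._resolver)
            if violations:
                raise StoreError(
                    f"annotation {inst.id}: {'; '.join(violations)}",
                    violations=violations)
            key = ((inst.begin, inst.end, inst.id)
                   if registry.lookup(inst.type_name).spanned else (inst.id,))
            for ancestor in registry.ancestors(inst.type_name):
                store._index.setdefault(ancestor, []).append(key)
        store._next_id = max(store._instances, default=0) + 1
        return store

    def validate(self) -> list[str]:
        """Violations across all instances (empty list = store conforms)."""
        out = []
        for inst in self:
            for v in self.registry.validate_instance(
                    inst, text_length=len(self.text), resolver=self._resolver):
                out.append(f"annotation {inst.id}: {v}")
        return out

    # -------------------------------------------------------------- equality
    def __eq__(self, other) -> bool:
        if not isinstance(other, DocumentStore):
            return NotImplemented
        return (self.text == other.text and self.metadata == other.metadata
                and self._as_comparable() == other._as_comparable())

    def _as_comparable(self):
        return {i.id: (i.type_name, i.begin, i.end,
                       {k: v for k, v in i.features.items() if v is not None})
                for i in self._instances.values()}
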