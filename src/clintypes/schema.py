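"""Meta-level schema registry for the clinical annotation type system.

The registry holds :class:`TypeDescriptor` entries for the seven namespaces
(structured, util, textspan, syntax, textsem, refsem, relation), answers
subsumption queries over the single-inheritance type tree, validates
annotation instances against their declared features, and computes the
per-namespace type/feature matrix.

Two root markers close the inheritance tree: ``SPAN_ROOT`` for spanned
(textual) annotations carrying begin/end character offsets, and ``TOP`` for
unspanned, document-level objects (the referential-semantics and relation
families). A type is spanned iff its supertype chain terminates at
``SPAN_ROOT``.

The on-disk schema dialect is JSON-lines: one type object per line,
``{"name", "namespace", "supertype", "spanned", "features": [{"name",
"range"}]}``, supertypes declared before their subtypes. Feature ranges are
``boolean``, ``integer``, ``float``, ``string``, ``stringarray``,
``ref:<qualified name>`` or ``refarray:<qualified name>``; a ref target may
also be a root marker (``ref:SPAN_ROOT`` accepts any spanned annotation).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from .errors import SchemaError
from .values import Ref

TOP = "TOP"
SPAN_ROOT = "SPAN_ROOT"
ROOT_MARKERS = frozenset({TOP, SPAN_ROOT})

NAMESPACES = ("structured", "util", "textspan", "syntax",
              "textsem", "refsem", "relation")

PRIMITIVE_RANGES = frozenset({"boolean", "integer", "float", "string",
                              "stringarray"})

_SCHEMA_KEY_ORDER = ("name", "namespace", "supertype", "spanned", "features",
                     "coreCem", "reconstructed")
_FEATURE_KEY_ORDER = ("name", "range", "reconstructed")


def _range_target(range_str: str) -> Optional[str]:
    """Return the reference target of a range string, or None for primitives."""
    if range_str.startswith("ref:"):
        return range_str[4:]
    if range_str.startswith("refarray:"):
        return range_str[9:]
    return None


@dataclass(frozen=True)
class FeatureDescriptor:
    """A feature declared on exactly one type (inherited features are not
    re-declared)."""

    name: str
    range: str
    declaring_type: str
    reconstructed: bool = False

    def __post_init__(self):
        if self.range not in PRIMITIVE_RANGES and _range_target(self.range) is None:
            raise SchemaError(
                f"feature {self.declaring_type}:{self.name} has unknown "
                f"range {self.range!r}")

    @property
    def is_reference(self) -> bool:
        return self.range.startswith(("ref:", "refarray:"))

    @property
    def is_array(self) -> bool:
        return self.range in ("stringarray",) or self.range.startswith("refarray:")

    @property
    def target(self) -> Optional[str]:
        return _range_target(self.range)


@dataclass(frozen=True)
class TypeDescriptor:
    """One entry in the type inventory: a qualified name, its namespace, a
    single supertype (or root marker), and the features it declares."""

    qualified_name: str
    namespace: str
    supertype: str
    features: tuple[FeatureDescriptor, ...]
    spanned: bool
    core_cem: bool = False
    reconstructed: bool = False

    @property
    def name(self) -> str:
        return self.qualified_name.split(".", 1)[1]


@dataclass
class SchemaRegistry:
    """The registered type inventory plus subsumption and feature indices.

    ``constants`` optionally carries the value-set/constraint tables from the
    shipped constants file; an empty dict disables value-set checking (used
    by ad-hoc registries in tests).
    """

    types: dict[str, TypeDescriptor] = field(default_factory=dict)
    constants: dict[str, Any] = field(default_factory=dict)
    _subtypes: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _all_features: dict[str, dict[str, FeatureDescriptor]] = field(
        default_factory=dict, repr=False)

    # ------------------------------------------------------------- registry
    def register_type(self, descriptor: TypeDescriptor) -> "SchemaRegistry":
        qn = descriptor.qualified_name
        if descriptor.namespace not in NAMESPACES:
            raise SchemaError(f"unknown namespace {descriptor.namespace!r} "
                              f"for type {qn}")
        if not qn.startswith(descriptor.namespace + "."):
            raise SchemaError(f"qualified name {qn} does not match "
                              f"namespace {descriptor.namespace}")
        if qn in self.types:
            raise SchemaError(f"duplicate type name {qn}")
        sup = descriptor.supertype
        if sup not in ROOT_MARKERS and sup not in self.types:
            raise SchemaError(f"unknown supertype {sup!r} for type {qn}")
        # spanned-ness is inherited from the root of the supertype chain
        expected_spanned = (sup == SPAN_ROOT if sup in ROOT_MARKERS
                            else self.types[sup].spanned)
        if descriptor.spanned != expected_spanned:
            raise SchemaError(
                f"type {qn} declares spanned={descriptor.spanned} but its "
                f"supertype chain implies spanned={expected_spanned}")
        inherited = (self._all_features.get(sup, {}) if sup not in ROOT_MARKERS
                     else {})
        own: dict[str, FeatureDescriptor] = {}
        for feat in descriptor.features:
            if feat.name in own:
                raise SchemaError(f"feature {feat.name!r} declared twice "
                                  f"on {qn}")
            if feat.name in inherited:
                raise SchemaError(f"feature {feat.name!r} on {qn} re-declares "
                                  f"an inherited feature")
            own[feat.name] = feat
        self.types[qn] = descriptor
        self._all_features[qn] = {**inherited, **own}
        self._subtypes.setdefault(qn, set())
        if sup not in ROOT_MARKERS:
            self._subtypes[sup].add(qn)
        return self

    def lookup(self, qualified_name: str) -> TypeDescriptor:
        try:
            return self.types[qualified_name]
        except KeyError:
            raise SchemaError(f"unknown type {qualified_name!r}") from None

    def subsumes(self, ancestor: str, descendant: str) -> bool:
        """True iff ``descendant`` equals ``ancestor`` or ``ancestor`` lies on
        its supertype chain (reflexive, transitive, antisymmetric)."""
        self.lookup(ancestor)
        current = self.lookup(descendant)
        while True:
            if current.qualified_name == ancestor:
                return True
            if current.supertype in ROOT_MARKERS:
                return False
            current = self.types[current.supertype]

    def ancestors(self, qualified_name: str) -> list[str]:
        """The supertype chain from the type itself up to (excluding) the
        root marker, nearest first."""
        chain = []
        current = self.lookup(qualified_name)
        while True:
            chain.append(current.qualified_name)
            if current.supertype in ROOT_MARKERS:
                return chain
            current = self.types[current.supertype]

    def descendants(self, qualified_name: str) -> set[str]:
        """The type itself and all transitive subtypes."""
        self.lookup(qualified_name)
        out, stack = set(), [qualified_name]
        while stack:
            qn = stack.pop()
            if qn not in out:
                out.add(qn)
                stack.extend(self._subtypes.get(qn, ()))
        return out

    def all_features(self, qualified_name: str) -> dict[str, FeatureDescriptor]:
        """Declared plus inherited features of a type, by name."""
        self.lookup(qualified_name)
        return dict(self._all_features[qualified_name])

    def core_cems(self) -> list[str]:
        return sorted(qn for qn, d in self.types.items() if d.core_cem)

    # ----------------------------------------------------------- validation
    def validate_registry(self) -> None:
        """Check that every feature's reference range resolves."""
        for qn, desc in self.types.items():
            for feat in desc.features:
                target = feat.target
                if target is not None and target not in ROOT_MARKERS \
                        and target not in self.types:
                    raise SchemaError(
                        f"feature {qn}:{feat.name} references unregistered "
                        f"type {target!r}")

    def validate_instance(self, instance, *, text_length: Optional[int] = None,
                          resolver: Optional[Callable[[int], Optional[str]]] = None,
                          ) -> list[str]:
        """Return the list of schema violations for one annotation instance
        (an empty list means the instance conforms).

        ``instance`` needs ``type_name``, ``begin``, ``end`` and ``features``
        attributes. ``resolver`` maps a referenced id to its type name (or
        None for a dangling id) and enables reference-target checking;
        without it only the shape of reference values is checked.
        """
        violations: list[str] = []
        tn = getattr(instance, "type_name")
        if tn not in self.types:
            return [f"unknown type {tn!r}"]
        desc = self.types[tn]
        begin, end = instance.begin, instance.end
        has_span = begin is not None or end is not None
        if desc.spanned and not (begin is not None and end is not None):
            violations.append(f"{tn} is spanned but instance has no span")
        elif not desc.spanned and has_span:
            violations.append(f"{tn} is unspanned but instance carries "
                              f"begin/end offsets")
        elif desc.spanned:
            if not (isinstance(begin, int) and isinstance(end, int)):
                violations.append(f"{tn} span offsets must be integers")
            elif not 0 <= begin <= end:
                violations.append(f"{tn} span [{begin},{end}) is not a valid "
                                  f"half-open offset pair")
            elif text_length is not None and end > text_length:
                violations.append(f"{tn} span [{begin},{end}) exceeds "
                                  f"document length {text_length}")
        declared = self._all_features[tn]
        for name, value in instance.features.items():
            feat = declared.get(name)
            if feat is None:
                violations.append(f"feature {name!r} not declared on {tn} "
                                  f"or an ancestor")
                continue
            violations.extend(self._check_value(tn, feat, value, resolver))
        violations.extend(self._check_constants(tn, instance.features))
        return violations

    def _check_value(self, tn, feat: FeatureDescriptor, value,
                     resolver) -> list[str]:
        label = f"{tn}:{feat.name}"
        rng = feat.range
        if value is None:
            return []
        if rng == "boolean":
            return [] if isinstance(value, bool) else \
                [f"{label} expects boolean, got {value!r}"]
        if rng == "integer":
            return [] if isinstance(value, int) and not isinstance(value, bool) \
                else [f"{label} expects integer, got {value!r}"]
        if rng == "float":
            return [] if isinstance(value, (int, float)) and not isinstance(value, bool) \
                else [f"{label} expects float, got {value!r}"]
        if rng == "string":
            return [] if isinstance(value, str) else \
                [f"{label} expects string, got {value!r}"]
        if rng == "stringarray":
            if not (isinstance(value, list)
                    and all(isinstance(v, str) for v in value)):
                return [f"{label} expects an array of strings, got {value!r}"]
            return []
        # reference ranges
        if rng.startswith("ref:"):
            items, single = [value], True
        else:
            if not isinstance(value, list):
                return [f"{label} expects an array of references, got {value!r}"]
            items, single = value, False
        out = []
        for item in items:
            if not isinstance(item, Ref):
                out.append(f"{label} expects a reference, got {item!r}")
                continue
            if resolver is None:
                continue
            target_tn = resolver(item.id)
            if target_tn is None:
                out.append(f"{label} references missing id {item.id}")
            elif not self._target_ok(feat.target, target_tn):
                out.append(f"{label} must reference {feat.target}, "
                           f"got {target_tn} (id {item.id})")
        del single
        return out

    def _target_ok(self, target: str, target_tn: str) -> bool:
        if target == TOP:
            return not self.types[target_tn].spanned
        if target == SPAN_ROOT:
            return self.types[target_tn].spanned
        return self.subsumes(target, target_tn)

    def _check_constants(self, tn: str, features: dict) -> list[str]:
        if not self.constants:
            return []
        out = []
        value_sets = self.constants.get("valueSets", {})
        for vs_type, allowed in value_sets.items():
            if vs_type in self.types and self.subsumes(vs_type, tn):
                value = features.get("value")
                if value is not None and value not in allowed:
                    out.append(f"{tn}:value {value!r} not in allowed set "
                               f"{sorted(allowed)}")
        for fname, domain in self.constants.get("featureDomains", {}).items():
            value = features.get(fname)
            if value is not None and value not in domain:
                out.append(f"{tn}:{fname} {value!r} not in {domain}")
        for fname in self.constants.get("unitIntervalFeatures", ()):
            value = features.get(fname)
            if value is not None and isinstance(value, (int, float)) \
                    and not isinstance(value, bool) and not 0 <= value <= 1:
                out.append(f"{tn}:{fname} {value!r} outside [0, 1]")
        patterns = self.constants.get("patterns", {})
        for fname in ("cui", "tui"):
            pattern = patterns.get(fname)
            value = features.get(fname)
            if pattern and isinstance(value, str) \
                    and not re.fullmatch(pattern, value):
                out.append(f"{tn}:{fname} {value!r} does not match "
                           f"{pattern}")
        return out

    # ------------------------------------------------------------ statistics
    def schema_stats(self) -> "SchemaStats":
        rows = {ns: [0, 0] for ns in NAMESPACES}
        for desc in self.types.values():
            rows[desc.namespace][0] += 1
            rows[desc.namespace][1] += len(desc.features)
        return SchemaStats(rows={ns: tuple(c) for ns, c in rows.items()})


@dataclass(frozen=True)
class SchemaStats:
    """Per-namespace (type count, declared feature count) matrix. Features
    are counted once, at the type that declares them; inherited features are
    never double-counted."""

    rows: dict[str, tuple[int, int]]

    @property
    def total_types(self) -> int:
        return sum(c[0] for c in self.rows.values())

    @property
    def total_features(self) -> int:
        return sum(c[1] for c in self.rows.values())

    @property
    def features_per_type(self) -> float:
        return round(self.total_features / self.total_types, 2)

    def as_table(self) -> str:
        width = max(len(ns) for ns in self.rows) + 2
        lines = [f"{'namespace':<{width}}{'types':>7}{'features':>10}"]
        for ns in NAMESPACES:
            tc, fc = self.rows[ns]
            lines.append(f"{ns:<{width}}{tc:>7}{fc:>10}")
        lines.append(f"{'total':<{width}}{self.total_types:>7}"
                     f"{self.total_features:>10}")
        return "\n".join(lines)


# ------------------------------------------------------------------ file I/O
def _descriptor_from_json(obj: dict, lineno: int) -> TypeDescriptor:
    try:
        ns, name = obj["namespace"], obj["name"]
        features = tuple(
            FeatureDescriptor(name=f["name"], range=f["range"],
                              declaring_type=f"{ns}.{name}",
                              reconstructed=bool(f.get("reconstructed", False)))
            for f in obj.get("features", ()))
        return TypeDescriptor(
            qualified_name=f"{ns}.{name}", namespace=ns,
            supertype=obj["supertype"], features=features,
            spanned=bool(obj["spanned"]),
            core_cem=bool(obj.get("coreCem", False)),
            reconstructed=bool(obj.get("reconstructed", False)))
    except KeyError as exc:
        raise SchemaError(f"line {lineno}: missing key {exc}") from None


def load_schema(source, constants: Optional[dict] = None) -> SchemaRegistry:
    """Load a JSON-lines schema file (path, str content, or text file)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = str(source)
        if "\n" in source or source.lstrip().startswith("{"):
            text = source
        else:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
    registry = SchemaRegistry(constants=dict(constants or {}))
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"line {lineno}: {exc}") from None
        registry.register_type(_descriptor_from_json(obj, lineno))
    registry.validate_registry()
    return registry


def _descriptor_to_json(desc: TypeDescriptor) -> dict:
    features = []
    for feat in desc.features:
        entry = {"name": feat.name, "range": feat.range}
        if feat.reconstructed:
            entry["reconstructed"] = True
        features.append(entry)
    obj = {"name": desc.name, "namespace": desc.namespace,
           "supertype": desc.supertype, "spanned": desc.spanned,
           "features": features}
    if desc.core_cem:
        obj["coreCem"] = True
    if desc.reconstructed:
        obj["reconstructed"] = True
    return obj


def dump_schema(registry: SchemaRegistry, destination=None) -> str:
    """Serialize a registry to the canonical JSON-lines form (types in
    registration order, fixed key order) and optionally write it out.
    ``dump_schema`` then :func:`load_schema` is the identity on the canonical
    form of a schema file."""
    lines = [json.dumps(_descriptor_to_json(d)) for d in registry.types.values()]
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text
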