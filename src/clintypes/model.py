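"""Access to the normative type inventory shipped with the package.

The inventory covers 100 types across the 7 namespaces; slots that the
underlying clinical model describes only by budget are reconstructed
following cTAKES v2.5 conventions and flagged ``"reconstructed": true`` in
the schema file. The companion constants file carries the closed value sets
for the four shared clinical attributes (Severity, Course, BodySide,
BodyLaterality), the feature-domain constraints (polarity in {-1, 1},
uncertainty in {0, 1}), default feature values, the semantic-group
``typeID`` code table mapping mention groups onto the six core Clinical
Element Model types, and the relation-category vocabulary the resolution
bridge understands.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Optional

from .errors import SchemaError
from .schema import SchemaRegistry, load_schema
from .store import AnnotationInstance

ATTRIBUTE_ROOT = "refsem.Attribute"
ELEMENT_ROOT = "refsem.Element"


def _data_text(name: str) -> str:
    return (resources.files("clintypes") / "data" / name).read_text("utf-8")


@lru_cache(maxsize=1)
def load_constants() -> dict:
    return json.loads(_data_text("constants.json"))


@lru_cache(maxsize=1)
def default_registry() -> SchemaRegistry:
    """The shipped 100-type registry with constants attached. Cached; treat
    as read-only (build ad-hoc registries for experiments)."""
    return load_schema(_data_text("schema.jsonl"), constants=load_constants())


def type_id_codes(registry: Optional[SchemaRegistry] = None) -> dict[int, Optional[str]]:
    """The semantic-group code table: typeID integer -> core CEM type name
    (None for the unknown group)."""
    constants = (registry or default_registry()).constants or load_constants()
    return {int(k): v for k, v in constants["typeIdCodes"].items()}


def allowed_values(attribute_type: str,
                   registry: Optional[SchemaRegistry] = None) -> Optional[frozenset]:
    """The closed value set for a clinical attribute type, or None when the
    attribute is unconstrained (free string or number-with-units).

    Value sets are enforced by instance validation only for the four shared
    attributes; element-to-attribute links stay open so applications can
    extend the vocabulary.
    """
    registry = registry or default_registry()
    desc = registry.lookup(attribute_type)
    if not registry.subsumes(ATTRIBUTE_ROOT, desc.qualified_name):
        raise SchemaError(f"{attribute_type} is not a clinical attribute type")
    constants = registry.constants or load_constants()
    values = constants.get("valueSets", {}).get(attribute_type)
    return None if values is None else frozenset(values)


def make_default(type_name: str,
                 registry: Optional[SchemaRegistry] = None) -> AnnotationInstance:
    """An unattached instance of the type with documented defaults applied:
    polarity 1, uncertainty 0, conditional/generic false, subject "patient",
    and "unmarked" for value-set attributes whose set contains it (BodySide
    has no unmarked value and is left unset)."""
    registry = registry or default_registry()
    desc = registry.lookup(type_name)
    constants = registry.constants or load_constants()
    defaults = constants.get("defaults", {})
    features = {}
    for name, feat in registry.all_features(type_name).items():
        if name in defaults and not feat.is_reference:
            features[name] = defaults[name]
    if registry.subsumes(ATTRIBUTE_ROOT, type_name) \
            and "value" in registry.all_features(type_name):
        values = constants.get("valueSets", {}).get(type_name)
        if values and "unmarked" in values:
            features["value"] = "unmarked"
    return AnnotationInstance(type_name=type_name, features=features)
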