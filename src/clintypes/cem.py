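"""The cetype XML dialect and CEM instance export.

A Clinical Element Model (CEM) definition has a kind, a name, a key (a
coded value for the real-world concept being described), a data value
choice (a coded domain plus a value type such as ``cwe`` — coded with
extensions — or ``pq`` — physical quantity), and three ordered slot lists:
qualifiers (information that does not change the meaning of the value,
e.g. severity), modifiers (information that does, e.g. negationInd), and
attributions (context of an action, e.g. observed).

The internal refsem model flattens the qualifier/modifier/attribution
trichotomy into plain features; the shipped per-CEM model files restore the
classification on export. XML writing is canonical (fixed attribute order,
one child per line) so write∘parse is the identity on canonical files.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional
from xml.sax.saxutils import quoteattr

from .errors import CemError
from .model import load_constants
from .store import AnnotationInstance, DocumentStore

_CARD_RE = re.compile(r"^(\d+)-(\d+|M)$")
_SLOT_TAGS = ("qual", "mod", "att")


@dataclass(frozen=True)
class CemSlot:
    """One qualifier/modifier/attribution declaration."""

    name: str
    type: str
    card: str

    def __post_init__(self):
        if not _CARD_RE.match(self.card):
            raise CemError(f"bad cardinality {self.card!r} on slot "
                           f"{self.name!r}")

    @property
    def bounds(self) -> tuple[int, Optional[int]]:
        lo, hi = _CARD_RE.match(self.card).groups()
        return int(lo), (None if hi == "M" else int(hi))


@dataclass(frozen=True)
class CetypeModel:
    """A parsed cetype definition."""

    kind: str
    name: str
    key_code: str
    data_domain: str
    data_type: str
    quals: tuple[CemSlot, ...] = ()
    mods: tuple[CemSlot, ...] = ()
    atts: tuple[CemSlot, ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.quals + self.mods + self.atts]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CemError(f"duplicate slot names in model {self.name}: "
                           f"{sorted(dupes)}")

    def slot(self, name: str) -> Optional[tuple[str, CemSlot]]:
        for tag, slots in zip(_SLOT_TAGS, (self.quals, self.mods, self.atts)):
            for s in slots:
                if s.name == name:
                    return tag, s
        return None


def parse_cetype_xml(text: str) -> CetypeModel:
    """Parse a cetype definition from its XML dialect."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise CemError(f"malformed cetype XML: {exc}") from None
    if root.tag != "cetype":
        raise CemError(f"expected <cetype> root, got <{root.tag}>")
    key = data = None
    slots: dict[str, list[CemSlot]] = {tag: [] for tag in _SLOT_TAGS}
    for child in root:
        if child.tag == "key":
            key = child.get("code")
        elif child.tag == "data":
            data = (child.get("domain"), child.get("type"))
        elif child.tag in _SLOT_TAGS:
            missing = [a for a in ("name", "type", "card")
                       if child.get(a) is None]
            if missing:
                raise CemError(f"<{child.tag}> missing attributes {missing}")
            slots[child.tag].append(CemSlot(name=child.get("name"),
                                            type=child.get("type"),
                                            card=child.get("card")))
        else:
            raise CemError(f"unknown element <{child.tag}> in cetype "
                           f"{root.get('name')!r}")
    if key is None or data is None:
        raise CemError("cetype must declare <key> and <data>")
    return CetypeModel(kind=root.get("kind", ""), name=root.get("name", ""),
                       key_code=key, data_domain=data[0], data_type=data[1],
                       quals=tuple(slots["qual"]), mods=tuple(slots["mod"]),
                       atts=tuple(slots["att"]))


def write_cetype_xml(model: CetypeModel) -> str:
    """Canonical cetype XML: attribute order (kind, name, xmlns) on the
    root, (card, name, type) on slots, one element per line."""
    lines = [f'<cetype kind={quoteattr(model.kind)} '
             f'name={quoteattr(model.name)} xmlns="">']
    lines.append(f'  <key code={quoteattr(model.key_code)} />')
    lines.append(f'  <data domain={quoteattr(model.data_domain)} '
                 f'type={quoteattr(model.data_type)} />')
    for tag, slots in zip(_SLOT_TAGS, (model.quals, model.mods, model.atts)):
        for s in slots:
            lines.append(f'  <{tag} card={quoteattr(s.card)} '
                         f'name={quoteattr(s.name)} '
                         f'type={quoteattr(s.type)} />')
    lines.append("</cetype>")
    return "\n".join(lines) + "\n"


@lru_cache(maxsize=1)
def default_models() -> dict[str, CetypeModel]:
    """The shipped cetype model for each core CEM type, by refsem name."""
    mapping = load_constants()["cemModels"]
    out = {}
    for type_name, filename in mapping.items():
        text = (resources.files("clintypes") / "data" / "cem"
                / filename).read_text("utf-8")
        out[type_name] = parse_cetype_xml(text)
    return out


# ------------------------------------------------------------- CEM instances
@dataclass
class CemInstance:
    """One populated CEM: slot values keyed by slot name, each a list."""

    model_name: str
    key: str
    data_value: Optional[str] = None
    quals: dict[str, list[str]] = field(default_factory=dict)
    mods: dict[str, list[str]] = field(default_factory=dict)
    atts: dict[str, list[str]] = field(default_factory=dict)

    def validate(self, model: CetypeModel) -> None:
        """Check slot names and cardinalities against the model."""
        if self.model_name != model.name:
            raise CemError(f"instance of {self.model_name!r} checked "
                           f"against model {model.name!r}")
        groups = {"qual": self.quals, "mod": self.mods, "att": self.atts}
        for tag, values in groups.items():
            for name, items in values.items():
                found = model.slot(name)
                if found is None or found[0] != tag:
                    raise CemError(f"model {model.name} declares no {tag} "
                                   f"named {name!r}")
                lo, hi = found[1].bounds
                if len(items) < lo or (hi is not None and len(items) > hi):
                    raise CemError(
                        f"{model.name}:{name} has {len(items)} values but "
                        f"cardinality is {found[1].card}")


def _attribute_display(store: DocumentStore, attribute) -> str:
    value = attribute.features.get("value")
    if value is not None:
        return str(value)
    number = attribute.features.get("number")
    unit = attribute.features.get("unit")
    if number is not None:
        return f"{number} {unit}".strip()
    return ""


def element_to_cem(element: AnnotationInstance, store: DocumentStore,
                   model: Optional[CetypeModel] = None) -> CemInstance:
    """Export a resolved core-CEM element as a CEM instance.

    The data value is the element's disambiguated ontology-concept code;
    attribute references whose feature names match model qualifiers become
    qualifier values; negative polarity sets the negationInd modifier,
    uncertainty sets the uncertainty modifier, and the subject flag maps to
    the subject modifier.
    """
    registry = store.registry
    type_name = element.type_name
    if not registry.lookup(type_name).core_cem:
        raise CemError(f"{type_name} is not a core CEM type")
    default = default_models().get(type_name)
    if model is None:
        model = default
        if model is None:
            raise CemError(f"no shipped model for {type_name}")
    elif default is not None and model.name != default.name:
        raise CemError(f"model {model.name!r} does not match element type "
                       f"{type_name} (expected {default.name!r})")

    concept = store.deref(element.features.get("ontologyConcept"))
    data_value = concept.features.get("code") if concept is not None else None
    instance = CemInstance(model_name=model.name, key=model.key_code,
                           data_value=data_value)
    for slot in model.quals:
        raw = element.features.get(slot.name)
        if raw is None:
            continue
        refs = raw if isinstance(raw, list) else [raw]
        values = [_attribute_display(store, store.deref(r)) for r in refs]
        instance.quals[slot.name] = values
    defaults = load_constants()["defaults"]
    if element.features.get("polarity", defaults["polarity"]) == -1 \
            and model.slot("negationInd"):
        instance.mods["negationInd"] = ["true"]
    if element.features.get("uncertainty", defaults["uncertainty"]) == 1 \
            and model.slot("uncertainty"):
        instance.mods["uncertainty"] = ["true"]
    subject = element.features.get("subject")
    if subject is not None and model.slot("subject"):
        instance.mods["subject"] = [subject]
    instance.validate(model)
    return instance


def write_cem_instance_xml(instance: CemInstance) -> str:
    """Serialize a CEM instance in the artifact-defined <ceinst> dialect
    (child elements mirror the model's slot names)."""
    lines = [f'<ceinst model={quoteattr(instance.model_name)} '
             f'key={quoteattr(instance.key)}>']
    if instance.data_value is not None:
        lines.append(f'  <data>{_escape(instance.data_value)}</data>')
    for tag, group in zip(_SLOT_TAGS,
                          (instance.quals, instance.mods, instance.atts)):
        for name in sorted(group):
            for value in group[name]:
                lines.append(f'  <{tag} name={quoteattr(name)}>'
                             f'{_escape(value)}</{tag}>')
    lines.append("</ceinst>")
    return "\n".join(lines) + "\n"


def _escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))
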