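"""Mention-to-element resolution: from shallow text semantics to CEM-style
referential semantics.

Upstream NLP components leave a document with spanned mentions
(``textsem.EventMention``/``EntityMention``), modifiers, time expressions,
and text relations, including coreference links. This module performs the
resolution a deep-semantic consumer needs:

* group coreferring mentions into chains (connected components of the
  coreference graph; non-coreferring mentions form singleton chains);
* create one unspanned ``refsem`` Element per chain — the real-world object
  the mentions denote — choosing the core CEM subtype from the mentions'
  semantic-group ``typeID``;
* pick a single disambiguated ontology concept from the mentions' ranked
  hypothesis arrays;
* aggregate the context flags (polarity, conditional, uncertainty, generic,
  subject), resolving conflicts by policy;
* normalize relative time expressions ("2 days ago") against the document
  date into calendar-correct ``refsem.Time``/``refsem.Date`` objects and
  attach them as event start times;
* attach normalized attribute modifiers (severity, course, ...) to the
  element slots their types declare; and
* lift the remaining text relations to unspanned element relations,
  preserving polarity and uncertainty.

The bridge consumes coreference relations; it does not compute them from
raw text.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass
from typing import Optional

from dateutil.relativedelta import relativedelta

from .errors import BridgeError
from .model import load_constants, type_id_codes
from .store import DocumentStore
from .values import Ref

LAST_MENTION_WINS = "last-mention-wins"
ERROR = "error"

_MENTION_ROOT = "textsem.IdentifiedAnnotation"
_CONTEXT_FLAGS = ("polarity", "conditional", "uncertainty", "generic", "subject")


@dataclass(frozen=True)
class CorefChain:
    """Mentions referring to one real-world instance, in document order."""

    mention_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.mention_ids)


@dataclass(frozen=True)
class BridgeConfig:
    """Resolution knobs.

    ``conflict_policy`` decides what happens when coreferring mentions
    disagree on a context flag or semantic group: ``last-mention-wins``
    (clinical narrative tends to refine earlier statements) or ``error``.
    ``document_date_key`` names the store-metadata key holding the ISO
    document date used to anchor relative time expressions.
    """

    conflict_policy: str = LAST_MENTION_WINS
    document_date_key: str = "documentDate"
    date_patterns: tuple[str, ...] = ("ago", "yesterday", "today")

    def __post_init__(self):
        if self.conflict_policy not in (LAST_MENTION_WINS, ERROR):
            raise BridgeError(
                f"unknown conflict policy {self.conflict_policy!r}")


# --------------------------------------------------------------------- chains
def build_coref_chains(store: DocumentStore) -> list[CorefChain]:
    """Connected components of the coreference graph over mentions, plus
    singleton chains for every entity/event mention that corefers with
    nothing. Chains are ordered by their first mention's span."""
    registry = store.registry
    universe = {m.id for m in store.get_by_type("textsem.EntityMention")}
    universe |= {m.id for m in store.get_by_type("textsem.EventMention")}
    parent: dict[int, int] = {m: m for m in universe}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rel in store.get_by_type("relation.CoreferenceRelation"):
        ends = []
        for slot in ("arg1", "arg2"):
            arg = store.deref(rel.features.get(slot))
            if arg is None:
                raise BridgeError(f"coreference relation {rel.id} lacks {slot}")
            mention = store.deref(arg.features.get("argument"))
            if mention is None or not registry.subsumes(
                    _MENTION_ROOT, mention.type_name):
                raise BridgeError(
                    f"coreference relation {rel.id} argument is not an "
                    f"identified-annotation mention")
            ends.append(mention.id)
        for m in ends:
            parent.setdefault(m, m)
        parent[find(ends[0])] = find(ends[1])

    groups: dict[int, list[int]] = {}
    for m in parent:
        groups.setdefault(find(m), []).append(m)

    def span_key(mid: int):
        inst = store.get(mid)
        return (inst.begin, inst.end, inst.id)

    chains = [CorefChain(tuple(sorted(ms, key=span_key)))
              for ms in groups.values()]
    chains.sort(key=lambda c: span_key(c.mention_ids[0]))
    return chains


def _last_mention(chain: CorefChain, store: DocumentStore):
    return max((store.get(m) for m in chain.mention_ids),
               key=lambda i: (i.begin, i.end, i.id))


# -------------------------------------------------------------- element type
def select_element_type(chain: CorefChain, store: DocumentStore,
                        config: BridgeConfig = BridgeConfig()) -> str:
    """The refsem type the chain resolves to: the core CEM mapped from the
    mentions' semantic-group typeID, or plain Entity/Event when the group is
    unknown. A chain mixing entity and event mentions is an error."""
    registry = store.registry
    kinds = set()
    type_ids = []
    for mid in chain.mention_ids:
        mention = store.get(mid)
        if registry.subsumes("textsem.EventMention", mention.type_name):
            kinds.add("event")
        elif registry.subsumes("textsem.EntityMention", mention.type_name):
            kinds.add("entity")
        else:
            raise BridgeError(
                f"mention {mid} ({mention.type_name}) cannot resolve to an "
                f"element")
        type_ids.append(mention.features.get("typeID", 0))
    if len(kinds) != 1:
        raise BridgeError(
            "chain mixes entity and event mentions: "
            f"{sorted(chain.mention_ids)}")
    kind = kinds.pop()
    if len(set(type_ids)) > 1:
        if config.conflict_policy == ERROR:
            raise BridgeError(
                f"chain {sorted(chain.mention_ids)} mentions disagree on "
                f"typeID: {sorted(set(type_ids))}")
        type_id = _last_mention(chain, store).features.get("typeID", 0)
    else:
        type_id = type_ids[0]
    mapped = type_id_codes(registry).get(type_id)
    fallback = "refsem.Entity" if kind == "entity" else "refsem.Event"
    if mapped is None:
        return fallback
    if not registry.subsumes(fallback, mapped):
        # semantic group disagrees with the mention kind (e.g. an
        # anatomical-site typeID on an EventMention chain): fall back
        return fallback
    return mapped


# ----------------------------------------------------------- disambiguation
def disambiguate_concept(chain: CorefChain,
                         store: DocumentStore) -> Optional[Ref]:
    """A single disambiguated ontology concept for the chain: the concept
    present in every nonempty hypothesis array with the best (lowest)
    rank-sum, ties broken lexicographically by code; when the mentions share
    no concept, the first mention's top-ranked hypothesis. None when every
    array is empty."""
    per_mention: list[dict[str, tuple[int, Ref]]] = []
    for mid in chain.mention_ids:
        arr = store.get(mid).features.get("ontologyConceptArr") or []
        ranked: dict[str, tuple[int, Ref]] = {}
        for rank, ref in enumerate(arr):
            code = store.deref(ref).features.get("code", "")
            ranked.setdefault(code, (rank, ref))
        if ranked:
            per_mention.append(ranked)
    if not per_mention:
        return None
    common = set(per_mention[0])
    for ranked in per_mention[1:]:
        common &= set(ranked)
    if common:
        best = min(common, key=lambda code: (
            sum(ranked[code][0] for ranked in per_mention), code))
        return per_mention[0][best][1]
    top = min(per_mention[0].values(), key=lambda rv: rv[0])
    return top[1]


# ------------------------------------------------------------- flag merging
def merge_context_flags(chain: CorefChain, store: DocumentStore,
                        config: BridgeConfig = BridgeConfig()) -> dict:
    """Aggregate polarity/conditional/uncertainty/generic/subject across the
    chain: unanimous values pass through; conflicts resolve per policy."""
    defaults = load_constants()["defaults"]
    merged = {}
    last = _last_mention(chain, store)
    for flag in _CONTEXT_FLAGS:
        values = [store.get(mid).features.get(flag, defaults[flag])
                  for mid in chain.mention_ids]
        distinct = {repr(v) for v in values}
        if len(distinct) == 1:
            merged[flag] = values[0]
        elif config.conflict_policy == ERROR:
            raise BridgeError(
                f"mentions {sorted(chain.mention_ids)} conflict on "
                f"{flag!r}: {values}")
        else:
            merged[flag] = last.features.get(flag, defaults[flag])
    return merged


# ------------------------------------------------------------ relative dates
_RELATIVE_RE = re.compile(
    r"(?P<n>\d+)\s+(?P<unit>day|week|month|year)s?\s+ago", re.IGNORECASE)


def normalize_relative_date(phrase: str,
                            document_date: datetime.date,
                            config: BridgeConfig = BridgeConfig(),
                            ) -> Optional[datetime.date]:
    """Anchor a relative time phrase to the document date.

    Grammar: ``<N> (day|week|month|year)s? ago``, ``yesterday``, ``today``.
    Month and year subtraction clamp the day to the target month's length
    (e.g. March 31 minus one month is February 28/29). Anything outside the
    grammar returns None — the caller leaves the mention unnormalized.
    """
    text = phrase.strip().lower()
    if text == "today" and "today" in config.date_patterns:
        return document_date
    if text == "yesterday" and "yesterday" in config.date_patterns:
        return document_date - datetime.timedelta(days=1)
    if "ago" not in config.date_patterns:
        return None
    match = _RELATIVE_RE.fullmatch(text)
    if match is None:
        return None
    n = int(match.group("n"))
    unit = match.group("unit")
    if unit == "day":
        return document_date - datetime.timedelta(days=n)
    if unit == "week":
        return document_date - datetime.timedelta(weeks=n)
    if unit == "month":
        return document_date - relativedelta(months=n)
    return document_date - relativedelta(years=n)


def _document_date(store: DocumentStore,
                   config: BridgeConfig) -> Optional[datetime.date]:
    raw = store.metadata.get(config.document_date_key)
    if raw is None:
        return None
    return datetime.date.fromisoformat(raw)


# --------------------------------------------------------- modifier handling
def attach_modifier(store: DocumentStore, modifier_id: int,
                    element_id: int) -> None:
    """Point an element's attribute slot at the modifier's normalized
    Attribute; the slot is the feature whose declared range accepts the
    attribute's type (so a medication strength cannot land on a procedure)."""
    registry = store.registry
    modifier = store.get(modifier_id)
    element = store.get(element_id)
    attr_ref = modifier.features.get("normalized")
    attribute = store.deref(attr_ref)
    if attribute is None or not registry.subsumes("refsem.Attribute",
                                                  attribute.type_name):
        raise BridgeError(
            f"modifier {modifier_id} is not normalized to a clinical "
            f"attribute")
    slot = None
    for name, feat in sorted(registry.all_features(element.type_name).items()):
        target = feat.target
        if target is None or target in ("TOP", "SPAN_ROOT"):
            continue
        if target in registry.types \
                and registry.subsumes("refsem.Attribute", target) \
                and registry.subsumes(target, attribute.type_name):
            slot = name
            break
    if slot is None:
        raise BridgeError(
            f"attribute kind {attribute.type_name} is not declared for "
            f"element type {element.type_name}")
    store.set_feature(element_id, slot, attr_ref)


def _ensure_normalized_modifier(store: DocumentStore, modifier) -> bool:
    """Create the refsem Attribute for a raw modifier (category + covered
    text) when upstream left it unnormalized. Returns False when the
    modifier cannot be normalized."""
    if store.deref(modifier.features.get("normalized")) is not None:
        return True
    category = modifier.features.get("category")
    if not category:
        return False
    attr_type = f"refsem.{category}"
    if attr_type not in store.registry.types:
        return False
    value = store.covered_text(modifier).lower()
    attr_id = store.add(attr_type, features={"value": value})
    store.set_feature(modifier.id, "normalized", Ref(attr_id))
    return True


# ------------------------------------------------------------------- lifting
def lift_relation(store: DocumentStore, relation_id: int,
                  element_map: dict[int, int]) -> int:
    """Lift a spanned binary text relation to an unspanned element relation
    between the elements its argument mentions resolved to. The subtype is
    chosen from the category (degreeOf, affects, locationOf, resultOf,
    manifestationOf; anything else stays a generic ElementRelation);
    polarity and uncertainty are copied exactly."""
    relation = store.get(relation_id)
    element_refs = []
    for slot in ("arg1", "arg2"):
        arg = store.deref(relation.features.get(slot))
        mention = store.deref(arg.features.get("argument")) if arg else None
        if mention is None or mention.id not in element_map:
            raise BridgeError(
                f"relation {relation_id} {slot} does not map to an element")
        element_refs.append(Ref(element_map[mention.id]))
    category = relation.features.get("category", "")
    lifted_types = load_constants()["relationCategories"]["lifted"]
    lifted_type = lifted_types.get(category, "relation.ElementRelation")
    features = {"arg1": element_refs[0], "arg2": element_refs[1],
                "category": category}
    for flag in ("polarity", "uncertainty"):
        if relation.features.get(flag) is not None:
            features[flag] = relation.features[flag]
    return store.add(lifted_type, features=features)


def resolved_elements(store: DocumentStore) -> list:
    """Elements produced by chain resolution: those carrying mention
    back-pointers (refsem.Time/Date objects are Element subtypes but are not
    chain products)."""
    return [inst for inst in store.get_by_type("refsem.Element")
            if inst.features.get("mention")]


# ------------------------------------------------------------ full pipeline
def resolve_document(store: DocumentStore,
                     config: BridgeConfig = BridgeConfig()) -> DocumentStore:
    """Run the full bridge over a document store, in place.

    Adds one Element per coreference chain (with bidirectional
    mention/element links), normalized Time/Date objects for time mentions,
    start-time assignments from temporal text relations, attribute
    attachments from degree/modifier relations, and lifted element relations
    for the rest. Running it a second time is a no-op: an already-resolved
    store (any existing Element) is returned unchanged.
    """
    registry = store.registry
    if resolved_elements(store):
        return store

    # 1. chains -> elements
    element_map: dict[int, int] = {}
    for chain in build_coref_chains(store):
        element_type = select_element_type(chain, store, config)
        features = merge_context_flags(chain, store, config)
        concept = disambiguate_concept(chain, store)
        if concept is not None:
            features["ontologyConcept"] = concept
        features["mention"] = [Ref(mid) for mid in chain.mention_ids]
        element_id = store.add(element_type, features=features)
        for mid in chain.mention_ids:
            element_map[mid] = element_id
            mention = store.get(mid)
            slots = registry.all_features(mention.type_name)
            for slot in ("event", "entity"):
                feat = slots.get(slot)
                if feat is not None and registry.subsumes(
                        feat.target, element_type):
                    store.set_feature(mid, slot, Ref(element_id))

    # 2. normalize time mentions against the document date
    doc_date = _document_date(store, config)
    time_map: dict[int, int] = {}
    for mention in store.get_by_type("textsem.TimeMention"):
        existing = store.deref(mention.features.get("time"))
        if existing is not None:
            time_map[mention.id] = existing.id
            continue
        if doc_date is None:
            continue
        resolved = normalize_relative_date(store.covered_text(mention),
                                           doc_date, config)
        if resolved is None:
            continue
        date_id = store.add("refsem.Date", features={
            "day": resolved.day, "month": resolved.month,
            "year": resolved.year})
        time_id = store.add("refsem.Time", features={
            "normalizedForm": resolved.isoformat(), "date": Ref(date_id)})
        store.set_feature(mention.id, "time", Ref(time_id))
        time_map[mention.id] = time_id

    # 3. dispatch the remaining text relations
    categories = load_constants()["relationCategories"]
    temporal = set(categories["temporal"])
    for relation in store.get_by_type("relation.BinaryTextRelation"):
        if registry.subsumes("relation.CoreferenceRelation",
                             relation.type_name):
            continue
        mentions = []
        for slot in ("arg1", "arg2"):
            arg = store.deref(relation.features.get(slot))
            mentions.append(store.deref(arg.features.get("argument"))
                            if arg else None)
        if any(m is None for m in mentions):
            continue
        category = relation.features.get("category", "")
        time_args = [m for m in mentions if m.id in time_map]
        modifier_args = [m for m in mentions
                         if registry.subsumes("textsem.Modifier", m.type_name)]
        mapped_args = [m for m in mentions if m.id in element_map]
        if category in temporal and time_args and mapped_args:
            _assign_start_time(store, element_map[mapped_args[0].id],
                               time_map[time_args[0].id])
        elif modifier_args and mapped_args:
            modifier = modifier_args[0]
            if _ensure_normalized_modifier(store, modifier):
                attach_modifier(store, modifier.id,
                                element_map[mapped_args[0].id])
        elif len(mapped_args) == 2:
            lift_relation(store, relation.id, element_map)
    return store


def _assign_start_time(store: DocumentStore, element_id: int,
                       time_id: int) -> None:
    """Set the element's start-time slot: a startTime feature targeting
    refsem.Time where declared, else a startDate feature targeting
    refsem.Date (medications carry dates rather than times)."""
    registry = store.registry
    element = store.get(element_id)
    slots = registry.all_features(element.type_name)
    feat = slots.get("startTime")
    if feat is not None and feat.target == "refsem.Time":
        store.set_feature(element_id, "startTime", Ref(time_id))
        return
    feat = slots.get("startDate")
    if feat is not None and feat.target == "refsem.Date":
        date_ref = store.get(time_id).features.get("date")
        if date_ref is not None:
            store.set_feature(element_id, "startDate", date_ref)
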