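"""Packaged worked-example document and a randomized synthetic generator.

The worked example is the two-sentence chief-complaint note used throughout
the documentation ("Chief complaint: severe cough and fever. Cough started
2 days ago, no expectoration.") with the shallow-semantic layer an NLP
pipeline would produce: event mentions with ranked concept hypotheses, a
severity modifier, a relative time mention, and the coreference, temporal,
degree and manifestation text relations between them. Running the bridge
over it yields three sign/symptom elements (the two cough mentions resolve
to one), a normalized start time, an attached severity, and one negated
manifestation-of element relation.

The synthetic generator emulates the same annotation shape at configurable
scale for property tests: mention density, coreference rate, negation rate
and relative-date rate are per-mention probabilities, and generation is a
pure function of the spec (same spec, same seed, byte-identical store).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from .errors import ClintypesError
from .model import default_registry
from .store import DocumentStore
from .values import Ref

WORKED_EXAMPLE_TEXT = ("Chief complaint: severe cough and fever. "
                       "Cough started 2 days ago, no expectoration.")
WORKED_EXAMPLE_DATE = "2006-09-03"


@dataclass(frozen=True)
class VocabularyEntry:
    """One concept the generator can mention: a surface form, its UMLS
    codes, and the semantic-group typeID (6 = anatomical site -> entity
    mention; anything else -> event mention)."""

    surface: str
    cui: str
    tui: str
    type_id: int


DEFAULT_VOCABULARY = (
    VocabularyEntry("cough", "C0010200", "T184", 3),
    VocabularyEntry("fever", "C0015967", "T184", 3),
    VocabularyEntry("pain", "C0030193", "T184", 3),
    VocabularyEntry("pneumonia", "C0032285", "T047", 2),
    VocabularyEntry("aspirin", "C0004057", "T121", 1),
    VocabularyEntry("glucose", "C0017725", "T123", 4),
    VocabularyEntry("biopsy", "C0005558", "T060", 5),
    VocabularyEntry("abdomen", "C0000726", "T029", 6),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic document."""

    seed: int = 0
    n_sentences: int = 5
    n_mentions_per_sentence: int = 2
    coref_rate: float = 0.3
    negation_rate: float = 0.2
    relative_date_rate: float = 0.2
    vocabulary: tuple[VocabularyEntry, ...] = DEFAULT_VOCABULARY

    def __post_init__(self):
        for name in ("coref_rate", "negation_rate", "relative_date_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ClintypesError(f"{name} must be a probability, got {p}")
        if self.n_sentences < 0 or self.n_mentions_per_sentence < 1:
            raise ClintypesError("sentence/mention counts out of range")
        if not self.vocabulary:
            raise ClintypesError("vocabulary must not be empty")


def worked_example_store(registry=None) -> DocumentStore:
    """The packaged worked example with its shallow-semantic annotations."""
    registry = registry or default_registry()
    store = DocumentStore(registry, text=WORKED_EXAMPLE_TEXT,
                          metadata={"documentDate": WORKED_EXAMPLE_DATE})
    store.add("textspan.Sentence", span=(0, 40),
              features={"sentenceNumber": 0})
    store.add("textspan.Sentence", span=(41, 84),
              features={"sentenceNumber": 1})

    def concept(cui: str, tui: str) -> Ref:
        return Ref(store.add("refsem.UMLSConcept", features={
            "code": cui, "codingScheme": "UMLS", "cui": cui, "tui": tui}))

    def mention(type_name, begin, end, *, type_id, concepts=(), polarity=1,
                extra=None):
        features = {"typeID": type_id, "polarity": polarity,
                    "uncertainty": 0, "conditional": False, "generic": False,
                    "subject": "patient"}
        if concepts:
            features["ontologyConceptArr"] = list(concepts)
        features.update(extra or {})
        return store.add(type_name, span=(begin, end), features=features)

    cough1 = mention("textsem.EventMention", 24, 29, type_id=3,
                     concepts=[concept("C0010200", "T184")])
    fever = mention("textsem.EventMention", 34, 39, type_id=3,
                    concepts=[concept("C0015967", "T184")])
    cough2 = mention("textsem.EventMention", 41, 46, type_id=3,
                     concepts=[concept("C0010200", "T184")])
    expectoration = mention("textsem.EventMention", 70, 83, type_id=3,
                            concepts=[concept("C0239181", "T184")],
                            polarity=-1)
    del fever
    severe = store.add("textsem.Modifier", span=(17, 23),
                       features={"category": "Severity"})
    two_days_ago = store.add("textsem.TimeMention", span=(55, 65),
                             features={"timeClass": "RELATIVE"})

    def wrap(mention_id: int) -> Ref:
        return Ref(store.add("relation.RelationArgument",
                             features={"argument": Ref(mention_id)}))

    store.add("relation.CoreferenceRelation", features={
        "category": "coreference", "arg1": wrap(cough1), "arg2": wrap(cough2)})
    store.add("relation.BinaryTextRelation", features={
        "category": "startTime", "arg1": wrap(cough2),
        "arg2": wrap(two_days_ago)})
    store.add("relation.BinaryTextRelation", features={
        "category": "degreeOf", "arg1": wrap(severe), "arg2": wrap(cough1)})
    store.add("relation.BinaryTextRelation", features={
        "category": "manifestationOf", "polarity": -1,
        "arg1": wrap(cough2), "arg2": wrap(expectoration)})
    return store


def generate(spec: FixtureSpec, registry=None) -> DocumentStore:
    """A schema-valid synthetic document, deterministic in the spec."""
    registry = registry or default_registry()
    rng = random.Random(spec.seed)
    store = DocumentStore(registry, metadata={"documentDate": "2010-06-15"})

    parts: list[str] = []
    cursor = 0

    def emit(token: str) -> tuple[int, int]:
        nonlocal cursor
        begin = cursor
        parts.append(token)
        cursor += len(token)
        return begin, cursor

    last_by_cui: dict[str, int] = {}
    sentence_spans = []

    # Text and annotations are built in one pass: offsets are final once
    # emitted, so mentions are added immediately, against a provisional
    # oversized text that is replaced by the real one at the end (span
    # validation only needs an upper bound on length during the pass).
    store.text = " " * (spec.n_sentences
                        * (40 + 20 * spec.n_mentions_per_sentence + 40))

    for s in range(spec.n_sentences):
        sent_begin = cursor
        emit("Patient reports ")
        sentence_mentions = []
        for m in range(spec.n_mentions_per_sentence):
            if m > 0:
                emit(" and ")
            entry = rng.choice(spec.vocabulary)
            negated = rng.random() < spec.negation_rate
            if negated:
                emit("no ")
            begin, end = emit(entry.surface)
            concept_id = store.add("refsem.UMLSConcept", features={
                "code": entry.cui, "codingScheme": "UMLS",
                "cui": entry.cui, "tui": entry.tui})
            type_name = ("textsem.EntityMention" if entry.type_id == 6
                         else "textsem.EventMention")
            mention_id = store.add(type_name, span=(begin, end), features={
                "typeID": entry.type_id,
                "polarity": -1 if negated else 1,
                "uncertainty": 0, "conditional": False, "generic": False,
                "subject": "patient",
                "ontologyConceptArr": [Ref(concept_id)]})
            sentence_mentions.append((mention_id, entry))
            previous = last_by_cui.get(entry.cui)
            if previous is not None and rng.random() < spec.coref_rate:
                arg1 = store.add("relation.RelationArgument",
                                 features={"argument": Ref(previous)})
                arg2 = store.add("relation.RelationArgument",
                                 features={"argument": Ref(mention_id)})
                store.add("relation.CoreferenceRelation", features={
                    "category": "coreference",
                    "arg1": Ref(arg1), "arg2": Ref(arg2)})
            last_by_cui[entry.cui] = mention_id
        event_mentions = [mid for mid, entry in sentence_mentions
                          if entry.type_id != 6]
        if event_mentions and rng.random() < spec.relative_date_rate:
            emit(" ")
            n_days = rng.randint(1, 30)
            begin, end = emit(f"{n_days} days ago")
            time_id = store.add("textsem.TimeMention", span=(begin, end),
                                features={"timeClass": "RELATIVE"})
            arg1 = store.add("relation.RelationArgument",
                             features={"argument": Ref(event_mentions[-1])})
            arg2 = store.add("relation.RelationArgument",
                             features={"argument": Ref(time_id)})
            store.add("relation.BinaryTextRelation", features={
                "category": "startTime",
                "arg1": Ref(arg1), "arg2": Ref(arg2)})
        emit(".")
        sentence_spans.append((sent_begin, cursor, s))
        if s < spec.n_sentences - 1:
            emit(" ")

    store.text = "".join(parts)
    for begin, end, number in sentence_spans:
        store.add("textspan.Sentence", span=(begin, end),
                  features={"sentenceNumber": number})
    return store
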