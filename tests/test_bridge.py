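"""The resolution bridge: coreference chaining, element typing, concept
disambiguation, flag merging, relative-date normalization, attribute
attachment, relation lifting, and the full document pass."""

import calendar
import datetime
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clintypes as ct
from clintypes.bridge import _assign_start_time
from clintypes.values import Ref


def make_store(registry, n_mentions, coref_pairs=(), text=None, **features):
    """A minimal store with n event mentions at spans [2i, 2i+1) and
    coreference relations between the given mention indices."""
    text = text or "x" * (2 * n_mentions + 2)
    store = ct.DocumentStore(registry, text=text,
                             metadata={"documentDate": "2006-09-03"})
    mids = []
    for i in range(n_mentions):
        feats = {"typeID": 3, "polarity": 1}
        feats.update({k: v[i] for k, v in features.items()})
        mids.append(store.add("textsem.EventMention", span=(2 * i, 2 * i + 1),
                              features=feats))
    for a, b in coref_pairs:
        arg1 = store.add("relation.RelationArgument",
                         features={"argument": Ref(mids[a])})
        arg2 = store.add("relation.RelationArgument",
                         features={"argument": Ref(mids[b])})
        store.add("relation.CoreferenceRelation",
                  features={"category": "coreference",
                            "arg1": Ref(arg1), "arg2": Ref(arg2)})
    return store, mids


class TestChains:
    def test_worked_example_chains(self, worked):
        chains = ct.build_coref_chains(worked)
        texts = [tuple(worked.covered_text(m) for m in c.mention_ids)
                 for c in chains]
        assert texts == [("cough", "Cough"), ("fever",), ("expectoration",)]

    def test_no_relations_gives_singletons(self, registry):
        store, mids = make_store(registry, 4)
        chains = ct.build_coref_chains(store)
        assert [c.mention_ids for c in chains] == [(m,) for m in mids]

    def test_transitive_closure(self, registry):
        store, mids = make_store(registry, 3, coref_pairs=[(0, 1), (1, 2)])
        chains = ct.build_coref_chains(store)
        assert [c.mention_ids for c in chains] == [tuple(mids)]

    def test_argument_must_be_a_mention(self, registry):
        store, _ = make_store(registry, 1)
        sentence = store.add("textspan.Sentence", span=(0, 2),
                             features={"sentenceNumber": 0})
        arg1 = store.add("relation.RelationArgument",
                         features={"argument": Ref(sentence)})
        arg2 = store.add("relation.RelationArgument",
                         features={"argument": Ref(sentence)})
        store.add("relation.CoreferenceRelation",
                  features={"arg1": Ref(arg1), "arg2": Ref(arg2)})
        with pytest.raises(ct.BridgeError, match="mention"):
            ct.build_coref_chains(store)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_components(self, registry, seed):
        """Chains are the connected components of the coreference graph."""
        rng = random.Random(seed)
        n = rng.randint(1, 50)
        pairs = [(rng.randrange(n), rng.randrange(n))
                 for _ in range(rng.randint(0, n))]
        store, mids = make_store(registry, n, coref_pairs=pairs)
        # oracle: repeated relaxation over an adjacency set
        comp = {m: {m} for m in mids}
        changed = True
        while changed:
            changed = False
            for a, b in pairs:
                union = comp[mids[a]] | comp[mids[b]]
                for m in union:
                    if comp[m] != union:
                        comp[m] = union
                        changed = True
        expected = {frozenset(s) for s in comp.values()}
        got = {frozenset(c.mention_ids)
               for c in ct.build_coref_chains(store)}
        assert got == expected


class TestElementType:
    def test_sign_symptom_chain(self, registry):
        store, mids = make_store(registry, 2, coref_pairs=[(0, 1)])
        chain = ct.build_coref_chains(store)[0]
        assert ct.select_element_type(chain, store) == "refsem.SignSymptom"

    def test_entity_mention_with_anatomical_site_group(self, registry):
        store = ct.DocumentStore(registry, text="abdomen")
        mid = store.add("textsem.EntityMention", span=(0, 7),
                        features={"typeID": 6})
        chain = ct.build_coref_chains(store)[0]
        assert chain.mention_ids == (mid,)
        assert ct.select_element_type(chain, store) == "refsem.AnatomicalSite"

    def test_unknown_group_falls_back_to_plain_event(self, registry):
        store, _ = make_store(registry, 1, typeID=[0])
        chain = ct.build_coref_chains(store)[0]
        assert ct.select_element_type(chain, store) == "refsem.Event"

    def test_mixed_entity_event_chain_rejected(self, registry):
        store = ct.DocumentStore(registry, text="cough abdomen")
        m1 = store.add("textsem.EventMention", span=(0, 5),
                       features={"typeID": 3})
        m2 = store.add("textsem.EntityMention", span=(6, 13),
                       features={"typeID": 6})
        a1 = store.add("relation.RelationArgument",
                       features={"argument": Ref(m1)})
        a2 = store.add("relation.RelationArgument",
                       features={"argument": Ref(m2)})
        store.add("relation.CoreferenceRelation",
                  features={"arg1": Ref(a1), "arg2": Ref(a2)})
        chain = ct.build_coref_chains(store)[0]
        with pytest.raises(ct.BridgeError, match="mixes"):
            ct.select_element_type(chain, store)

    def test_type_id_conflict_under_error_policy(self, registry):
        store, _ = make_store(registry, 2, coref_pairs=[(0, 1)],
                              typeID=[3, 2])
        chain = ct.build_coref_chains(store)[0]
        with pytest.raises(ct.BridgeError, match="typeID"):
            ct.select_element_type(chain, store,
                                   ct.BridgeConfig(conflict_policy="error"))
        # last-mention-wins picks the later mention's group
        assert ct.select_element_type(chain, store) == "refsem.DiseaseDisorder"


def add_concepts(store, mid, codes):
    refs = [Ref(store.add("refsem.OntologyConcept",
                          features={"code": c, "codingScheme": "UMLS"}))
            for c in codes]
    store.set_feature(mid, "ontologyConceptArr", refs)


class TestDisambiguation:
    def test_unanimous_concept_wins(self, registry):
        store, mids = make_store(registry, 2, coref_pairs=[(0, 1)])
        for mid in mids:
            add_concepts(store, mid, ["C0010200"])
        chain = ct.build_coref_chains(store)[0]
        ref = ct.disambiguate_concept(chain, store)
        assert store.deref(ref).features["code"] == "C0010200"

    def test_single_umls_hypothesis_passes_through(self, registry):
        store = ct.DocumentStore(registry, text="pain")
        concept = store.add("refsem.UMLSConcept", features={
            "code": "C0030193", "codingScheme": "UMLS",
            "cui": "C0030193", "tui": "T184"})
        mid = store.add("textsem.EventMention", span=(0, 4), features={
            "typeID": 3, "ontologyConceptArr": [Ref(concept)]})
        chain = ct.build_coref_chains(store)[0]
        got = store.deref(ct.disambiguate_concept(chain, store))
        assert got.features["cui"] == "C0030193"
        assert got.features["tui"] == "T184"

    def test_rank_sum_tie_breaks_lexicographically(self, registry):
        # A ranks (c1, c2), B ranks (c2, c1): both rank-sums are 1, so the
        # lexicographically smaller code wins
        store, mids = make_store(registry, 2, coref_pairs=[(0, 1)])
        add_concepts(store, mids[0], ["C0000001", "C0000002"])
        add_concepts(store, mids[1], ["C0000002", "C0000001"])
        chain = ct.build_coref_chains(store)[0]
        ref = ct.disambiguate_concept(chain, store)
        assert store.deref(ref).features["code"] == "C0000001"

    def test_no_common_concept_takes_first_mentions_top(self, registry):
        store, mids = make_store(registry, 2, coref_pairs=[(0, 1)])
        add_concepts(store, mids[0], ["C0000009"])
        add_concepts(store, mids[1], ["C0000001"])
        chain = ct.build_coref_chains(store)[0]
        ref = ct.disambiguate_concept(chain, store)
        assert store.deref(ref).features["code"] == "C0000009"

    def test_all_arrays_empty_gives_none(self, registry):
        store, _ = make_store(registry, 2, coref_pairs=[(0, 1)])
        chain = ct.build_coref_chains(store)[0]
        assert ct.disambiguate_concept(chain, store) is None


class TestFlagMerging:
    def test_unanimous_values_pass_through(self, registry):
        store, _ = make_store(registry, 2, coref_pairs=[(0, 1)])
        chain = ct.build_coref_chains(store)[0]
        merged = ct.merge_context_flags(chain, store)
        assert merged["polarity"] == 1 and merged["subject"] == "patient"

    def test_conflict_resolved_by_last_mention(self, registry):
        store, _ = make_store(registry, 2, coref_pairs=[(0, 1)],
                              polarity=[1, -1])
        chain = ct.build_coref_chains(store)[0]
        assert ct.merge_context_flags(chain, store)["polarity"] == -1

    def test_conflict_under_error_policy_names_the_flag(self, registry):
        store, _ = make_store(registry, 2, coref_pairs=[(0, 1)],
                              polarity=[1, -1])
        chain = ct.build_coref_chains(store)[0]
        with pytest.raises(ct.BridgeError, match="polarity"):
            ct.merge_context_flags(chain, store,
                                   ct.BridgeConfig(conflict_policy="error"))


def oracle_months_back(date, n):
    """Independent month arithmetic: walk the month index back and clamp
    the day to the target month's length."""
    month_index = date.year * 12 + (date.month - 1) - n
    year, month = divmod(month_index, 12)
    month += 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return datetime.date(year, month, day)


class TestRelativeDates:
    @pytest.mark.parametrize("phrase,anchor,expected", [
        ("2 days ago", "2006-09-03", "2006-09-01"),
        ("14 days ago", "2006-09-03", "2006-08-20"),
        ("today", "2011-02-28", "2011-02-28"),
        ("yesterday", "2011-03-01", "2011-02-28"),
        ("1 week ago", "2006-09-03", "2006-08-27"),
        ("1 month ago", "2006-03-31", "2006-02-28"),  # clamped day
        ("1 year ago", "2012-02-29", "2011-02-28"),   # leap-day clamp
        ("3 years ago", "2006-09-03", "2003-09-03"),
    ])
    def test_grammar(self, phrase, anchor, expected):
        got = ct.normalize_relative_date(
            phrase, datetime.date.fromisoformat(anchor))
        assert got == datetime.date.fromisoformat(expected)

    @pytest.mark.parametrize("phrase", [
        "a few days ago", "next week", "2 fortnights ago", "09/01/2006"])
    def test_outside_grammar_returns_none(self, phrase):
        assert ct.normalize_relative_date(
            phrase, datetime.date(2006, 9, 3)) is None

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(0, 400),
           offset=st.integers(0, 40000), k=st.integers(-50, 50))
    def test_day_phrases_are_translation_equivariant(self, n, offset, k):
        base = datetime.date(1950, 1, 1) + datetime.timedelta(days=offset)
        phrase = f"{n} days ago"
        a = ct.normalize_relative_date(phrase, base)
        b = ct.normalize_relative_date(
            phrase, base + datetime.timedelta(days=k))
        assert b - a == datetime.timedelta(days=k)

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(0, 60), offset=st.integers(0, 40000))
    def test_month_phrases_match_calendar_oracle(self, n, offset):
        anchor = datetime.date(1950, 1, 1) + datetime.timedelta(days=offset)
        got = ct.normalize_relative_date(f"{n} months ago", anchor)
        assert got == oracle_months_back(anchor, n)


class TestModifiersAndLifting:
    def test_severity_attaches_to_sign_symptom(self, registry):
        store, _ = make_store(registry, 1)
        element = store.add("refsem.SignSymptom", features={"polarity": 1})
        severity = store.add("refsem.Severity", features={"value": "severe"})
        modifier = store.add("textsem.Modifier", span=(0, 1),
                             features={"normalized": Ref(severity)})
        ct.attach_modifier(store, modifier, element)
        assert store.get(element).features["severity"] == Ref(severity)

    def test_unmarked_severity_accepted(self, registry):
        store, _ = make_store(registry, 1)
        element = store.add("refsem.SignSymptom")
        severity = store.add("refsem.Severity", features={"value": "unmarked"})
        modifier = store.add("textsem.Modifier", span=(0, 1),
                             features={"normalized": Ref(severity)})
        ct.attach_modifier(store, modifier, element)
        assert store.get(element).features["severity"] == Ref(severity)

    def test_medication_strength_rejected_on_procedure(self, registry):
        store, _ = make_store(registry, 1)
        procedure = store.add("refsem.Procedure")
        strength = store.add("refsem.MedicationStrength",
                             features={"number": "100", "unit": "mg"})
        modifier = store.add("textsem.Modifier", span=(0, 1),
                             features={"normalized": Ref(strength)})
        with pytest.raises(ct.BridgeError, match="not declared"):
            ct.attach_modifier(store, modifier, procedure)

    def _lift_fixture(self, registry, category, polarity):
        store, mids = make_store(registry, 2)
        elements = [store.add("refsem.SignSymptom") for _ in mids]
        element_map = dict(zip(mids, elements))
        args = [store.add("relation.RelationArgument",
                          features={"argument": Ref(m)}) for m in mids]
        rel = store.add("relation.BinaryTextRelation", features={
            "category": category, "polarity": polarity, "uncertainty": 0,
            "arg1": Ref(args[0]), "arg2": Ref(args[1])})
        return store, rel, element_map, elements

    def test_manifestation_lifts_with_polarity(self, registry):
        store, rel, element_map, elements = self._lift_fixture(
            registry, "manifestationOf", -1)
        lifted = store.get(ct.lift_relation(store, rel, element_map))
        assert lifted.type_name == "relation.ManifestationOf"
        assert lifted.features["polarity"] == -1
        assert lifted.features["arg1"] == Ref(elements[0])

    def test_location_of_category_maps_to_subtype(self, registry):
        store, rel, element_map, _ = self._lift_fixture(
            registry, "locationOf", -1)
        lifted = store.get(ct.lift_relation(store, rel, element_map))
        assert lifted.type_name == "relation.LocationOf"
        assert lifted.features["polarity"] == -1

    def test_unknown_category_stays_generic(self, registry):
        store, rel, element_map, _ = self._lift_fixture(
            registry, "treats", 1)
        lifted = store.get(ct.lift_relation(store, rel, element_map))
        assert lifted.type_name == "relation.ElementRelation"

    def test_unmapped_argument_rejected(self, registry):
        store, rel, element_map, _ = self._lift_fixture(
            registry, "affects", 1)
        with pytest.raises(ct.BridgeError, match="does not map"):
            ct.lift_relation(store, rel, {})

    def test_start_time_assignment_uses_date_slot_for_medications(
            self, registry):
        store, _ = make_store(registry, 1)
        med = store.add("refsem.Medication")
        date = store.add("refsem.Date",
                         features={"day": 1, "month": 9, "year": 2006})
        time = store.add("refsem.Time", features={
            "normalizedForm": "2006-09-01", "date": Ref(date)})
        _assign_start_time(store, med, time)
        assert store.get(med).features["startDate"] == Ref(date)


class TestResolveDocument:
    def test_worked_example_layers(self, resolved):
        elements = ct.resolved_elements(resolved)
        assert [e.type_name for e in elements] == ["refsem.SignSymptom"] * 3
        cough = elements[0]
        mentions = [resolved.covered_text(resolved.deref(r))
                    for r in cough.features["mention"]]
        assert mentions == ["cough", "Cough"]
        start = resolved.deref(cough.features["startTime"])
        date = resolved.deref(start.features["date"])
        assert (date.features["year"], date.features["month"],
                date.features["day"]) == (2006, 9, 1)
        assert resolved.deref(
            cough.features["severity"]).features["value"] == "severe"
        concept = resolved.deref(cough.features["ontologyConcept"])
        assert concept.features["cui"] == "C0010200"
        manifestations = resolved.get_by_type("relation.ManifestationOf")
        assert len(manifestations) == 1
        assert manifestations[0].features["polarity"] == -1
        assert resolved.validate() == []

    def test_mention_element_links_are_bidirectional(self, resolved):
        for element in ct.resolved_elements(resolved):
            for ref in element.features["mention"]:
                mention = resolved.deref(ref)
                assert mention.features["event"].id == element.id

    def test_empty_textsem_layer_is_untouched(self, registry):
        store = ct.DocumentStore(registry, text="No annotations here.")
        before = store.serialize()
        ct.resolve_document(store)
        assert store.serialize() == before

    def test_resolution_is_idempotent(self, registry):
        store = ct.worked_example_store(registry)
        once = ct.resolve_document(store).serialize()
        twice = ct.resolve_document(store).serialize()
        assert once == twice

    def test_partition_property_on_generated_documents(self, registry):
        """Every entity/event mention lands in exactly one element's mention
        array, and the element count equals the chain count."""
        for seed in range(15):
            store = ct.generate(ct.FixtureSpec(seed=seed, n_sentences=4,
                                               coref_rate=0.6,
                                               relative_date_rate=0.4))
            chains = ct.build_coref_chains(store)
            ct.resolve_document(store)
            elements = ct.resolved_elements(store)
            assert len(elements) == len(chains)
            seen = {}
            for element in elements:
                for ref in element.features["mention"]:
                    assert ref.id not in seen
                    seen[ref.id] = element.id
            mentions = {m.id for m in
                        store.get_by_type("textsem.EntityMention")}
            mentions |= {m.id for m in
                         store.get_by_type("textsem.EventMention")}
            assert set(seen) == mentions
            assert store.validate() == []
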