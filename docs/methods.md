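# Methods

This note records the data model, the resolution procedure, the defaults
and the design decisions behind `clintypes`, in enough detail to reason
about what its tests do and do not establish.

## The type system

The inventory is a single-inheritance tree over two roots. Types whose
supertype chain ends at `SPAN_ROOT` are *spanned*: their instances carry
0-based, half-open character offsets over Unicode code points into the
document text. Types rooted at `TOP` are *unspanned*, document-level
objects: the entire referential-semantics layer (`refsem`), the relation
family, utilities and structured metadata. Spanned-ness is therefore a
derived property; the schema loader rejects a file whose `spanned` flags
disagree with the supertype chain. Two housed-elsewhere types follow their
inheritance rather than their namespace: `syntax.StanfordDependency` and
`textsem.SemanticRoleRelation` both extend `relation.BinaryTextRelation`
and are unspanned, like every other relation.

Features are declared once, at exactly one type, and inherited; a subtype
cannot re-declare an inherited feature. Feature ranges are the primitives
`boolean`/`integer`/`float`/`string`, string arrays, and typed references
(`ref:` / `refarray:`); a reference target may be a root marker, meaning
"any spanned annotation" (used by `relation.RelationArgument.argument`).
The statistics operation counts features at the declaring type only — the
only convention under which the per-namespace budgets are additive
(structured 4/24, util 3/3, textspan 5/5, syntax 26/33, textsem 17/33,
refsem 31/96, relation 14/13; totals 100 types, 207 features, 2.07
features per type).

### Reconstructed slots

The clinical model this library implements fixes the namespace budgets and
names the load-bearing types and features, but not every slot. Slots
filled to meet the budgets follow cTAKES v2.5 conventions and are flagged
`"reconstructed": true` in `src/clintypes/data/schema.jsonl` rather than
presented as normative: all of `structured`, `textspan.ListEntry`,
`syntax.Lemma`, the non-phrasal details of the treebank nodes,
`textsem.Markable` (the 17th textsem type), the quick-index annotations'
`value` feature, and `refsem.EventProperties`' field list. The six core
CEM types carry `"coreCem": true`.

### Encodings and defaults

Polarity is encoded {−1, 1} (negated/affirmed) and uncertainty {0, 1};
the constants file also fixes the defaults applied by `make_default`:
polarity 1, uncertainty 0, conditional and generic false, subject
"patient", and `"unmarked"` for value-set attributes *whose set contains
it*. `refsem.BodySide` (left, right, bilateral) has no unmarked value, so
its default is simply unset. Value sets are enforced by instance
validation only for the four shared attributes (Severity, Course,
BodySide, BodyLaterality); element-to-attribute links are deliberately not
value-checked, because hard-coded vocabularies hamper downstream tools.
UMLS identifiers are shape-checked (`C\d{7}` / `T\d{3}`) but never
resolved against a UMLS release.

## The document store

A `DocumentStore` is build-once: instances can be added and features
updated, never deleted, and ids are never reused. Every instance is
validated on entry (declared features, ranges, span presence matching
spanned-ness, reference targets, value sets) and indexed under its type
and all ancestors, so supertype queries include subtypes by construction.
Spanned query results are ordered by (begin, end, id), unspanned by id.
Serialization is canonical — sorted keys, instances in id order,
references as `{"$ref": id}` — so equal stores produce byte-identical
JSON and a round trip is the identity. The document date lives in store
metadata under `documentDate` (ISO 8601).

## The resolution bridge

Resolution consumes upstream outputs; it computes no coreference, NER or
parsing itself. The pass is:

1. **Chains.** Union-find over the coreference relations restricted to
   entity/event mentions; every non-coreferring mention forms a singleton
   chain. Chains and their mentions are ordered by span, which makes the
   pass deterministic.
2. **One element per chain.** The refsem subtype comes from the mentions'
   semantic-group `typeID` via the shipped code table (1 Medication,
   2 DiseaseDisorder, 3 SignSymptom, 4 Lab, 5 Procedure, 6 AnatomicalSite;
   0/unknown falls back to plain `refsem.Event` or `refsem.Entity` by
   mention kind, as does a group that contradicts the mention kind). A
   chain mixing entity and event mentions is an error.
3. **Concept disambiguation.** Among concepts present in *every* nonempty
   hypothesis array, the lowest rank-sum wins; ties break
   lexicographically by code; with no common concept, the first mention's
   top hypothesis is taken; all-empty arrays leave the concept unset.
4. **Flag aggregation.** Unanimous context flags pass through. Conflicts
   resolve by policy: the default `last-mention-wins` takes the value of
   the mention with the greatest begin offset (clinical narrative tends to
   refine earlier statements); `error` raises, naming the flag.
   Mention/element links are written bidirectionally (element→mention
   array, mention→event/entity).
5. **Times.** Time mentions matching the grammar `<N> (day|week|month|
   year)s? ago | yesterday | today` are normalized against the document
   date; month/year subtraction clamps the day to the target month's
   length (March 31 − 1 month = February 28/29). Phrases outside the
   grammar are left unnormalized rather than guessed. Internally a date is
   day/month/year integers plus an ISO string; the `09/01/2006`-style
   month-first rendering is purely a CLI display concern.
6. **Relation dispatch.** Each remaining binary text relation is consumed
   by the first matching rule: a temporal category (`startTime`,
   `TIMEX-of`) linking a normalized time to an element sets the element's
   `startTime` (or `startDate`, for medications, via the time's date); a
   relation with a modifier argument attaches the modifier's normalized
   attribute to the element slot whose declared range accepts it (so a
   medication strength can never land on a procedure); a relation whose
   both arguments resolved becomes an unspanned element relation — the
   subtype chosen by category (degreeOf, affects, locationOf, resultOf,
   manifestationOf, else generic `ElementRelation`) — with polarity and
   uncertainty copied exactly. Anything else is left untouched.

The pass is idempotent: a store already containing chain-produced elements
(detected by mention back-pointers, since `refsem.Time`/`Date` are also
Element subtypes) is returned unchanged. After resolution the store still
validates, and the element count equals the chain count.

## CEM export

The refsem layer flattens the qualifier/modifier/attribution trichotomy
into plain features; the shipped per-CEM cetype files (seeded from the
sign/symptom CoughAssert pattern) restore the classification on export.
Slot cardinalities (`0-1`, `0-M`, ...) are enforced when building an
instance. The element's concept code becomes the data value; polarity −1
sets `negationInd`, uncertainty 1 sets the `uncertainty` modifier, and
the subject flag maps to the `subject` modifier. Cetype XML writing is
canonical (fixed attribute order `kind, name, xmlns` / `card, name,
type`, one element per line), making write∘parse the identity; the
instance dialect (`<ceinst>`) is defined by this artifact, as no standard
instance serialization accompanies the model dialect. No XML-namespace
processing is performed; `xmlns=""` is emitted verbatim. ECID registry
resolution and full HL7 v3 data types are out of scope.

## The synthetic generator

`generate(FixtureSpec)` emulates the *annotation shape* of a processed
clinical note — sentences containing concept mentions drawn from a small
vocabulary (including pain C0030193/T184), per-mention negation,
same-concept coreference links, and relative-date attachments — as a pure
function of the spec: identical specs yield byte-identical stores.
Defaults (5 sentences, 2 mentions each, coreference 0.3, negation 0.2,
relative-date 0.2) were chosen once as a plausible density for a short
clinical note. The generator makes no attempt at realistic clinical prose,
lexical variation, sense ambiguity, discontinuous or overlapping mentions,
or cross-sentence syntax; green property tests on generated data therefore
establish the algebra of the pipeline (partitioning, determinism,
round-trip identity, oracle agreement), not extraction quality on real
notes.

## Numerical and procedural choices

- Tie-breaks are total everywhere (span order then id; lexicographic
  concept codes), so no operation depends on dict/set iteration order.
- Degenerate inputs are defined: empty documents round-trip; an empty
  textsem layer resolves to itself; empty concept arrays leave the
  element's concept unset; the empty window selects nothing.
- Calendar arithmetic uses `dateutil.relativedelta` for the clamped
  month/year cases; the test oracle re-derives clamping independently
  from month-length tables.
- Test and acceptance problem sizes — up to 50-mention coreference graphs,
  200 round-tripped stores, 500–1000 random date pairs — were chosen as
  the point where the checked properties stabilize; the whole suite runs
  in a few seconds.

## Known limitations

- The bridge trusts upstream typeIDs and coreference links; it has no
  recovery strategy for wrong input beyond the conflict policy.
- One document per store: no multi-view or cross-document coreference.
- The relative-time grammar is deliberately minimal; "last Tuesday" or
  "post-op day 3" are left unnormalized.
- Reconstructed schema slots are conventional, not normative; consumers
  should treat the flagged entries accordingly.
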