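# clintypes

A common type system for clinical natural language processing, implemented
as a standalone Python library — no UIMA required.

Clinical NLP pipelines only interoperate when they agree on the data
structures they read and write. `clintypes` provides that contract as a
typed annotation model spanning four layers: document structure and
utilities (`structured`, `util`, `textspan`), syntax (tokens, chunks,
CONLL-X dependency nodes, Penn-Treebank constituents, Stanford
dependencies), **textual semantics** (spanned mentions with negation,
uncertainty and ranked ontology-concept hypotheses), and **referential
semantics** (unspanned, document-level clinical elements modeled on
Intermountain Healthcare's Clinical Element Models, CEMs). The inventory
comprises 100 types with 207 declared features across 7 namespaces, with
six core CEM types: `refsem.AnatomicalSite`, `refsem.DiseaseDisorder`,
`refsem.Lab`, `refsem.Medication`, `refsem.Procedure` and
`refsem.SignSymptom`.

The distinction that does the work is **mention vs. element**: a mention is
a span of text that refers to something ("cough" at offsets [24,29)); an
element is the single real-world instance that one or more coreferring
mentions denote, carrying a disambiguated UMLS concept (CUI/TUI),
aggregated context flags, normalized times, and post-coordinated attributes
(severity, course, laterality, ...). The library ships the resolution
bridge that builds the element layer from the mention layer, plus
readers/writers for the cetype XML dialect in which CEM definitions are
exchanged.

Who it is for: builders of clinical information-extraction systems who need
a typed target representation deeper than named-entity output, and anyone
who wants to validate, store, transform or export layered clinical
annotations without running a UIMA/cTAKES stack.

## Worked example

The packaged fixture is the two-sentence note
*"Chief complaint: severe cough and fever. Cough started 2 days ago, no
expectoration."* (document date 2006-09-03) with the shallow layer an NLP
pipeline would produce: four event mentions, a severity modifier, a
relative time mention, and coreference / temporal / degree / manifestation
text relations.

```python
import clintypes as ct

store = ct.worked_example_store()
ct.resolve_document(store)
for element in ct.resolved_elements(store):
    mentions = [store.covered_text(store.deref(r))
                for r in element.features["mention"]]
    print(element.type_name, mentions, element.features["polarity"])
```

or, from the shell, `clintypes demo`, which prints:

```
refsem.SignSymptom #25: mentions=['cough', 'Cough'] polarity=1 concept=C0010200 startTime=09/01/2006 severity=severe
refsem.SignSymptom #26: mentions=['fever'] polarity=1 concept=C0015967
refsem.SignSymptom #27: mentions=['expectoration'] polarity=-1 concept=C0239181
relation.ManifestationOf #31: refsem.SignSymptom -> refsem.SignSymptom polarity=-1
```

Reading the output: the two cough mentions were recognized as coreferring,
so they resolve to **one** sign/symptom element whose severity comes from
the "severe" modifier and whose start time is "2 days ago" normalized
against the document date (2006-09-01, displayed month-first). "fever" and
"expectoration" form singleton chains; the expectoration element and the
manifestation-of relation carry polarity −1 because the text *negates*
expectoration — exactly the reading a structured-data consumer needs.

`clintypes stats` prints the per-namespace type/feature matrix (100 types,
207 features, 2.07 features per type); `clintypes validate|resolve|convert|
generate` cover document validation, resolution, CEM XML export and
synthetic-document generation. The same operations are available as
library calls; see `examples/` for one short script per capability.

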