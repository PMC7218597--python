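# combokg

Automated discovery of **combination drug therapies** from biomedical
literature, and their organization into a combination-centric knowledge
graph.

Clinical trial reports state their validated findings in the conclusive
sentences of their abstracts ("CONCLUSION: A combination of GTI-2040,
capecitabine and oxaliplatin is feasible in patients with advanced solid
tumors."). Semantic-predication extractors such as SemRep reduce each such
sentence to subject–predicate–object triples over UMLS concepts. `combokg`
consumes those triples and detects combined-therapy knowledge with a simple,
auditable rule:

> Within one conclusive claim, two or more predications
> S₁-P-O, S₂-P-O, … (i ≥ 2) with an **identical treatment predicate**
> P ∈ {TREATS, INHIBITS, PREVENTS, DISRUPTS} and an **identical disease
> object** O, but **distinct drug subjects** Sᵢ ∈ Chemicals and Drugs,
> constitute the combined-therapy knowledge (S₁+S₂+…)-P-O.

Around that rule the package provides the full pipeline a user needs:

- **claims** — sentence segmentation, conclusive-claim selection by the
  wildcard keywords `conclusion*` / `conclude*`, and detection of the four
  combination markers (`combin*`, `coadministration`, `co-administered`,
  `regimen`);
- **predications** — a pipe-delimited SemMedDB-style dialect, predicate
  normalization (`TREATS(INFER)`, `NEG_TREATS`), and predicate/semantic-type
  filtering with negation exclusion;
- **mesh_filters** — exclusion lists for broad concepts built from a MeSH
  descriptor table: pharmacologic actions (the `D27.505` branch) and generic
  disease names (the category-C root plus the undotted `C01`–`C26` headings,
  27 terms);
- **discovery** — the grouping rule above, comparison flagging via
  `COMPARED_WITH`, summary tables and mechanism-pattern counting;
- **knowledge_graph** — drugs bound into combination nodes directed at
  diseases, claim-level evidence on every edge, D3-ready JSON and flat TSV
  exports, disease-centered queries;
- **synthetic** — a corpus generator with planted ground truth, so the whole
  pipeline is testable without PubMed, SemRep or a UMLS license.

## Worked example

The GTI-2040 claim ships as a built-in fixture: one conclusive sentence
(sentence 15 of its abstract) from which an extractor emits 7 predications —
the disease is a `PROCESS_OF` the patient group, each of the three drugs
`TREATS` Patients, and inference chains both into `TREATS(INFER)` onto the
disease.

```python
from combokg import discover_combinations, extract_conclusive_claims
from combokg.predications import group_by_sentence
from combokg.synthetic import worked_example_abstract, worked_example_predications

claim = extract_conclusive_claims(worked_example_abstract())[0]
pset = group_by_sentence(worked_example_predications())[claim.sentence_id]
for g in discover_combinations(claim, pset):
    print(g.sentence_id, g.predicate_base, g.object_name,
          [name for _, name in g.subjects], g.any_inferred)
```

prints

```
19322566.ab.15 TREATS Advanced Malignant Solid Neoplasm ['oxaliplatin', 'capecitabine', 'GTI2040'] True
```

i.e. the three `TREATS(INFER)` predications survive the predicate and
semantic-type filters (the `TREATS` → Patients triples fail the disease-object
test, `PROCESS_OF` fails the predicate test) and merge into the single
candidate *GTI2040 + capecitabine + oxaliplatin — TREATS — Advanced Malignant
Solid Neoplasm*; `True` records that inferred predications contributed.

From the shell, the same pipeline over a synthetic corpus:

```bash
combokg simulate -o corpus --seed 7 --n-abstracts 200
combokg build-filters corpus/mesh.tsv -o filters
combokg discover corpus/abstracts.jsonl corpus/predications.psv \
    --filters filters -o candidates.tsv --summary summary.json
combokg build-kg candidates.tsv --out-json kg.json --out-tsv kg.tsv
```

`discover` logs the funnel at each stage (abstracts read, claims found,
predications parsed, survivors of the treatment filter and of the
broad-concept filter, groups discovered).

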