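# Methods

## The discovery rule and its assumptions

`combokg` detects combined drug therapies from *semantic predications* —
subject–predicate–object triples whose subject and object are normalized
biomedical concepts (UMLS-style CUI, preferred name, semantic types). The
rule: within one conclusive claim, predications sharing a treatment
predicate P ∈ {TREATS, INHIBITS, PREVENTS, DISRUPTS} and a disease object O
but differing in drug subject are merged into one candidate combination
(S₁+…+Sₖ)-P-O, k ≥ 2.

Assumptions this rests on:

1. **Conclusive sentences carry the validated knowledge.** Sentences
   matching `conclusion*` / `conclude*` are treated as the claims an
   article's evidence supports. Abstracts that phrase their conclusion
   differently are missed by construction.
2. **The upstream extractor emits inference chains.** Combination claims
   typically read "a combination of X, Y and Z is feasible in patients with
   D"; extractors then emit X TREATS Patients plus X TREATS(INFER) D.
   Discovery therefore normalizes `(INFER)` away and judges the base
   predicate — without this merging the canonical combination claim would
   never produce a group.
3. **Grouping by object CUI, not name.** Synonymous disease names with one
   CUI must not split a group; distinct CUIs with similar names must.
4. **Comparative claims are a known false-positive mode.** "Both X and Y
   had comparable efficacy…" yields X TREATS D and Y TREATS D and is
   indistinguishable from a combination by the rule alone. When a
   `COMPARED_WITH` predication links two group members, the group is
   *flagged*, never silently deleted; `--drop-comparisons` opts into hard
   filtering. Likewise "X plus either Y or Z" claims surface as one
   k-drug group — disambiguation is out of scope.

## Filtering

**Treatment filter.** A predication survives iff its base predicate is a
treatment predicate, its subject carries at least one "Chemicals and Drugs"
semantic type, its object at least one disease type, and it is not negated
(`NEG_` prefix) when `exclude_negated` is on (default). Semantic-type match
is set intersection, since concepts carry several types. The shipped type
lists (`src/combokg/data/*.txt`) are editable: drugs = {phsu, orch, antb,
clnd, aapp, bacs, horm, imft, vita, enzy}, diseases = {dsyn, neop, mobd}.
The disease child-type enumeration is an assumption — upstream vocabularies
name only the parent groups — so it is configuration, not code.

**Broad-concept filter.** Headings too generic to name a therapy are
removed by two lists built from a MeSH descriptor table:

- *pharmacologic actions*: every heading whose tree number descends,
  segment-wise, from a configured branch (default `D27.505`, the
  Pharmacologic Actions subtree). Segment-wise means `D27.505` matches
  `D27.505.954.248` but not `D27.5059`.
- *generic disease names*: the category-C root label plus every heading
  with an undotted category-C tree number (`C01`…`C26`). The root is not
  itself a descriptor, so its label is supplied as configuration (default
  `"diseases"`), giving the familiar 27-term list.

Matching against predications is by case-folded preferred-name string.
MeSH headings and UMLS preferred names largely coincide, and string
matching needs no UMLS license; the residual mismatch (a broad concept
surfacing under a non-MeSH synonym) is a documented limitation. A
name→CUI map can be layered on by the caller where a license is available.

**MeSH input dialect.** A three-column TSV (`ui<TAB>name<TAB>tree numbers
;-joined`) rather than MeSH XML. To produce it from a real release:
`desc20XX.xml` → for each `DescriptorRecord` take `DescriptorUI`,
`DescriptorName/String` and all `TreeNumber` elements (e.g. with
`lxml.etree.iterparse`, ~15 lines). The predication dialect is likewise a
distillate: pipe-delimited SemMedDB-style columns; users with native
SemRep fielded output keep only the SPO fields and the sentence locator.

## The knowledge graph

Combined drugs are bound into a *combination node* which is directed at the
disease (`member_of` edges drug→combination, one `treats_like` edge
combination→disease labeled with the base predicate). Combination identity
is the deterministic id `cmb:<sorted member CUIs>:<predicate>:<object CUI>`,
so the same drug set treating two diseases yields two nodes, and the same
combination asserted in several claims merges into one node whose edge
accumulates one evidence item (PMID, sentence id, claim text, markers,
inference flag) per claim. The alternative — one node per claim — was
rejected because the graph's purpose is per-combination evidence
aggregation; the claim-level view is still fully recoverable from the
evidence lists. Exports: D3 `{"nodes": [...], "links": [...]}` JSON with
sorted keys and sorted node/edge order (byte-stable across runs), a flat
triples TSV, and a networkx conversion for GraphML.

## The synthetic corpus

The generator emulates the pipeline's three inputs with planted truth.
Per abstract: filler sentences plus one conclusive claim built from
templates exercising the four markers and the comparative phrasings
("Both X and Y had comparable efficacy…", "X plus either Y or Z…"). The
predication file contains what a SemRep-style extractor plausibly emits
for each claim, including the TREATS→Patients / TREATS(INFER)→disease
pairs, `COMPARED_WITH` records for comparisons and `NEG_` prefixes for
negated findings.

Default condition parameters: 200 abstracts; P(combination claim) = 0.6;
combination sizes 2:3:4 drawn at 210:43:2 (the size split observed among
curated real combinations); P(comparative single-therapy claim) = 0.12 and
P(negation) = 0.05, matching the error-taxonomy rates of the curated
corpus (40/325 comparisons, 17/325 missed negations); broad-concept
contamination 0.05 per side. Generic-subject contamination is confined to
2-drug claims so a contaminated claim always falls below the 2-subject
threshold after filtering — this keeps the planted truth unambiguous.

What the generator does **not** emulate: real NLP noise (entity-recognition
errors, unparsed sentences, predications from non-conclusive sentences),
synonymy between concept names, and abstracts whose conclusions lack the
keywords. Perfect zero-noise precision/recall therefore demonstrates the
*algorithm's* correctness on well-formed predications, not end-to-end
performance on PubMed.

## Numerical and procedural choices

- **Sentence segmentation** is a deterministic regex splitter (boundary =
  `[.?!]` + whitespace + uppercase/digit, with a short abbreviation
  guard), chosen over a statistical segmenter so sentence ids are
  reproducible byte-for-byte across runs and platforms.
- **Keyword and marker matching** is case-insensitive word-boundary regex;
  the wildcard stems admit all word continuations (`conclusions`,
  `concluded`, `concluding`).
- **"regimen" tabulation**: the detector reports every marker present;
  summary tables count `regimen` only for claims carrying none of the
  other three markers. Tabulation is per distinct claim, not per group.
- **Ordering/tie-breaks**: subjects sorted by CUI; groups by (sentence id,
  predicate, object CUI); graph nodes/edges sorted on export. All outputs
  are permutation-invariant in their inputs.
- **Degenerate inputs**: empty files parse to empty lists; an empty group
  list builds an empty graph that still serializes validly; unknown
  diseases query to an empty subgraph.
- **Pattern labels** order mechanism classes by the conventional
  precedence Immunotherapy, Targeted, Cytotoxic, Hormonal, then others
  alphabetically with "Other" last, so "Targeted + Cytotoxic + Cytotoxic"
  is the canonical form regardless of member order. Unmapped drugs class
  as "Other"; the drug→class map is user-supplied.

## Verification

- The grouping rule is checked against an independent brute-force oracle
  (exhaustive subset enumeration with independently restated filter
  clauses) on randomly generated predication sets of ≤ 6 records.
- The built-in GTI-2040 worked example must reduce to exactly one
  three-drug candidate through the full stack.
- Planted-truth recovery on the zero-noise synthetic corpus must reach
  precision = recall = 1.0, and no negated plant may survive when negation
  exclusion is on.
- All serializations are round-trip byte-stable; all filters idempotent.

Problem sizes used by the test suite and `scripts/acceptance.py` (200
synthetic abstracts, 1,000 oracle trials) were chosen as the smallest
sizes at which every claim category and combination size is exercised
many times over.

## Known limitations

- String-based broad-concept matching (above).
- The `D27.505` default branch prefix is an assumption about where
  pharmacologic actions live in the MeSH tree; override with
  `--action-prefix` if your release differs.
- No re-ranking or machine scoring of candidates; comparison and marker
  flags are provided precisely so a downstream classifier or curator can
  triage.
- Abstracts only; no full-text parsing, no PubMed retrieval client.
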