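"""Synthetic corpus generator with planted ground truth.

Real inputs to the pipeline are PubMed abstracts, a SemRep predication
run over their conclusive sentences, and a MeSH descriptor table — none
of which can be redistributed or downloaded at test time.  This module
emulates all three with templated text and planted combinations so that
every pipeline stage is testable end-to-end: each generated abstract
carries filler sentences plus one conclusive claim, and the predication
file contains the records a SemRep-style extractor would plausibly emit
for that claim (drug TREATS Patients plus drug TREATS(INFER) disease
pairs for combinations, COMPARED_WITH records for comparative
single-therapy claims, NEG_-prefixed predicates for negated findings,
and broad-concept contamination at configurable rates).

A truth table records what was planted in each claim, so discovery
precision and recall are computable exactly.  Identical seeds yield
byte-identical output files.

The module also ships the GTI-2040 worked example — the
"CONCLUSION: A combination of GTI-2040, capecitabine and oxaliplatin is
feasible in patients with advanced solid tumors." claim and the seven
predications an extractor emits for it — as a deterministic named
fixture.  Apart from that sentence and its concept names, all text and
identifiers here are synthetic.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .claims import AbstractRecord
from .predications import Predication

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_corpus",
    "read_truth_tsv",
    "evaluate_discovery",
    "worked_example_abstract",
    "worked_example_predications",
    "example_abstracts",
    "write_mesh_fixture",
]

# ---------------------------------------------------------------------------
# vocabulary pools (synthetic)
# ---------------------------------------------------------------------------

_DRUG_STEMS = (
    "velo", "dara", "miro", "calu", "zeta", "orli", "pexi", "tavo",
    "lumi", "sora", "nira", "gefa", "bora", "cilo", "ruda", "mave",
)
_DRUG_SUFFIXES = ("tinib", "mab", "platin", "taxel", "citabine", "rubicin")

_DISEASES = (
    ("CX0001", "advanced gastric carcinoma"),
    ("CX0002", "metastatic colorectal carcinoma"),
    ("CX0003", "relapsed follicular lymphoma"),
    ("CX0004", "non-small cell lung carcinoma"),
    ("CX0005", "hormone refractory prostate cancer"),
    ("CX0006", "recurrent ovarian carcinoma"),
    ("CX0007", "metastatic breast carcinoma"),
    ("CX0008", "advanced hepatocellular carcinoma"),
    ("CX0009", "refractory multiple myeloma"),
    ("CX0010", "advanced renal cell carcinoma"),
    ("CX0011", "metastatic pancreatic carcinoma"),
    ("CX0012", "recurrent glioblastoma"),
)

_PHARM_ACTIONS = (
    ("CA0001", "Antineoplastic Agents", "D27.505.954.248"),
    ("CA0002", "Anti-Inflammatory Agents", "D27.505.954.158"),
    ("CA0003", "Lipid Regulating Agents", "D27.505.954.502"),
    ("CA0004", "Immunosuppressive Agents", "D27.505.696.477"),
    ("CA0005", "Angiogenesis Inhibitors", "D27.505.954.248.050"),
)

# 2019-era MeSH category-C top level: one heading per undotted C-code.
_GENERIC_DISEASES = (
    ("C01", "Infections"), ("C02", "Virus Diseases"),
    ("C03", "Parasitic Diseases"), ("C04", "Neoplasms"),
    ("C05", "Musculoskeletal Diseases"), ("C06", "Digestive System Diseases"),
    ("C07", "Stomatognathic Diseases"), ("C08", "Respiratory Tract Diseases"),
    ("C09", "Otorhinolaryngologic Diseases"), ("C10", "Nervous System Diseases"),
    ("C11", "Eye Diseases"), ("C12", "Male Urogenital Diseases"),
    ("C13", "Female Urogenital Diseases and Pregnancy Complications"),
    ("C14", "Cardiovascular Diseases"), ("C15", "Hemic and Lymphatic Diseases"),
    ("C16", "Congenital, Hereditary, and Neonatal Diseases and Abnormalities"),
    ("C17", "Skin and Connective Tissue Diseases"),
    ("C18", "Nutritional and Metabolic Diseases"),
    ("C19", "Endocrine System Diseases"), ("C20", "Immune System Diseases"),
    ("C21", "Disorders of Environmental Origin"), ("C22", "Animal Diseases"),
    ("C23", "Pathological Conditions, Signs and Symptoms"),
    ("C24", "Occupational Diseases"), ("C25", "Chemically-Induced Disorders"),
    ("C26", "Wounds and Injuries"),
)

_PATIENTS = ("C0030705", "Patients")

_FILLERS = (
    "Eligible patients were enrolled between 2009 and 2019.",
    "The primary endpoint was progression-free survival.",
    "Treatment was administered in 21-day cycles.",
    "Adverse events were graded according to standard criteria.",
    "Median follow-up was 18 months.",
    "Dose reductions were permitted for hematologic toxicity.",
    "The objective response rate was assessed by independent review.",
    "Baseline characteristics were balanced between arms.",
    "Pharmacokinetic sampling was performed during cycle 1.",
    "Quality of life was assessed with validated questionnaires.",
)


def _drug_pool() -> list[tuple[str, str]]:
    pool = []
    i = 0
    for stem in _DRUG_STEMS:
        for suffix in _DRUG_SUFFIXES:
            i += 1
            pool.append((f"CD{i:04d}", stem + suffix))
    return pool


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus.

    Defaults mirror the conditions of the study the pipeline targets:
    every abstract has one conclusive claim; planted combination sizes
    follow the 210:43:2 split over 2/3/4 drugs observed for verified
    combinations; comparative single-therapy claims and negated
    findings occur at the rates of the curated error taxonomy
    (40/325 ≈ 0.12 comparisons; 17/325 ≈ 0.05 negation-missed claims).
    """

    n_abstracts: int = 200
    p_combination_claim: float = 0.6
    combo_size_dist: dict[int, float] = field(
        default_factory=lambda: {2: 210 / 255, 3: 43 / 255, 4: 2 / 255}
    )
    p_single_comparison: float = 0.12
    p_negation: float = 0.05
    p_generic_subject: float = 0.05
    p_generic_object: float = 0.05
    n_filler_sentences: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_combination_claim", "p_single_comparison",
                     "p_negation", "p_generic_subject", "p_generic_object"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.combo_size_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"combo_size_dist sums to {total}, expected 1")
        if not set(self.combo_size_dist) <= {2, 3, 4}:
            raise ValueError("combo sizes must be in {2, 3, 4}")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted in one generated conclusive claim."""

    sentence_id: str
    true_label: str  # combination | single_comparison | negated | contaminated | none
    planted_subjects: tuple[tuple[str, str], ...] = ()
    planted_object: tuple[str, str] | None = None
    planted_predicate: str = ""


# claim templates; {drugs} is the rendered drug-name list
_COMBO_TEMPLATES = (
    "CONCLUSION: A combination of {drugs} is feasible in patients with {disease}.",
    "We conclude that coadministration of {drugs} is effective in patients with {disease}.",
    "CONCLUSION: {first} co-administered with {rest} improved outcomes in patients with {disease}.",
    "In conclusion, the {drugs} regimen allows excellent long-lasting response in patients with {disease}.",
)
_COMPARISON_TEMPLATES = (
    "CONCLUSION: Both {a} and {b} had comparable efficacy in patients with {disease}.",
    "CONCLUSION: {a} plus either {b} or {c} was feasible in patients with {disease}.",
)
_NEGATED_TEMPLATE = (
    "CONCLUSION: The combination of {drugs} failed to improve outcomes in "
    "patients with {disease}."
)
_SINGLE_TEMPLATE = (
    "In conclusion, {a} monotherapy was well tolerated in patients with {disease}."
)


def _join_names(names: Sequence[str]) -> str:
    if len(names) == 1:
        return names[0]
    return ", ".join(names[:-1]) + " and " + names[-1]


def _pred(pmid: str, sid: str, subj: tuple[str, str], subj_types: str,
          predicate: str, obj: tuple[str, str], obj_types: str) -> Predication:
    return Predication(
        pmid=pmid, sentence_id=sid,
        subject_cui=subj[0], subject_name=subj[1],
        subject_semtypes=frozenset(subj_types.split(",")),
        predicate_raw=predicate,
        object_cui=obj[0], object_name=obj[1],
        object_semtypes=frozenset(obj_types.split(",")),
    )


def _combination_records(
    pmid: str, sid: str, drugs: Sequence[tuple[str, str]],
    disease: tuple[str, str], negated: bool,
) -> list[Predication]:
    """SemRep-style output for a combination claim: the disease is a
    process of the patient population, each drug directly TREATS
    Patients, and inference chains both into drug TREATS(INFER) disease."""
    neg = "NEG_" if negated else ""
    records = [
        _pred(pmid, sid, disease, "neop", "PROCESS_OF", _PATIENTS, "podg")
    ]
    for d in drugs:
        records.append(_pred(pmid, sid, d, "phsu,orch", f"{neg}TREATS",
                             _PATIENTS, "podg"))
        records.append(_pred(pmid, sid, d, "phsu,orch", f"{neg}TREATS(INFER)",
                             disease, "neop"))
    return records


def generate_corpus(
    cfg: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate abstracts (JSONL), predications (pipe dialect), a MeSH
    fixture table (TSV) and the truth table (TSV) under *outdir*.

    Returns the four paths keyed by "abstracts", "predications", "mesh",
    "truth".  Deterministic: the same config (including seed) yields
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)
    drugs_pool = _drug_pool()
    sizes = sorted(cfg.combo_size_dist)
    weights = [cfg.combo_size_dist[s] for s in sizes]

    abstracts: list[AbstractRecord] = []
    predications: list[Predication] = []
    truth: list[TruthRecord] = []

    for i in range(cfg.n_abstracts):
        pmid = str(30000000 + i)
        disease = rng.choice(_DISEASES)
        fillers = [rng.choice(_FILLERS) for _ in range(cfg.n_filler_sentences)]
        sentence_index = cfg.n_filler_sentences + 1
        sid = f"{pmid}.ab.{sentence_index}"

        if rng.random() < cfg.p_combination_claim:
            size = rng.choices(sizes, weights=weights)[0]
            drugs = rng.sample(drugs_pool, size)
            negated = rng.random() < cfg.p_negation
            contaminate_subject = (
                not negated and rng.random() < cfg.p_generic_subject
            )
            contaminate_object = (
                not negated and not contaminate_subject
                and rng.random() < cfg.p_generic_object
            )
            if contaminate_subject:
                # a broad pharmacologic-action heading usurps one drug
                # slot; only 2-drug claims are contaminated so the MeSH
                # filter leaves <2 subjects and the claim must vanish
                action = rng.choice(_PHARM_ACTIONS)
                drugs = [drugs[0], (action[0], action[1])]
                size = 2
            names = [n for _, n in drugs]
            obj = disease
            if contaminate_object:
                code, gname = rng.choice(_GENERIC_DISEASES)
                obj = (f"CG{code}", gname)
            if negated:
                text = _NEGATED_TEMPLATE.format(
                    drugs=_join_names(names), disease=obj[1]
                )
                label = "negated"
            else:
                tmpl = rng.choice(_COMBO_TEMPLATES)
                text = tmpl.format(
                    drugs=_join_names(names), first=names[0],
                    rest=_join_names(names[1:]), disease=obj[1],
                )
                label = (
                    "contaminated"
                    if contaminate_subject or contaminate_object
                    else "combination"
                )
            predications.extend(
                _combination_records(pmid, sid, drugs, obj, negated)
            )
            truth.append(TruthRecord(
                sentence_id=sid, true_label=label,
                planted_subjects=tuple(sorted(drugs)),
                planted_object=obj,
                planted_predicate="TREATS",
            ))
        elif rng.random() < cfg.p_single_comparison:
            tmpl = rng.choice(_COMPARISON_TEMPLATES)
            k = 3 if "{c}" in tmpl else 2
            drugs = rng.sample(drugs_pool, k)
            names = [n for _, n in drugs]
            text = tmpl.format(
                a=names[0], b=names[1], c=names[-1], disease=disease[1]
            )
            for d in drugs:
                predications.append(
                    _pred(pmid, sid, d, "phsu,orch", "TREATS", disease, "neop")
                )
            # the compared pair: last two names in the rendered sentence
            predications.append(
                _pred(pmid, sid, drugs[-2], "phsu,orch", "COMPARED_WITH",
                      drugs[-1], "phsu,orch")
            )
            truth.append(TruthRecord(
                sentence_id=sid, true_label="single_comparison",
                planted_subjects=tuple(sorted(drugs)),
                planted_object=disease, planted_predicate="TREATS",
            ))
        else:
            d = rng.choice(drugs_pool)
            text = _SINGLE_TEMPLATE.format(a=d[1], disease=disease[1])
            predications.append(
                _pred(pmid, sid, d, "phsu,orch", "TREATS", disease, "neop")
            )
            truth.append(TruthRecord(
                sentence_id=sid, true_label="none",
                planted_subjects=((d[0], d[1]),),
                planted_object=disease, planted_predicate="TREATS",
            ))

        abstracts.append(
            AbstractRecord(pmid=pmid, text=" ".join(fillers + [text]))
        )

    paths = {
        "abstracts": outdir / "abstracts.jsonl",
        "predications": outdir / "predications.psv",
        "mesh": outdir / "mesh.tsv",
        "truth": outdir / "truth.tsv",
    }
    with paths["abstracts"].open("w", encoding="utf-8", newline="") as fh:
        import json
        for a in abstracts:
            fh.write(json.dumps({"pmid": a.pmid, "abstract": a.text},
                                ensure_ascii=False) + "\n")
    from .predications import write_predications
    write_predications(predications, paths["predications"])
    write_mesh_fixture(paths["mesh"])
    _write_truth_tsv(truth, paths["truth"])
    return paths


def write_mesh_fixture(path: str | Path) -> None:
    """Write the synthetic MeSH descriptor table: the pharmacologic
    actions used by the generator (D27.505 branch), the 26 top-level
    category-C headings, and a few specific-disease descriptors that
    must NOT be caught by either filter."""
    rows = [
        (cui, name, tree) for cui, name, tree in _PHARM_ACTIONS
    ]
    rows += [
        (f"D{code}", name, code) for code, name in _GENERIC_DISEASES
    ]
    rows += [
        ("D008175", "Lung Neoplasms", "C04.588.894"),
        ("D001943", "Breast Neoplasms", "C04.588.180"),
        ("D000970", "Fluorouracil", "D03.383.742"),
    ]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("# ui\tname\ttree_numbers\n")
        for ui, name, trees in rows:
            fh.write(f"{ui}\t{name}\t{trees}\n")


def _write_truth_tsv(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sentence_id", "true_label", "planted_subjects",
                         "planted_object", "planted_predicate"])
        for t in truth:
            writer.writerow([
                t.sentence_id,
                t.true_label,
                "+".join(f"{c}:{n}" for c, n in t.planted_subjects),
                f"{t.planted_object[0]}:{t.planted_object[1]}"
                if t.planted_object else "",
                t.planted_predicate,
            ])


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            subjects = tuple(
                tuple(item.split(":", 1))
                for item in row["planted_subjects"].split("+") if item
            )
            obj = None
            if row["planted_object"]:
                cui, name = row["planted_object"].split(":", 1)
                obj = (cui, name)
            records.append(TruthRecord(
                sentence_id=row["sentence_id"],
                true_label=row["true_label"],
                planted_subjects=subjects,  # type: ignore[arg-type]
                planted_object=obj,
                planted_predicate=row["planted_predicate"],
            ))
    return records


def evaluate_discovery(groups, truth: Sequence[TruthRecord]) -> dict:
    """Precision/recall of discovered groups against planted truth.

    A discovered group is a true positive when a truth record labeled
    ``combination`` matches its subject-CUI set, base predicate and
    object CUI exactly.  Returns counts plus precision and recall
    (defined as 1.0 when the respective denominator is zero) and the
    number of discovered groups matching *negated* plants, which must
    stay zero whenever negation exclusion is on.
    """
    planted = {
        (t.sentence_id, frozenset(c for c, _ in t.planted_subjects),
         t.planted_predicate, t.planted_object[0]): t.true_label
        for t in truth if t.planted_object and len(t.planted_subjects) >= 2
    }
    n_true = sum(1 for lbl in planted.values() if lbl == "combination")
    tp = fp = negated_hits = 0
    for g in groups:
        k = (g.sentence_id, g.subject_cuis, g.predicate_base, g.object_cui)
        label = planted.get(k)
        if label == "combination":
            tp += 1
        else:
            fp += 1
            if label == "negated":
                negated_hits += 1
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / n_true if n_true else 1.0
    return {
        "n_planted_combinations": n_true,
        "n_discovered": tp + fp,
        "true_positives": tp,
        "false_positives": fp,
        "negated_plants_discovered": negated_hits,
        "precision": precision,
        "recall": recall,
    }


# ---------------------------------------------------------------------------
# the GTI-2040 worked example (deterministic named fixture)
# ---------------------------------------------------------------------------

_GTI_SENTENCE = (
    "CONCLUSION: A combination of GTI-2040, capecitabine and oxaliplatin "
    "is feasible in patients with advanced solid tumors."
)
_GTI_PMID = "19322566"
_GTI_SID = f"{_GTI_PMID}.ab.15"
_ASN = ("C2981143", "Advanced Malignant Solid Neoplasm")
_GTI_DRUGS = (
    ("C1101765", "GTI2040"),
    ("C0671970", "capecitabine"),
    ("C0069717", "oxaliplatin"),
)


def worked_example_abstract() -> AbstractRecord:
    """The GTI-2040 abstract with its conclusive claim as sentence 15.

    Only the conclusive sentence is authentic; the 14 sentences before
    it are synthetic filler so the 1-based index is exercised."""
    fillers = [_FILLERS[i % len(_FILLERS)] for i in range(14)]
    return AbstractRecord(
        pmid=_GTI_PMID, text=" ".join(fillers + [_GTI_SENTENCE])
    )


def worked_example_predications() -> list[Predication]:
    """The seven predications extracted from the GTI-2040 claim: the
    disease is a PROCESS_OF Patients, each of the three drugs TREATS
    Patients, and each is inferred to treat the disease."""
    records = [
        _pred(_GTI_PMID, _GTI_SID, _ASN, "neop", "PROCESS_OF",
              _PATIENTS, "podg")
    ]
    for d in _GTI_DRUGS:
        records.append(
            _pred(_GTI_PMID, _GTI_SID, d, "phsu,orch", "TREATS",
                  _PATIENTS, "podg")
        )
        records.append(
            _pred(_GTI_PMID, _GTI_SID, d, "phsu,orch", "TREATS(INFER)",
                  _ASN, "neop")
        )
    return records


_EXAMPLE_SENTENCES = {
    # pmid -> (1-based index of the conclusive sentence, its text)
    "19322566": (15, _GTI_SENTENCE),
    "28101592": (10, "In conclusion, FCM regimen allows excellent "
                     "long-lasting response in previously untreated "
                     "patients with FL."),
    "21198717": (10, "WHAT IS NEW AND CONCLUSION: The use of novel agents "
                     "such as thalidomide, bortezomib and lenalidomide for "
                     "RRMM is highly prevalent in France from the first "
                     "relapse."),
    "23197589": (8, "We conclude that intraventricular rituximab in "
                    "combination with MTX is feasible and highly active in "
                    "the treatment of drug-resistant CNS NHL that is "
                    "refractory or unresponsive to IV rituximab."),
}


def example_abstracts() -> list[AbstractRecord]:
    """Four example abstracts whose conclusive claims sit at known
    sentence positions (synthetic filler before each authentic claim)."""
    records = []
    for pmid, (index, sentence) in sorted(_EXAMPLE_SENTENCES.items()):
        fillers = [_FILLERS[i % len(_FILLERS)] for i in range(index - 1)]
        records.append(
            AbstractRecord(pmid=pmid, text=" ".join(fillers + [sentence]))
        )
    return records
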