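"""Semantic-predication parsing, normalization and treatment filtering.

A semantic predication is a subject–predicate–object triple whose
subject and object are normalized biomedical concepts (UMLS-style CUI +
preferred name + semantic types) and whose predicate comes from a fixed
relation inventory (TREATS, INHIBITS, PROCESS_OF, COMPARED_WITH, ...).
Predications arrive in a pipe-delimited file modeled on the SemMedDB
PREDICATION table; producers with native SemRep fielded output can
convert it with a few lines of awk (see docs/methods.md).

Raw predicates may carry two decorations that are normalized away here:

* a trailing ``(INFER)`` — the triple was inferred by chaining two
  directly extracted triples (e.g. drug TREATS patients + disease
  PROCESS_OF patients => drug TREATS(INFER) disease);
* a leading ``NEG_`` — the relation was asserted negated.

Discovery operates on the normalized base predicate; negated
predications are excluded by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Predication",
    "PredicationSet",
    "TypeConfig",
    "DEFAULT_TREATMENT_PREDICATES",
    "DEFAULT_DRUG_SEMTYPES",
    "DEFAULT_DISEASE_SEMTYPES",
    "normalize_predicate",
    "parse_predications",
    "parse_predication_line",
    "write_predications",
    "filter_treatment_predications",
    "group_by_sentence",
]

#: Predicates that closely relate to human disease treatment.
DEFAULT_TREATMENT_PREDICATES = frozenset(
    {"TREATS", "INHIBITS", "PREVENTS", "DISRUPTS"}
)

#: UMLS "Chemicals and Drugs" group — semantic-type abbreviations a
#: drug subject may carry.  Editable: see TypeConfig.from_files.
DEFAULT_DRUG_SEMTYPES = frozenset(
    {"phsu", "orch", "antb", "clnd", "aapp", "bacs", "horm", "imft",
     "vita", "enzy"}
)

#: "Disease or Syndrome" and child types an object must carry to count
#: as a disease (dsyn = disease or syndrome, neop = neoplastic process,
#: mobd = mental or behavioral dysfunction).
DEFAULT_DISEASE_SEMTYPES = frozenset({"dsyn", "neop", "mobd"})

_SENTENCE_ID_RE = re.compile(r"^.+\.ab\.\d+$")


def normalize_predicate(raw: str) -> tuple[str, bool, bool]:
    """Split a raw predicate into (base, inferred, negated).

    Strips exactly one trailing ``(INFER)`` and one leading ``NEG_`` if
    present; the base is uppercased.  ``NEG_TREATS(INFER)`` therefore
    yields ``("TREATS", True, True)``.
    """
    if not raw:
        raise ValueError("predicate must be non-empty")
    base = raw.strip()
    inferred = False
    negated = False
    if base.upper().endswith("(INFER)"):
        base = base[: -len("(INFER)")]
        inferred = True
    if base.upper().startswith("NEG_"):
        base = base[len("NEG_"):]
        negated = True
    return base.upper(), inferred, negated


@dataclass(frozen=True)
class Predication:
    """One subject–predicate–object record tied to a conclusive claim."""

    pmid: str
    sentence_id: str
    subject_cui: str
    subject_name: str
    subject_semtypes: frozenset[str]
    predicate_raw: str
    object_cui: str
    object_name: str
    object_semtypes: frozenset[str]
    predicate_base: str = field(default="", compare=True)
    inferred: bool = False
    negated: bool = False

    def __post_init__(self) -> None:
        if not self.predicate_base:
            base, inferred, negated = normalize_predicate(self.predicate_raw)
            object.__setattr__(self, "predicate_base", base)
            object.__setattr__(self, "inferred", inferred)
            object.__setattr__(self, "negated", negated)


@dataclass
class PredicationSet:
    """All predications extracted from one conclusive claim."""

    sentence_id: str
    predications: list[Predication]

    def __post_init__(self) -> None:
        for p in self.predications:
            if p.sentence_id != self.sentence_id:
                raise ValueError(
                    f"predication sentence_id {p.sentence_id!r} does not "
                    f"match set sentence_id {self.sentence_id!r}"
                )


@dataclass(frozen=True)
class TypeConfig:
    """Predicate and semantic-type restrictions for discovery.

    ``exclude_negated`` defaults to True: negated treatment claims
    (NEG_TREATS etc.) are dropped before grouping.  Setting it False
    restores the raw behaviour useful for error-taxonomy studies.
    """

    treatment_predicates: frozenset[str] = DEFAULT_TREATMENT_PREDICATES
    drug_semtypes: frozenset[str] = DEFAULT_DRUG_SEMTYPES
    disease_semtypes: frozenset[str] = DEFAULT_DISEASE_SEMTYPES
    exclude_negated: bool = True

    def __post_init__(self) -> None:
        if not (self.treatment_predicates and self.drug_semtypes
                and self.disease_semtypes):
            raise ValueError("type-config sets must be non-empty")

    @classmethod
    def from_files(
        cls,
        drug_semtypes_path: str | Path | None = None,
        disease_semtypes_path: str | Path | None = None,
        **kwargs,
    ) -> "TypeConfig":
        """Build a config reading semantic-type lists from one-per-line
        text files (blank lines and ``#`` comments ignored)."""

        def _load(path: str | Path) -> frozenset[str]:
            lines = Path(path).read_text(encoding="utf-8").splitlines()
            return frozenset(
                ln.strip() for ln in lines
                if ln.strip() and not ln.lstrip().startswith("#")
            )

        if drug_semtypes_path is not None:
            kwargs["drug_semtypes"] = _load(drug_semtypes_path)
        if disease_semtypes_path is not None:
            kwargs["disease_semtypes"] = _load(disease_semtypes_path)
        return cls(**kwargs)


_N_FIELDS = 9


def parse_predication_line(line: str, lineno: int = 0) -> Predication:
    """Parse one pipe-delimited predication record.

    Field order: pmid | sentence_id | subject_cui | subject_name |
    subject_semtypes (comma-joined) | predicate_raw | object_cui |
    object_name | object_semtypes (comma-joined).
    """
    parts = line.split("|")
    if len(parts) != _N_FIELDS:
        raise ValueError(
            f"predication line {lineno}: expected {_N_FIELDS} '|'-separated "
            f"fields, got {len(parts)}"
        )
    (pmid, sentence_id, s_cui, s_name, s_types,
     predicate, o_cui, o_name, o_types) = (p.strip() for p in parts)
    if not _SENTENCE_ID_RE.match(sentence_id):
        raise ValueError(
            f"predication line {lineno}: sentence_id {sentence_id!r} does "
            "not match 'PMID.ab.N'"
        )
    if not predicate:
        raise ValueError(f"predication line {lineno}: empty predicate field")
    return Predication(
        pmid=pmid,
        sentence_id=sentence_id,
        subject_cui=s_cui,
        subject_name=s_name,
        subject_semtypes=frozenset(t for t in s_types.split(",") if t),
        predicate_raw=predicate,
        object_cui=o_cui,
        object_name=o_name,
        object_semtypes=frozenset(t for t in o_types.split(",") if t),
    )


def parse_predications(source: str | Path) -> list[Predication]:
    """Parse a predication file (one record per line, ``#`` header lines
    and blank lines skipped).  Errors report the offending line number."""
    preds = []
    with Path(source).open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            preds.append(parse_predication_line(line, lineno))
    return preds


def format_predication_line(p: Predication) -> str:
    return "|".join(
        [
            p.pmid,
            p.sentence_id,
            p.subject_cui,
            p.subject_name,
            ",".join(sorted(p.subject_semtypes)),
            p.predicate_raw,
            p.object_cui,
            p.object_name,
            ",".join(sorted(p.object_semtypes)),
        ]
    )


def write_predications(preds: Iterable[Predication], path: str | Path) -> None:
    """Write predications back to the pipe-delimited dialect (round-trip
    safe: re-parsing yields records equal to the input)."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        handle.write(
            "# pmid|sentence_id|subject_cui|subject_name|subject_semtypes|"
            "predicate|object_cui|object_name|object_semtypes\n"
        )
        for p in preds:
            handle.write(format_predication_line(p) + "\n")


def filter_treatment_predications(
    preds: Iterable[Predication], cfg: TypeConfig | None = None
) -> list[Predication]:
    """Keep predications eligible for combination discovery.

    A predication survives iff its base predicate is a treatment
    predicate, its subject carries at least one drug semantic type, its
    object carries at least one disease semantic type, and (when
    ``cfg.exclude_negated``) it is not negated.  Inferred predications
    are judged on their base predicate, so TREATS(INFER) passes with
    TREATS.  Idempotent; output order follows input order.
    """
    cfg = cfg or TypeConfig()
    return [
        p for p in preds
        if p.predicate_base in cfg.treatment_predicates
        and p.subject_semtypes & cfg.drug_semtypes
        and p.object_semtypes & cfg.disease_semtypes
        and not (cfg.exclude_negated and p.negated)
    ]


def group_by_sentence(preds: Iterable[Predication]) -> dict[str, PredicationSet]:
    """Group predications by sentence_id, preserving file order."""
    buckets: dict[str, list[Predication]] = {}
    for p in preds:
        buckets.setdefault(p.sentence_id, []).append(p)
    return {
        sid: PredicationSet(sentence_id=sid, predications=ps)
        for sid, ps in buckets.items()
    }
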