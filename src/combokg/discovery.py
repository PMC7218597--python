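"""Combination-therapy discovery from filtered predications.

The discovery rule: within one conclusive claim, two or more semantic
predications S1-P-O, S2-P-O, ... that share the treatment predicate P
and the disease object O but have *different* drug subjects constitute
one piece of combined-therapy knowledge (S1+S2+...)-P-O.  Direct and
inferred forms of the same base predicate (TREATS and TREATS(INFER))
merge — this merging is exactly what turns the typical
"each drug TREATS(INFER) the disease" pattern of a combination claim
into a single multi-drug group.

Groups are never deleted for looking like a drug-vs-drug comparison;
they are flagged (``comparison_flag``) when a COMPARED_WITH predication
links two of the group's subjects, leaving triage to the caller.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .claims import Claim
from .mesh_filters import FilterLists, apply_filters
from .predications import (
    Predication,
    PredicationSet,
    TypeConfig,
    filter_treatment_predications,
)

__all__ = [
    "CandidateGroup",
    "discover_combinations",
    "flag_comparisons",
    "summarize_groups",
    "count_patterns",
    "pattern_label",
    "write_candidates_tsv",
    "read_candidates_tsv",
]


@dataclass(frozen=True)
class CandidateGroup:
    """A discovered combination: >=2 distinct drug subjects bound to one
    treatment predicate and one disease object within one claim.

    ``subjects`` is a tuple of (cui, name) pairs sorted by CUI;
    ``any_inferred`` records whether inference contributed at least one
    member; ``source_predication_count`` is the number of predications
    merged into the group.
    """

    sentence_id: str
    claim_text: str
    predicate_base: str
    object_cui: str
    object_name: str
    subjects: tuple[tuple[str, str], ...]
    any_inferred: bool = False
    markers: frozenset[str] = field(default_factory=frozenset)
    comparison_flag: bool = False
    source_predication_count: int = 0

    def __post_init__(self) -> None:
        cuis = [cui for cui, _ in self.subjects]
        if len(cuis) < 2:
            raise ValueError("a combination needs >= 2 subjects")
        if len(set(cuis)) != len(cuis):
            raise ValueError("duplicate subject CUIs in group")

    @property
    def subject_cuis(self) -> frozenset[str]:
        return frozenset(cui for cui, _ in self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def pmid(self) -> str:
        return self.sentence_id.rsplit(".ab.", 1)[0]


def discover_combinations(
    claim: Claim,
    preds: PredicationSet,
    cfg: TypeConfig | None = None,
    lists: FilterLists | None = None,
) -> list[CandidateGroup]:
    """Apply the discovery rule to one claim's predications.

    Pipeline: treatment filter (predicate/type/negation) -> broad-concept
    filter -> group by (base predicate, object CUI) -> emit every group
    with >=2 distinct subject CUIs.  Subjects are deduplicated by CUI
    (keeping the first name seen) and sorted by CUI; groups are sorted by
    (predicate, object CUI) so output is invariant under permutation of
    the input predications.
    """
    if preds.sentence_id != claim.sentence_id:
        raise ValueError(
            f"predication set {preds.sentence_id!r} does not belong to "
            f"claim {claim.sentence_id!r}"
        )
    kept = filter_treatment_predications(preds.predications, cfg)
    if lists is not None:
        kept = apply_filters(kept, lists)

    grouped: dict[tuple[str, str], list[Predication]] = {}
    for p in kept:
        grouped.setdefault((p.predicate_base, p.object_cui), []).append(p)

    groups: list[CandidateGroup] = []
    for (predicate, object_cui), members in sorted(grouped.items()):
        subject_names: dict[str, str] = {}
        for p in members:
            subject_names.setdefault(p.subject_cui, p.subject_name)
        if len(subject_names) < 2:
            continue
        groups.append(
            CandidateGroup(
                sentence_id=claim.sentence_id,
                claim_text=claim.text,
                predicate_base=predicate,
                object_cui=object_cui,
                object_name=members[0].object_name,
                subjects=tuple(sorted(subject_names.items())),
                any_inferred=any(p.inferred for p in members),
                markers=claim.markers,
                source_predication_count=len(members),
            )
        )
    return [replace(g, comparison_flag=flag_comparisons(g, preds)) for g in groups]


def flag_comparisons(group: CandidateGroup, all_preds: PredicationSet) -> bool:
    """True iff a COMPARED_WITH predication in the claim links two of the
    group's subjects (either direction).  Such groups typically come from
    comparative trials of *single* therapies and deserve triage, but the
    flag never deletes the group."""
    cuis = group.subject_cuis
    return any(
        p.predicate_base == "COMPARED_WITH"
        and p.subject_cui in cuis
        and p.object_cui in cuis
        and p.subject_cui != p.object_cui
        for p in all_preds.predications
    )


def summarize_groups(groups: Sequence[CandidateGroup]) -> dict:
    """Tabulate discovered groups.

    Returns counts by combination size, marker occurrence over the
    groups' claims (with "regimen" counted only when none of the other
    three markers is present, matching the reporting convention), and
    comparison-flag counts.  Marker tabulation is per distinct claim, so
    a claim yielding two groups is counted once.
    """
    by_size = Counter(g.n_subjects for g in groups)
    claims_seen: dict[str, frozenset[str]] = {}
    for g in groups:
        claims_seen.setdefault(g.sentence_id, g.markers)
    marker_counts: Counter[str] = Counter()
    for markers in claims_seen.values():
        others = markers - {"regimen"}
        for m in others:
            marker_counts[m] += 1
        if "regimen" in markers and not others:
            marker_counts["regimen"] += 1
    return {
        "n_groups": len(groups),
        "n_claims": len(claims_seen),
        "by_size": dict(sorted(by_size.items())),
        "markers": dict(sorted(marker_counts.items())),
        "n_comparison_flagged": sum(g.comparison_flag for g in groups),
        "n_any_inferred": sum(g.any_inferred for g in groups),
    }


#: Display order for mechanism classes in pattern labels; classes not
#: listed sort alphabetically after these, "Other" always last.
_CLASS_PRECEDENCE = ("Immunotherapy", "Targeted", "Cytotoxic", "Hormonal")


def pattern_label(classes: Iterable[str]) -> str:
    """Canonical, order-insensitive label for a multiset of mechanism
    classes, e.g. ``"Targeted + Cytotoxic + Cytotoxic"``."""

    def key(c: str):
        if c in _CLASS_PRECEDENCE:
            return (0, _CLASS_PRECEDENCE.index(c), c)
        if c == "Other":
            return (2, 0, c)
        return (1, 0, c)

    return " + ".join(sorted(classes, key=key))


def count_patterns(
    groups: Sequence[CandidateGroup],
    class_map: Mapping[str, str],
) -> Counter[str]:
    """Count combination-mechanism patterns.

    ``class_map`` maps a drug CUI or case-folded name to its mechanism
    class (e.g. Cytotoxic, Targeted, Immunotherapy); unmapped drugs fall
    into class "Other".  Each group contributes the multiset of its
    members' classes, labeled canonically.
    """
    folded = {k.casefold(): v for k, v in class_map.items()}
    counts: Counter[str] = Counter()
    for g in groups:
        classes = [
            folded.get(cui.casefold(), folded.get(name.casefold(), "Other"))
            for cui, name in g.subjects
        ]
        counts[pattern_label(classes)] += 1
    return counts


_CANDIDATE_COLUMNS = [
    "sentence_id", "predicate", "object_cui", "object_name", "subjects",
    "n_subjects", "any_inferred", "markers", "comparison_flag", "claim_text",
]


def write_candidates_tsv(
    groups: Iterable[CandidateGroup], path: str | Path
) -> None:
    """Write candidate groups as TSV; subjects are "CUI:name" joined
    with "+", sorted by CUI; rows sorted for reproducible diffs."""
    rows = sorted(
        groups, key=lambda g: (g.sentence_id, g.predicate_base, g.object_cui)
    )
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CANDIDATE_COLUMNS)
        for g in rows:
            writer.writerow([
                g.sentence_id,
                g.predicate_base,
                g.object_cui,
                g.object_name,
                "+".join(f"{cui}:{name}" for cui, name in g.subjects),
                g.n_subjects,
                int(g.any_inferred),
                ";".join(sorted(g.markers)),
                int(g.comparison_flag),
                g.claim_text,
            ])


def read_candidates_tsv(path: str | Path) -> list[CandidateGroup]:
    """Read a candidate TSV written by :func:`write_candidates_tsv`."""
    groups = []
    with Path(path).open(encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            subjects = tuple(
                tuple(item.split(":", 1)) for item in row["subjects"].split("+")
            )
            groups.append(
                CandidateGroup(
                    sentence_id=row["sentence_id"],
                    claim_text=row["claim_text"],
                    predicate_base=row["predicate"],
                    object_cui=row["object_cui"],
                    object_name=row["object_name"],
                    subjects=subjects,  # type: ignore[arg-type]
                    any_inferred=bool(int(row["any_inferred"])),
                    markers=frozenset(
                        m for m in row["markers"].split(";") if m
                    ),
                    comparison_flag=bool(int(row["comparison_flag"])),
                )
            )
    return groups
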