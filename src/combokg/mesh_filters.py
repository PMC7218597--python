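"""Broad-concept exclusion lists derived from a MeSH descriptor table.

Combination discovery should name *specific* drugs and diseases, but
concept extraction also emits broad headings: *pharmacologic actions*
("Antineoplastic Agents", "Anti-Inflammatory Agents", ...) as subjects,
and top-level disease classes ("Neoplasms", "Virus Diseases", ...) as
objects.  Two exclusion lists are built from a MeSH descriptor table:

* pharmacologic actions — every heading whose tree number descends from
  a configurable chemicals-and-drugs branch (default ``D27.505``, the
  Pharmacologic Actions subtree);
* generic disease names — the category-C root label itself plus every
  heading with an undotted category-C tree number (``C01`` ... ``C26``).

Matching against predications is by case-folded preferred-name string;
MeSH headings and UMLS preferred names largely coincide, and name
matching needs no UMLS license (a documented approximation).

The MeSH input is a three-column TSV distillate (ui, name, tree numbers
semicolon-joined) rather than native MeSH XML, so fixtures are plain
text and tiny; ``docs/methods.md`` shows how to produce the TSV from a
real MeSH release.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .predications import Predication

__all__ = [
    "MeshDescriptor",
    "FilterLists",
    "DEFAULT_ACTION_PREFIXES",
    "DEFAULT_DISEASE_ROOT_LABELS",
    "load_mesh",
    "tree_number_matches",
    "build_pharmacologic_actions",
    "build_generic_diseases",
    "build_filter_lists",
    "apply_filters",
]

#: MeSH branch holding pharmacologic-action headings.
DEFAULT_ACTION_PREFIXES: tuple[str, ...] = ("D27.505",)

#: The category-C root ("Diseases") is not itself a MeSH descriptor, so
#: its label is supplied explicitly.
DEFAULT_DISEASE_ROOT_LABELS: tuple[str, ...] = ("diseases",)

_TREE_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")
_TOPLEVEL_C_RE = re.compile(r"^C[0-9]+$")


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH heading: descriptor UI, preferred name, tree numbers."""

    ui: str
    name: str
    tree_numbers: frozenset[str]

    def __post_init__(self) -> None:
        for t in self.tree_numbers:
            if not _TREE_RE.match(t):
                raise ValueError(f"malformed tree number {t!r} on {self.ui}")


@dataclass(frozen=True)
class FilterLists:
    """The two exclusion sets, names case-folded; provenance records the
    source file and prefix configuration used to build them."""

    pharmacologic_actions: frozenset[str]
    generic_diseases: frozenset[str]
    provenance: str = ""


def load_mesh(source: str | Path) -> list[MeshDescriptor]:
    """Read the MeSH TSV dialect: ui<TAB>name<TAB>trees(;-joined).

    Blank lines and ``#`` comments are skipped; duplicate UIs and
    malformed tree numbers are rejected with the line number.
    """
    descriptors: list[MeshDescriptor] = []
    seen: dict[str, int] = {}
    with Path(source).open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"mesh TSV line {lineno}: expected 3 fields, got {len(parts)}"
                )
            ui, name, trees = (p.strip() for p in parts)
            if ui in seen:
                raise ValueError(
                    f"mesh TSV line {lineno}: duplicate descriptor UI {ui!r} "
                    f"(first seen on line {seen[ui]})"
                )
            seen[ui] = lineno
            try:
                desc = MeshDescriptor(
                    ui=ui,
                    name=name,
                    tree_numbers=frozenset(
                        t.strip() for t in trees.split(";") if t.strip()
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"mesh TSV line {lineno}: {exc}") from exc
            descriptors.append(desc)
    return descriptors


def tree_number_matches(tree: str, prefix: str) -> bool:
    """Segment-wise prefix test on dotted tree codes.

    ``D27.505`` matches ``D27.505`` and ``D27.505.954.248`` but not
    ``D27.5059`` — raw string prefixing would accept the latter.
    """
    t_parts = tree.split(".")
    p_parts = prefix.split(".")
    return t_parts[: len(p_parts)] == p_parts


def build_pharmacologic_actions(
    descriptors: Iterable[MeshDescriptor],
    prefixes: Sequence[str] = DEFAULT_ACTION_PREFIXES,
) -> frozenset[str]:
    """Names (case-folded) of headings at or below any action prefix."""
    if not prefixes:
        raise ValueError("at least one tree-code prefix is required")
    return frozenset(
        d.name.casefold()
        for d in descriptors
        if any(
            tree_number_matches(t, p) for t in d.tree_numbers for p in prefixes
        )
    )


def build_generic_diseases(
    descriptors: Iterable[MeshDescriptor],
    root_labels: Sequence[str] = DEFAULT_DISEASE_ROOT_LABELS,
) -> frozenset[str]:
    """Root label(s) plus names of headings with an undotted C-code.

    With the single default root label and one descriptor per C01–C26
    top-level heading this yields the 27-term generic-disease list.
    """
    names = {lbl.casefold() for lbl in root_labels}
    names.update(
        d.name.casefold()
        for d in descriptors
        if any(_TOPLEVEL_C_RE.match(t) for t in d.tree_numbers)
    )
    return frozenset(names)


def build_filter_lists(
    descriptors: Iterable[MeshDescriptor],
    action_prefixes: Sequence[str] = DEFAULT_ACTION_PREFIXES,
    root_labels: Sequence[str] = DEFAULT_DISEASE_ROOT_LABELS,
    provenance: str = "",
) -> FilterLists:
    descriptors = list(descriptors)
    return FilterLists(
        pharmacologic_actions=build_pharmacologic_actions(
            descriptors, action_prefixes
        ),
        generic_diseases=build_generic_diseases(descriptors, root_labels),
        provenance=provenance
        or f"prefixes={list(action_prefixes)} roots={list(root_labels)}",
    )


def apply_filters(
    preds: Iterable[Predication], lists: FilterLists
) -> list[Predication]:
    """Drop predications naming a broad concept.

    A predication is removed when its case-folded subject name is a
    pharmacologic action or its case-folded object name is a generic
    disease.  Idempotent, order-preserving, subset of input.
    """
    return [
        p for p in preds
        if p.subject_name.casefold() not in lists.pharmacologic_actions
        and p.object_name.casefold() not in lists.generic_diseases
    ]


def write_filter_list(names: Iterable[str], path: str | Path) -> None:
    """Export one filter list as one-name-per-line text (sorted)."""
    Path(path).write_text(
        "".join(n + "\n" for n in sorted(names)), encoding="utf-8"
    )
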