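"""Conclusive-claim extraction from biomedical abstracts.

A *conclusive claim* is a sentence of a PubMed-style abstract matched by
the wildcard keywords ``conclusion*`` / ``conclude*``.  Such sentences
summarise the validated knowledge content of a clinical study and are the
unit of discovery for the combination-therapy pipeline: every downstream
semantic predication is tied back to the claim it was extracted from via
a sentence identifier of the form ``PMID.ab.N`` (N = 1-based sentence
position within the abstract).

The module also detects the four surface *markers* that signal combined
medication in a claim: ``combin*``, ``coadministration``,
``co-administered`` and ``regimen``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "AbstractRecord",
    "Claim",
    "MARKER_PATTERNS",
    "split_sentences",
    "extract_conclusive_claims",
    "detect_markers",
    "read_abstracts",
    "write_claims_tsv",
    "read_claims_tsv",
]


@dataclass(frozen=True)
class AbstractRecord:
    """One abstract: PubMed identifier plus full abstract text.

    Structured-section labels such as ``CONCLUSION:`` are part of the
    text and are retained in extracted sentences.
    """

    pmid: str
    text: str

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not self.text:
            raise ValueError("abstract text must be non-empty")


@dataclass(frozen=True)
class Claim:
    """A conclusive sentence with provenance.

    ``sentence_id`` is ``pmid + ".ab." + sentence_index`` where
    ``sentence_index`` is the 1-based position of the sentence in the
    abstract.  ``markers`` holds the combination-marker labels found in
    the sentence text.
    """

    pmid: str
    sentence_index: int
    text: str
    markers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sentence_index < 1:
            raise ValueError("sentence_index is 1-based and must be >= 1")

    @property
    def sentence_id(self) -> str:
        return f"{self.pmid}.ab.{self.sentence_index}"


# Abbreviations whose trailing period must not end a sentence.  Kept
# deliberately short: abstracts are formal prose and over-protection
# breaks more boundaries than it saves.
_ABBREVIATIONS = (
    "vs", "dr", "mr", "mrs", "ms", "prof", "fig", "figs", "ref", "refs",
    "al", "e.g", "i.e", "ca", "approx", "no", "vol", "st",
)
_ABBREV_RE = re.compile(
    r"(?:^|\s)(?:" + "|".join(re.escape(a) for a in _ABBREVIATIONS) + r")\.$",
    re.IGNORECASE,
)

# A boundary is [.?!]+ followed by whitespace and an uppercase letter,
# digit or opening bracket/quote.  Decimal points never precede
# whitespace, so they are safe without special handling.
_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s+[\"'(\[]?[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split abstract text into sentences, order-preserving.

    Deterministic rule-based splitter: sentence ends at ``[.?!]``
    followed by whitespace and an uppercase letter or digit, unless the
    period terminates a known abbreviation.  Concatenating the result
    (modulo the inter-sentence whitespace) restores the input, which
    keeps the 1-based sentence numbering reproducible across runs.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        candidate = text[start : m.end()]
        if _ABBREV_RE.search(candidate):
            continue
        sentences.append(candidate.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# conclusion* / conclude* with wildcard = any word continuation; the
# shared stem "conclud" additionally admits "concluding".
_CONCLUSIVE_RE = re.compile(r"\b(?:conclusion|conclud)\w*", re.IGNORECASE)

#: Marker label -> compiled pattern.  ``combin*`` matches any token
#: beginning "combin"; the others are literal word matches (plural
#: "regimens" included).
MARKER_PATTERNS: dict[str, re.Pattern[str]] = {
    "combin*": re.compile(r"\bcombin\w*", re.IGNORECASE),
    "coadministration": re.compile(r"\bcoadministration\b", re.IGNORECASE),
    "co-administered": re.compile(r"\bco-administered\b", re.IGNORECASE),
    "regimen": re.compile(r"\bregimens?\b", re.IGNORECASE),
}


def detect_markers(text: str) -> frozenset[str]:
    """Return the set of combination-marker labels present in *text*.

    Matching is case-insensitive.  All matching markers are returned;
    the "regimen only in the absence of the others" rule is a
    tabulation convention applied by the summary stage, not here.
    """
    return frozenset(
        label for label, pat in MARKER_PATTERNS.items() if pat.search(text)
    )


def extract_conclusive_claims(abstract: AbstractRecord) -> list[Claim]:
    """Select the conclusive sentences of one abstract as claims.

    Every sentence whose text matches ``conclusion*`` or ``conclude*``
    (case-insensitive) becomes a :class:`Claim`; an abstract may
    contribute several.  Markers are detected on each selected sentence.
    """
    claims = []
    for idx, sentence in enumerate(split_sentences(abstract.text), start=1):
        if _CONCLUSIVE_RE.search(sentence):
            claims.append(
                Claim(
                    pmid=abstract.pmid,
                    sentence_index=idx,
                    text=sentence,
                    markers=detect_markers(sentence),
                )
            )
    return claims


# ---------------------------------------------------------------------------
# I/O: abstracts in (JSONL or 2-column TSV), claims out (TSV)
# ---------------------------------------------------------------------------

def _iter_jsonl(handle: TextIO) -> Iterator[AbstractRecord]:
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
            yield AbstractRecord(pmid=str(obj["pmid"]), text=obj["abstract"])
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"abstracts JSONL line {lineno}: {exc}") from exc


def _iter_tsv(handle: TextIO) -> Iterator[AbstractRecord]:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"abstracts TSV line {lineno}: expected 2 fields, got {len(parts)}"
            )
        yield AbstractRecord(pmid=parts[0], text=parts[1])


def read_abstracts(path: str | Path, fmt: str | None = None) -> list[AbstractRecord]:
    """Read abstract records from JSONL ({pmid, abstract}) or 2-column TSV.

    ``fmt`` is "jsonl" or "tsv"; when None it is inferred from the file
    suffix (.jsonl/.json -> JSONL, anything else -> TSV).
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".json"} else "tsv"
    with path.open(encoding="utf-8") as handle:
        if fmt == "jsonl":
            return list(_iter_jsonl(handle))
        if fmt == "tsv":
            return list(_iter_tsv(handle))
    raise ValueError(f"unknown abstract format: {fmt!r}")


_CLAIM_COLUMNS = ["sentence_id", "pmid", "sentence_index", "text", "markers"]


def write_claims_tsv(claims: Iterable[Claim], path: str | Path) -> None:
    """Write claims as TSV (markers semicolon-joined, sorted)."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CLAIM_COLUMNS)
        for c in claims:
            writer.writerow(
                [c.sentence_id, c.pmid, c.sentence_index, c.text,
                 ";".join(sorted(c.markers))]
            )


def read_claims_tsv(path: str | Path) -> list[Claim]:
    """Read a claims TSV written by :func:`write_claims_tsv`."""
    claims = []
    with Path(path).open(encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            markers = frozenset(
                m for m in row["markers"].split(";") if m
            )
            claims.append(
                Claim(
                    pmid=row["pmid"],
                    sentence_index=int(row["sentence_index"]),
                    text=row["text"],
                    markers=markers,
                )
            )
    return claims
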