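"""Combination-centric knowledge graph with claim-level evidence.

Classic triple stores draw one edge per drug-TREATS-disease triple,
which dissolves a combination into unrelated spokes.  Here the combined
drugs are first bound into a *combination node* which is then directed
at the disease, so a three-drug regimen renders as::

    drug A ──member_of──┐
    drug B ──member_of──┼──> [A+B+C] ──treats_like(TREATS)──> disease
    drug C ──member_of──┘

Each treats_like edge carries the supporting conclusive claims as
evidence items; identical combinations asserted in different claims
merge into one node with accumulated evidence.

Combination-node identity includes the predicate and the disease: the
same drug set treating two diseases yields two combination nodes, so a
disease-centred query returns self-contained clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .discovery import CandidateGroup

__all__ = [
    "KGNode",
    "KGEdge",
    "Evidence",
    "KnowledgeGraph",
    "combination_node_id",
    "build_graph",
    "query_by_disease",
    "export_d3_json",
    "import_d3_json",
    "export_triples_tsv",
    "to_networkx",
]


@dataclass(frozen=True)
class Evidence:
    """One supporting conclusive claim for a combination edge."""

    pmid: str
    sentence_id: str
    claim_text: str
    markers: frozenset[str] = field(default_factory=frozenset)
    any_inferred: bool = False

    def __post_init__(self) -> None:
        if not self.sentence_id.startswith(self.pmid + "."):
            raise ValueError(
                f"sentence_id {self.sentence_id!r} does not parse to "
                f"pmid {self.pmid!r}"
            )


@dataclass(frozen=True)
class KGNode:
    """Graph node: a drug, a disease, or a bound drug combination.

    ``cui`` is empty for combination nodes, whose identity lives in
    ``member_cuis`` (sorted) plus the predicate/object baked into ``id``.
    """

    id: str
    kind: str  # drug | disease | combination
    label: str
    cui: str = ""
    member_cuis: tuple[str, ...] = ()


@dataclass(frozen=True)
class KGEdge:
    """member_of (drug -> combination) or treats_like (combination ->
    disease, labeled with the base predicate)."""

    source: str
    target: str
    kind: str  # member_of | treats_like
    predicate: str = ""
    evidence: tuple[Evidence, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "treats_like" and not self.evidence:
            raise ValueError("treats_like edges must carry evidence")


@dataclass
class KnowledgeGraph:
    """Node/edge store with deterministic ordering for serialization."""

    nodes: dict[str, KGNode] = field(default_factory=dict)
    edges: list[KGEdge] = field(default_factory=list)

    def node_count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.nodes)
        return sum(1 for n in self.nodes.values() if n.kind == kind)

    def edge_count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.edges)
        return sum(1 for e in self.edges if e.kind == kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.nodes == other.nodes and sorted(
            self.edges, key=lambda e: (e.kind, e.source, e.target)
        ) == sorted(other.edges, key=lambda e: (e.kind, e.source, e.target))


def combination_node_id(
    member_cuis: Iterable[str], predicate: str, object_cui: str
) -> str:
    """Deterministic combination-node id:
    ``cmb:<sorted member CUIs "+"-joined>:<predicate>:<object CUI>``."""
    return f"cmb:{'+'.join(sorted(member_cuis))}:{predicate}:{object_cui}"


def build_graph(groups: Iterable[CandidateGroup]) -> KnowledgeGraph:
    """Assemble the knowledge graph from discovered candidate groups.

    Drug and disease nodes are unique per CUI.  Groups with identical
    (sorted member CUIs, predicate, object CUI) merge into a single
    combination node whose treats_like edge accumulates one evidence
    item per contributing claim.
    """
    nodes: dict[str, KGNode] = {}
    members: dict[str, list[KGEdge]] = {}
    evidence: dict[str, list[Evidence]] = {}
    combo_meta: dict[str, tuple[str, str]] = {}  # id -> (predicate, disease id)

    for g in groups:
        cuis = [cui for cui, _ in g.subjects]
        combo_id = combination_node_id(cuis, g.predicate_base, g.object_cui)
        disease_id = f"dis:{g.object_cui}"

        for cui, name in g.subjects:
            nodes.setdefault(
                f"drg:{cui}", KGNode(id=f"drg:{cui}", kind="drug",
                                     label=name, cui=cui)
            )
        nodes.setdefault(
            disease_id,
            KGNode(id=disease_id, kind="disease", label=g.object_name,
                   cui=g.object_cui),
        )
        if combo_id not in nodes:
            nodes[combo_id] = KGNode(
                id=combo_id,
                kind="combination",
                label=" + ".join(name for _, name in g.subjects),
                member_cuis=tuple(sorted(cuis)),
            )
            members[combo_id] = [
                KGEdge(source=f"drg:{cui}", target=combo_id, kind="member_of")
                for cui in sorted(cuis)
            ]
            combo_meta[combo_id] = (g.predicate_base, disease_id)
        evidence.setdefault(combo_id, []).append(
            Evidence(
                pmid=g.pmid,
                sentence_id=g.sentence_id,
                claim_text=g.claim_text,
                markers=g.markers,
                any_inferred=g.any_inferred,
            )
        )

    edges: list[KGEdge] = []
    for combo_id in sorted(members):
        edges.extend(members[combo_id])
        predicate, disease_id = combo_meta[combo_id]
        edges.append(
            KGEdge(
                source=combo_id,
                target=disease_id,
                kind="treats_like",
                predicate=predicate,
                evidence=tuple(
                    sorted(evidence[combo_id], key=lambda e: e.sentence_id)
                ),
            )
        )
    return KnowledgeGraph(nodes=nodes, edges=edges)


def query_by_disease(graph: KnowledgeGraph, disease: str) -> KnowledgeGraph:
    """Disease-centred subgraph: the disease node, every combination
    targeting it, their member drugs, and all evidence.

    ``disease`` may be a CUI or a preferred name (case-insensitive exact
    match).  Unknown disease -> empty graph.
    """
    wanted = disease.casefold()
    target_ids = {
        n.id for n in graph.nodes.values()
        if n.kind == "disease"
        and (n.cui.casefold() == wanted or n.label.casefold() == wanted)
    }
    if not target_ids:
        return KnowledgeGraph()

    treat_edges = [
        e for e in graph.edges
        if e.kind == "treats_like" and e.target in target_ids
    ]
    combo_ids = {e.source for e in treat_edges}
    member_edges = [
        e for e in graph.edges
        if e.kind == "member_of" and e.target in combo_ids
    ]
    keep_ids = (
        target_ids | combo_ids | {e.source for e in member_edges}
    )
    return KnowledgeGraph(
        nodes={nid: graph.nodes[nid] for nid in graph.nodes if nid in keep_ids},
        edges=member_edges + treat_edges,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_obj(n: KGNode) -> dict:
    obj = {"id": n.id, "kind": n.kind, "label": n.label}
    if n.cui:
        obj["cui"] = n.cui
    if n.member_cuis:
        obj["member_cuis"] = list(n.member_cuis)
    return obj


def _edge_obj(e: KGEdge) -> dict:
    obj: dict = {"source": e.source, "target": e.target, "kind": e.kind}
    if e.predicate:
        obj["predicate"] = e.predicate
    if e.evidence:
        obj["evidence"] = [
            {
                "pmid": ev.pmid,
                "sentence_id": ev.sentence_id,
                "claim_text": ev.claim_text,
                "markers": sorted(ev.markers),
                "any_inferred": ev.any_inferred,
            }
            for ev in e.evidence
        ]
    return obj


def export_d3_json(graph: KnowledgeGraph, path: str | Path | None = None) -> str:
    """Serialize to the D3 force-layout contract
    ``{"nodes": [...], "links": [...]}`` with sorted keys and stable
    node/link order, so re-export is byte-identical."""
    doc = {
        "nodes": [_node_obj(graph.nodes[nid]) for nid in sorted(graph.nodes)],
        "links": [
            _edge_obj(e)
            for e in sorted(
                graph.edges, key=lambda e: (e.kind, e.source, e.target)
            )
        ],
    }
    text = json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def import_d3_json(source: str | Path) -> KnowledgeGraph:
    """Inverse of :func:`export_d3_json` (accepts a path or a JSON
    string); import(export(G)) == G."""
    text = (
        Path(source).read_text(encoding="utf-8")
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        )
        else str(source)
    )
    doc = json.loads(text)
    nodes = {
        obj["id"]: KGNode(
            id=obj["id"],
            kind=obj["kind"],
            label=obj["label"],
            cui=obj.get("cui", ""),
            member_cuis=tuple(obj.get("member_cuis", ())),
        )
        for obj in doc["nodes"]
    }
    edges = [
        KGEdge(
            source=obj["source"],
            target=obj["target"],
            kind=obj["kind"],
            predicate=obj.get("predicate", ""),
            evidence=tuple(
                Evidence(
                    pmid=ev["pmid"],
                    sentence_id=ev["sentence_id"],
                    claim_text=ev["claim_text"],
                    markers=frozenset(ev.get("markers", ())),
                    any_inferred=ev.get("any_inferred", False),
                )
                for ev in obj.get("evidence", ())
            ),
        )
        for obj in doc["links"]
    ]
    return KnowledgeGraph(nodes=nodes, edges=edges)


def export_triples_tsv(graph: KnowledgeGraph, path: str | Path | None = None) -> str:
    """Flat interchange: one row per drug-MEMBER_OF-combination edge and
    one per combination-predicate-disease edge, evidence PMIDs joined."""
    lines = ["subject\tpredicate\tobject\tevidence_pmids"]
    for e in sorted(graph.edges, key=lambda e: (e.kind, e.source, e.target)):
        if e.kind == "member_of":
            lines.append(f"{e.source}\tMEMBER_OF\t{e.target}\t")
        else:
            pmids = ";".join(
                sorted({ev.pmid for ev in e.evidence})
            )
            lines.append(f"{e.source}\t{e.predicate}\t{e.target}\t{pmids}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def to_networkx(graph: KnowledgeGraph) -> nx.DiGraph:
    """Convert to a networkx DiGraph (e.g. for GraphML export via
    ``networkx.write_graphml``)."""
    g = nx.DiGraph()
    for n in graph.nodes.values():
        g.add_node(n.id, kind=n.kind, label=n.label, cui=n.cui)
    for e in graph.edges:
        g.add_edge(
            e.source, e.target, kind=e.kind, predicate=e.predicate,
            n_evidence=len(e.evidence),
        )
    return g
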