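"""End-to-end wiring: abstracts + predications + filters -> candidates.

Keeps the per-stage funnel counts (claims found, predications parsed,
survivors of the predicate/type filter, survivors of the broad-concept
filter, groups discovered) that the CLI logs after each run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .claims import AbstractRecord, Claim, extract_conclusive_claims
from .discovery import CandidateGroup, discover_combinations
from .mesh_filters import FilterLists, apply_filters
from .predications import (
    Predication,
    PredicationSet,
    TypeConfig,
    filter_treatment_predications,
    group_by_sentence,
)

__all__ = ["FunnelCounts", "run_discovery"]


@dataclass
class FunnelCounts:
    n_abstracts: int = 0
    n_claims: int = 0
    n_predications: int = 0
    n_after_treatment_filter: int = 0
    n_after_mesh_filter: int = 0
    n_groups: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def run_discovery(
    abstracts: Sequence[AbstractRecord],
    predications: Sequence[Predication],
    cfg: TypeConfig | None = None,
    lists: FilterLists | None = None,
    drop_comparisons: bool = False,
) -> tuple[list[Claim], list[CandidateGroup], FunnelCounts]:
    """Run claim extraction and combination discovery over a corpus.

    Predications are joined to claims by sentence_id; predications whose
    sentence has no conclusive claim are ignored (they came from
    non-conclusive sentences upstream).  With ``drop_comparisons`` the
    comparison-flagged groups are removed instead of merely flagged.
    """
    cfg = cfg or TypeConfig()
    counts = FunnelCounts(
        n_abstracts=len(abstracts), n_predications=len(predications)
    )

    claims: list[Claim] = []
    for a in abstracts:
        claims.extend(extract_conclusive_claims(a))
    counts.n_claims = len(claims)
    by_sentence = group_by_sentence(predications)

    survivors = filter_treatment_predications(predications, cfg)
    counts.n_after_treatment_filter = len(survivors)
    if lists is not None:
        survivors = apply_filters(survivors, lists)
    counts.n_after_mesh_filter = len(survivors)

    groups: list[CandidateGroup] = []
    for claim in claims:
        pset = by_sentence.get(claim.sentence_id)
        if pset is None:
            continue
        groups.extend(discover_combinations(claim, pset, cfg, lists))
    if drop_comparisons:
        groups = [g for g in groups if not g.comparison_flag]
    counts.n_groups = len(groups)
    return claims, groups, counts
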