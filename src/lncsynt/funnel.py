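"""The candidate-selection funnel.

Syntenic lncRNAs are winnowed through an ordered cascade of exclusion
filters:

  S1 conservation   — synteny status in an allowed set (collinear/syntenic)
  S2 trait overlap  — at least ``min_trait_neighbors`` of the k nearest
                      protein-coding neighbors belong to the consolidated
                      trait gene set (also reports the distinct trait genes
                      hit among all S1 survivors' neighbors)
  S3 multiexonic    — the lncRNA gene has a transcript with >= min_exons exons
  S4 single ortholog— the lncRNA has exactly ``required_ortholog_transcripts``
                      predicted target-species ortholog transcripts
  S5 prioritization — survivors ranked by the number of Mendelian-disease
                      neighbors (ties: trait neighbor count, then id)

The per-stage survivor counts form the pipeline's headline bookkeeping and
are returned alongside the ranked candidate table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotations_io import GeneSet, TranscriptModel
from .neighborhood import NeighborContext
from .synteny import STATUS_COLLINEAR, STATUS_SYNTENIC, SyntenyCall

log = logging.getLogger(__name__)

STAGE_NAMES = (
    "S1_conservation",
    "S2_trait_overlap",
    "S3_multiexonic",
    "S4_single_ortholog",
    "S5_prioritization",
)


class FunnelConsistencyError(Exception):
    """Inputs disagree (e.g. a lncRNA lacking a synteny call)."""


@dataclass
class FunnelConfig:
    k: int = 5
    min_trait_neighbors: int = 2
    min_exons: int = 2
    #: exact required count; None disables the filter (wildcard)
    required_ortholog_transcripts: Optional[int] = 1
    allowed_statuses: frozenset = frozenset({STATUS_COLLINEAR, STATUS_SYNTENIC})
    top_n: Optional[int] = None

    def __post_init__(self):
        self.allowed_statuses = frozenset(self.allowed_statuses)
        for name in ("k", "min_trait_neighbors", "min_exons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Stage:
    name: str
    n_in: int
    n_out: int
    surviving_ids: list


@dataclass
class FunnelReport:
    stages: list = field(default_factory=list)
    #: distinct trait genes among the neighbors of conservation-passing lncRNAs
    neighbor_overlap_count: int = 0

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out,
                 "surviving_ids": list(s.surviving_ids)}
                for s in self.stages
            ],
            "neighbor_overlap_count": self.neighbor_overlap_count,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class CandidateRecord:
    lncrna_id: str
    disease_neighbor_count: int
    trait_neighbor_count: int
    trait_sets_hit: set
    rank: int


def consolidate_trait_sets(sets: Sequence[GeneSet]) -> GeneSet:
    """Union several trait gene sets, keeping per-set membership."""
    if not sets:
        raise ValueError("at least one gene set required")
    union = set()
    members = {}
    for s in sets:
        union |= s.ids
        members[s.name] = set(s.ids)
    log.info(
        "consolidated %d sets (sizes %s) into %d genes",
        len(sets), [len(s) for s in sets], len(union),
    )
    return GeneSet(name="consolidated", ids=union, members_by_set=members)


def run_funnel(
    contexts: Sequence[NeighborContext],
    synteny: Sequence[SyntenyCall],
    transcripts: Sequence[TranscriptModel],
    trait: GeneSet,
    disease: GeneSet,
    ortholog_tx_counts: Mapping[str, int],
    config: FunnelConfig = None,
):
    """Run the five-stage funnel; returns (FunnelReport, [CandidateRecord])."""
    config = config or FunnelConfig()
    calls = {c.lncrna_id: c for c in synteny}
    ctx = {c.lncrna_id: c for c in contexts}
    missing = sorted(set(ctx) - set(calls))
    if missing:
        raise FunnelConsistencyError(
            "lncRNAs without a synteny call: " + ", ".join(missing)
        )
    max_exons: dict = {}
    for t in transcripts:
        max_exons[t.gene_id] = max(max_exons.get(t.gene_id, 0), t.exon_count)

    def trait_neighbors(lid):
        return [n.gene_id for n in ctx[lid].neighbors if n.gene_id in trait.ids]

    def disease_neighbors(lid):
        return [n.gene_id for n in ctx[lid].neighbors if n.gene_id in disease.ids]

    report = FunnelReport()
    current = sorted(ctx)  # lexicographic: order-independent bookkeeping

    def record(name, survivors):
        nonlocal current
        report.stages.append(Stage(name, len(current), len(survivors), survivors))
        log.info("%s: %d -> %d", name, len(current), len(survivors))
        current = survivors

    # S1: conservation
    record(STAGE_NAMES[0],
           [l for l in current if calls[l].status in config.allowed_statuses])

    # S2: trait overlap (and the distinct trait genes among S1 survivors' neighbors)
    report.neighbor_overlap_count = len(
        {g for l in current for g in trait_neighbors(l)}
    )
    record(STAGE_NAMES[1],
           [l for l in current
            if len(trait_neighbors(l)) >= config.min_trait_neighbors])

    # S3: multiexonic
    record(STAGE_NAMES[2],
           [l for l in current if max_exons.get(l, 0) >= config.min_exons])

    # S4: single predicted ortholog transcript
    def tx_count(lid):
        if lid not in ortholog_tx_counts:
            log.info("no ortholog transcript count for %s; treated as 0", lid)
            return 0
        return ortholog_tx_counts[lid]

    if config.required_ortholog_transcripts is None:
        record(STAGE_NAMES[3], list(current))
    else:
        record(STAGE_NAMES[3],
               [l for l in current
                if tx_count(l) == config.required_ortholog_transcripts])

    # S5: rank by Mendelian-disease neighbors
    scored = sorted(
        current,
        key=lambda l: (-len(disease_neighbors(l)), -len(trait_neighbors(l)), l),
    )
    if config.top_n is not None:
        scored = scored[: config.top_n]
    record(STAGE_NAMES[4], sorted(scored))

    candidates = []
    for rank, lid in enumerate(scored, start=1):
        tn = trait_neighbors(lid)
        candidates.append(
            CandidateRecord(
                lncrna_id=lid,
                disease_neighbor_count=len(disease_neighbors(lid)),
                trait_neighbor_count=len(tn),
                trait_sets_hit={
                    name for name, ids in trait.members_by_set.items()
                    if any(g in ids for g in tn)
                },
                rank=rank,
            )
        )
    return report, candidates
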