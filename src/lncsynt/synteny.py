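"""Synteny and collinearity calling for lncRNA neighborhoods.

A lncRNA neighborhood is projected into the target genome through an
ortholog map: each protein-coding neighbor with an ortholog contributes an
*anchor*.  The call distinguishes

- ``collinear`` — >= min_anchors anchors on one target chromosome whose
  positions, taken in query gene order, are strictly monotonic (whole-block
  inversion allowed: decreasing order means orientation ``-``);
- ``syntenic``  — quorum on one chromosome but order not preserved;
- ``not_conserved`` — anchors exist but no chromosome reaches quorum, or
  the anchor span exceeds ``max_span``;
- ``unmappable`` — fewer than min_anchors anchors altogether.

Anchor position is the ortholog's interval midpoint, which is robust to
length differences between orthologs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotations_io import GeneRecord, OrthologMap
from .neighborhood import NeighborContext

log = logging.getLogger(__name__)

STATUS_COLLINEAR = "collinear"
STATUS_SYNTENIC = "syntenic"
STATUS_NOT_CONSERVED = "not_conserved"
STATUS_UNMAPPABLE = "unmappable"


@dataclass(frozen=True)
class Anchor:
    """A neighbor gene placed in the target genome via its ortholog."""

    query_gene_id: str
    target_gene_id: str
    target_chrom: str
    target_start: int
    target_end: int

    @property
    def midpoint(self) -> float:
        return (self.target_start + self.target_end) / 2.0


@dataclass
class SyntenyCall:
    lncrna_id: str
    status: str
    anchor_count: int = 0
    target_chrom: Optional[str] = None
    orientation: Optional[str] = None  # '+', '-' or None
    inferred_interval: Optional[tuple] = None
    anchors: list = field(default_factory=list)


def resolve_anchors(
    context: NeighborContext,
    orthologs: OrthologMap,
    target_genes: Sequence[GeneRecord],
) -> list:
    """Map neighborhood genes to target-genome anchors.

    Neighbors with a single ortholog anchor directly.  A neighbor with
    several orthologs keeps only the one on the chromosome carrying the
    most candidate anchors overall (majority-chromosome consensus); if
    that still leaves a tie, or none of its orthologs lie on the majority
    chromosome, the neighbor is dropped from anchoring.
    """
    index = {g.gene_id: g for g in target_genes}
    candidates = []  # (neighbor gene_id, [target GeneRecord, ...])
    for n in context.neighbors:
        recs = []
        for tid in sorted(orthologs.forward(n.gene_id)):
            rec = index.get(tid)
            if rec is None:
                log.debug(
                    "ortholog %s of %s absent from target annotation; skipped",
                    tid,
                    n.gene_id,
                )
                continue
            recs.append(rec)
        if recs:
            candidates.append((n.gene_id, recs))
    if not candidates:
        return []

    votes = Counter(r.chrom for _, recs in candidates for r in recs)
    top = max(votes.values())
    majority_chrom = min(c for c, v in votes.items() if v == top)

    anchors = []
    for qid, recs in candidates:
        if len(recs) == 1:
            keep = recs[0]
        else:
            on_majority = [r for r in recs if r.chrom == majority_chrom]
            if len(on_majority) != 1:
                log.debug("ambiguous orthologs for %s; neighbor dropped", qid)
                continue
            keep = on_majority[0]
        anchors.append(
            Anchor(qid, keep.gene_id, keep.chrom, keep.start, keep.end)
        )
    return anchors


def _is_strictly_monotonic(values: Sequence[float]):
    """Return '+', '-' or None for a sequence of anchor positions."""
    if len(values) < 2:
        return "+"
    inc = all(a < b for a, b in zip(values, values[1:]))
    dec = all(a > b for a, b in zip(values, values[1:]))
    if inc:
        return "+"
    if dec:
        return "-"
    return None


def call_synteny(
    anchors: Sequence[Anchor],
    context: NeighborContext,
    min_anchors: int = 2,
    max_span: Optional[int] = None,
) -> SyntenyCall:
    """Classify the conservation of a lncRNA neighborhood from its anchors."""
    lnc = context.lncrna_id
    if len(anchors) < min_anchors:
        return SyntenyCall(lnc, STATUS_UNMAPPABLE, anchor_count=len(anchors),
                           anchors=list(anchors))

    by_chrom = Counter(a.target_chrom for a in anchors)
    top = max(by_chrom.values())
    if top < min_anchors:
        return SyntenyCall(lnc, STATUS_NOT_CONSERVED, anchor_count=len(anchors),
                           anchors=list(anchors))
    chrom = min(c for c, v in by_chrom.items() if v == top)
    on_chrom = [a for a in anchors if a.target_chrom == chrom]

    span = max(a.target_end for a in on_chrom) - min(a.target_start for a in on_chrom)
    if max_span is not None and span > max_span:
        return SyntenyCall(lnc, STATUS_NOT_CONSERVED, anchor_count=len(on_chrom),
                           target_chrom=chrom, anchors=on_chrom)

    # query gene order: signed offset from the lncRNA, then id for determinism
    ordered = sorted(
        on_chrom, key=lambda a: (context.signed_offset(a.query_gene_id), a.query_gene_id)
    )
    orientation = _is_strictly_monotonic([a.midpoint for a in ordered])

    interval = _infer_interval(ordered, context)
    if orientation is None:
        return SyntenyCall(lnc, STATUS_SYNTENIC, anchor_count=len(ordered),
                           target_chrom=chrom, orientation=None,
                           inferred_interval=interval, anchors=ordered)
    return SyntenyCall(lnc, STATUS_COLLINEAR, anchor_count=len(ordered),
                       target_chrom=chrom, orientation=orientation,
                       inferred_interval=interval, anchors=ordered)


def _infer_interval(ordered: Sequence[Anchor], context: NeighborContext):
    """Putative orthologous locus: the target gap between the two anchors
    flanking the lncRNA in query order; an overlapping anchor's own span
    when the lncRNA sits inside a neighbor; otherwise the whole anchor span."""
    overlap = [a for a in ordered if context.signed_offset(a.query_gene_id) == 0]
    if overlap:
        a = overlap[0]
        return (a.target_start, a.target_end)
    ups = [a for a in ordered if context.signed_offset(a.query_gene_id) < 0]
    downs = [a for a in ordered if context.signed_offset(a.query_gene_id) > 0]
    if ups and downs:
        left = max(ups, key=lambda a: context.signed_offset(a.query_gene_id))
        right = min(downs, key=lambda a: context.signed_offset(a.query_gene_id))
        lo = min(left.target_end, right.target_end)
        hi = max(left.target_start, right.target_start)
        if lo < hi:
            return (lo, hi)
    return (
        min(a.target_start for a in ordered),
        max(a.target_end for a in ordered),
    )
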