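"""Nearest protein-coding neighborhood of a lncRNA gene.

The discovery pipeline characterizes each lncRNA locus by its k closest
protein-coding genes on the same chromosome (k = 5 by default).  Distance
is the interval gap in bp — 0 when the intervals overlap or abut — and is
strand-agnostic: antisense overlaps (a lncRNA arising antisense to a 3'
UTR, say) rank first with distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotations_io import BIOTYPE_LNCRNA, BIOTYPE_PROTEIN_CODING, GeneRecord

SIDE_UPSTREAM = "upstream"
SIDE_DOWNSTREAM = "downstream"
SIDE_OVERLAPPING = "overlapping"


class UnknownGeneError(KeyError):
    pass


class BiotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Neighbor:
    gene_id: str
    distance: int
    side: str


@dataclass(frozen=True)
class NeighborContext:
    """A lncRNA with its nearest protein-coding genes, closest first."""

    lncrna_id: str
    chrom: str
    lncrna_start: int
    lncrna_end: int
    neighbors: tuple

    def signed_offset(self, gene_id: str) -> int:
        """Genomic-order key: negative upstream, 0 overlapping, positive downstream."""
        for n in self.neighbors:
            if n.gene_id == gene_id:
                if n.side == SIDE_UPSTREAM:
                    return -n.distance
                if n.side == SIDE_DOWNSTREAM:
                    return n.distance
                return 0
        raise UnknownGeneError(gene_id)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp separating two half-open intervals; 0 if they overlap or abut."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def _classify_side(gene: GeneRecord, lnc: GeneRecord) -> str:
    if interval_gap(gene.start, gene.end, lnc.start, lnc.end) == 0:
        return SIDE_OVERLAPPING
    return SIDE_UPSTREAM if gene.end <= lnc.start else SIDE_DOWNSTREAM


def extract_neighbors(
    genes: Sequence[GeneRecord],
    lncrna_id: str,
    k: int = 5,
    k_per_side: bool = False,
) -> NeighborContext:
    """Return the k nearest protein-coding genes of a lncRNA gene.

    With ``k_per_side`` the k nearest genes are taken on each side
    separately (overlapping genes count toward both budgets once,
    reported once).  Ties are broken by smaller gene start then gene_id,
    so the result is deterministic and invariant under permutation of
    ``genes``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    try:
        lnc = next(g for g in genes if g.gene_id == lncrna_id)
    except StopIteration:
        raise UnknownGeneError(f"gene id not found: {lncrna_id}") from None
    if lnc.biotype != BIOTYPE_LNCRNA:
        raise BiotypeError(f"{lncrna_id} has biotype {lnc.biotype}, expected lncRNA")

    scored = []
    for g in genes:
        if g.biotype != BIOTYPE_PROTEIN_CODING or g.chrom != lnc.chrom:
            continue
        d = interval_gap(g.start, g.end, lnc.start, lnc.end)
        scored.append((d, g.start, g.gene_id, _classify_side(g, lnc)))
    scored.sort()

    if k_per_side:
        chosen, n_up, n_down = [], 0, 0
        for d, start, gid, side in scored:
            if side == SIDE_OVERLAPPING:
                chosen.append((d, start, gid, side))
            elif side == SIDE_UPSTREAM and n_up < k:
                chosen.append((d, start, gid, side))
                n_up += 1
            elif side == SIDE_DOWNSTREAM and n_down < k:
                chosen.append((d, start, gid, side))
                n_down += 1
    else:
        chosen = scored[:k]

    return NeighborContext(
        lncrna_id=lncrna_id,
        chrom=lnc.chrom,
        lncrna_start=lnc.start,
        lncrna_end=lnc.end,
        neighbors=tuple(Neighbor(gid, d, side) for d, _, gid, side in chosen),
    )
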