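"""Genomic <-> transcript coordinate mapping over an exon chain.

Transcript coordinates are 1-based, counted 5'->3' along the transcript's
strand (the convention molecular biologists use to describe lesions such
as "a 12-bp deletion at position 594").  Genomic coordinates stay 0-based
half-open.  Because the printed inclusive-end and open-end renderings of a
deletion differ by one, annotations carry both.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Union

from .annotations_io import TranscriptModel


@dataclass(frozen=True)
class TranscriptCoordinateMap:
    """Bijection between exonic genomic positions and transcript positions 1..L."""

    transcript: TranscriptModel
    cumulative_exon_lengths: tuple

    @classmethod
    def from_transcript(cls, transcript: TranscriptModel) -> "TranscriptCoordinateMap":
        exons = cls._tx_order_exons(transcript)
        cum, total = [], 0
        for s, e in exons:
            total += e - s
            cum.append(total)
        return cls(transcript=transcript, cumulative_exon_lengths=tuple(cum))

    @staticmethod
    def _tx_order_exons(transcript: TranscriptModel):
        """Exons in transcript (5'->3') order."""
        exons = list(transcript.exons)
        return exons if transcript.strand == "+" else exons[::-1]

    @property
    def total_length(self) -> int:
        return self.cumulative_exon_lengths[-1]


def genomic_to_transcript(cmap: TranscriptCoordinateMap, gpos: int) -> Optional[int]:
    """1-based transcript position of a 0-based genomic position, or None
    when the position is intronic or outside the transcript."""
    t = cmap.transcript
    exons = TranscriptCoordinateMap._tx_order_exons(t)
    offset = 0
    for (s, e), cum in zip(exons, cmap.cumulative_exon_lengths):
        if s <= gpos < e:
            within = (gpos - s) if t.strand == "+" else (e - 1 - gpos)
            return offset + within + 1
        offset = cum
    return None


def transcript_to_genomic(cmap: TranscriptCoordinateMap, tpos: int) -> int:
    """0-based genomic position of a 1-based transcript position."""
    if not (1 <= tpos <= cmap.total_length):
        raise ValueError(f"transcript position {tpos} outside 1..{cmap.total_length}")
    idx = bisect_right(list(cmap.cumulative_exon_lengths), tpos - 1)
    prev = cmap.cumulative_exon_lengths[idx - 1] if idx else 0
    within = tpos - 1 - prev
    s, e = TranscriptCoordinateMap._tx_order_exons(cmap.transcript)[idx]
    return s + within if cmap.transcript.strand == "+" else e - 1 - within


@dataclass(frozen=True)
class DeletionAnnotation:
    """A genomic deletion projected into transcript space.

    ``tx_end_inclusive`` is the last deleted transcript base;
    ``tx_end_open`` is one past it — both renderings are kept because
    published lesion descriptions use either convention.
    """

    tx_start: Optional[int]
    tx_end_inclusive: Optional[int]
    tx_end_open: Optional[int]
    length: int
    exon_index: Union[int, str, None]  # 1-based transcript-order index, or "spans"


def annotate_deletion(cmap: TranscriptCoordinateMap, genomic_interval) -> DeletionAnnotation:
    """Describe which transcript bases a genomic deletion removes.

    ``length`` counts exonic bases only: a deletion spanning an
    exon/intron junction removes fewer transcript bases than its genomic
    footprint.  An entirely intronic deletion yields a zero-length
    annotation with no exon index.
    """
    gstart, gend = genomic_interval
    if gstart >= gend:
        raise ValueError("empty genomic interval")
    t = cmap.transcript
    exons = TranscriptCoordinateMap._tx_order_exons(t)
    tx_positions, exon_indices = [], set()
    for i, (s, e) in enumerate(exons, start=1):
        lo, hi = max(s, gstart), min(e, gend)
        for g in range(lo, hi):
            tx_positions.append(genomic_to_transcript(cmap, g))
            exon_indices.add(i)
    if not tx_positions:
        return DeletionAnnotation(None, None, None, 0, None)
    first, last = min(tx_positions), max(tx_positions)
    exon_index: Union[int, str]
    exon_index = exon_indices.pop() if len(exon_indices) == 1 else "spans"
    return DeletionAnnotation(
        tx_start=first,
        tx_end_inclusive=last,
        tx_end_open=last + 1,
        length=len(tx_positions),
        exon_index=exon_index,
    )
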