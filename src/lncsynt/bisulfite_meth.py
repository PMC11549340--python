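"""Targeted-amplicon bisulfite methylation calling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
T) while 5-methylcytosine resists conversion.  On the original-top (OT)
strand this shows up as C->T changes; on the original-bottom (OB) strand,
viewed in forward-strand coordinates, as G->A changes.  Reads from a
single amplicon are placed by an exhaustive ungapped, bisulfite-aware
scan (read T matches reference C on OT; read A matches reference G on
OB), and each covered CpG yields one methylated/unmethylated/ambiguous
call.  Per-CpG tallies give the percentage methylation profile;
conversion efficiency is estimated from non-CpG cytosines, where
methylation is assumed absent.

Positions throughout are 1-based on the amplicon forward strand, matching
how CpG sites in an amplicon are usually enumerated; the bedGraph writer
converts to 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

STRAND_OT = "OT"
STRAND_OB = "OB"

CALL_METH = "methylated"
CALL_UNMETH = "unmethylated"
CALL_AMBIG = "ambiguous"

_VALID = set("ACGT")


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRef:
    """A bisulfite amplicon with its CpG cytosine positions (1-based, forward)."""

    name: str
    seq: str
    cpg_positions: tuple

    @classmethod
    def from_sequence(cls, name: str, seq: str) -> "AmpliconRef":
        seq = seq.upper()
        if set(seq) - _VALID:
            raise AlphabetError(f"non-ACGT characters in amplicon {name}")
        if len(seq) < 20:
            raise ValueError("amplicon too short (< 20 bp)")
        cpgs = tuple(
            i + 1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
        return cls(name=name, seq=seq, cpg_positions=cpgs)

    @classmethod
    def from_fasta(cls, path: str) -> "AmpliconRef":
        rec = next(SeqIO.parse(path, "fasta"))
        return cls.from_sequence(rec.id, str(rec.seq))


@dataclass
class ReadAssignment:
    read_id: str
    offset: int
    strand: str
    mismatches: int
    #: (cpg_position, call) for every CpG the read covers
    calls: list = field(default_factory=list)
    #: (converted, unconverted) tallies over covered non-CpG cytosines
    non_cpg: tuple = (0, 0)


@dataclass
class CpGRow:
    position: int
    n_methylated: int = 0
    n_unmethylated: int = 0
    n_ambiguous: int = 0

    @property
    def percent(self) -> Optional[float]:
        n = self.n_methylated + self.n_unmethylated
        if n == 0:
            return None
        return 100.0 * self.n_methylated / n


@dataclass
class MethylationProfile:
    amplicon: str
    rows: list = field(default_factory=list)
    conversion_efficiency: Optional[float] = None

    def to_tsv(self, path: str) -> None:
        lines = ["position\tn_methylated\tn_unmethylated\tn_ambiguous\tpercent"]
        for r in self.rows:
            pct = "NA" if r.percent is None else f"{r.percent:.2f}"
            lines.append(
                f"{r.position}\t{r.n_methylated}\t{r.n_unmethylated}"
                f"\t{r.n_ambiguous}\t{pct}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_bedgraph(self, path: str) -> None:
        lines = []
        for r in self.rows:
            if r.percent is None:
                continue
            lines.append(
                f"{self.amplicon}\t{r.position - 1}\t{r.position}\t{r.percent:.2f}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def bisulfite_convert(seq: str, strand: str, methylated_positions: set) -> str:
    """In-silico bisulfite chemistry on a forward-strand sequence.

    OT: every C whose 1-based position is not in ``methylated_positions``
    becomes T.  OB: complement-strand logic rendered on the forward
    representation — every unprotected G becomes A.  Converting an
    already-converted sequence is a no-op (idempotence).
    """
    seq = seq.upper()
    if set(seq) - _VALID:
        raise AlphabetError("non-ACGT characters in sequence")
    if strand == STRAND_OT:
        src = "C"
        dst = "T"
    elif strand == STRAND_OB:
        src = "G"
        dst = "A"
    else:
        raise ValueError(f"strand must be OT or OB, got {strand!r}")
    out = [
        dst if (b == src and (i + 1) not in methylated_positions) else b
        for i, b in enumerate(seq)
    ]
    return "".join(out)


def _mismatches(read: str, ref_window: str, strand: str) -> int:
    n = 0
    if strand == STRAND_OT:
        for r, c in zip(read, ref_window):
            if r != c and not (c == "C" and r == "T"):
                n += 1
    else:
        for r, c in zip(read, ref_window):
            if r != c and not (c == "G" and r == "A"):
                n += 1
    return n


def assign_read(
    read: str,
    ref: AmpliconRef,
    max_mismatch_rate: float = 0.1,
    read_id: str = "read",
) -> Optional[ReadAssignment]:
    """Place a read on the amplicon by exhaustive ungapped scan.

    All offsets on both bisulfite strands are scored; the fewest-mismatch
    placement wins (ties: lowest offset, OT before OB).  Returns None when
    even the best placement exceeds ``max_mismatch_rate``.
    """
    read = read.upper()
    L, R = len(ref.seq), len(read)
    if R > L:
        return None
    best = None  # (mismatches, strand_rank, offset)
    for strand_rank, strand in enumerate((STRAND_OT, STRAND_OB)):
        for off in range(L - R + 1):
            mm = _mismatches(read, ref.seq[off : off + R], strand)
            key = (mm, off, strand_rank)
            if best is None or key < best:
                best = key
    mm, off, strand_rank = best
    if mm > math.floor(max_mismatch_rate * R):
        return None
    strand = (STRAND_OT, STRAND_OB)[strand_rank]

    calls = []
    for p in ref.cpg_positions:
        # the informative base is the C (OT) or the paired G at p+1 (OB)
        probe = p if strand == STRAND_OT else p + 1
        idx = probe - 1 - off
        if not (0 <= idx < R):
            continue
        base = read[idx]
        if strand == STRAND_OT:
            call = {"C": CALL_METH, "T": CALL_UNMETH}.get(base, CALL_AMBIG)
        else:
            call = {"G": CALL_METH, "A": CALL_UNMETH}.get(base, CALL_AMBIG)
        calls.append((p, call))

    cpg_set = set(ref.cpg_positions)
    converted = unconverted = 0
    for i in range(off, off + R):
        pos = i + 1
        base = read[i - off]
        if strand == STRAND_OT and ref.seq[i] == "C" and pos not in cpg_set:
            if base == "T":
                converted += 1
            elif base == "C":
                unconverted += 1
        elif strand == STRAND_OB and ref.seq[i] == "G" and (pos - 1) not in cpg_set:
            if base == "A":
                converted += 1
            elif base == "G":
                unconverted += 1
    return ReadAssignment(
        read_id=read_id,
        offset=off,
        strand=strand,
        mismatches=mm,
        calls=calls,
        non_cpg=(converted, unconverted),
    )


def call_profile(assignments: Sequence[ReadAssignment], ref: AmpliconRef) -> MethylationProfile:
    """Aggregate per-read CpG calls into a per-CpG methylation profile."""
    rows = {p: CpGRow(position=p) for p in ref.cpg_positions}
    converted = unconverted = 0
    for a in assignments:
        if a is None:
            continue
        for p, call in a.calls:
            row = rows[p]
            if call == CALL_METH:
                row.n_methylated += 1
            elif call == CALL_UNMETH:
                row.n_unmethylated += 1
            else:
                row.n_ambiguous += 1
        converted += a.non_cpg[0]
        unconverted += a.non_cpg[1]
    if not any(
        r.n_methylated or r.n_unmethylated or r.n_ambiguous for r in rows.values()
    ):
        log.warning("no read assignments for amplicon %s; profile is all-NA", ref.name)
    eff = None
    if converted + unconverted > 0:
        eff = converted / (converted + unconverted)
    return MethylationProfile(
        amplicon=ref.name,
        rows=[rows[p] for p in ref.cpg_positions],
        conversion_efficiency=eff,
    )


def read_reads(path: str, fmt: Optional[str] = None):
    """Load reads from FASTA or FASTQ (qualities ignored) as (id, seq) pairs."""
    if fmt is None:
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]
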