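"""Genome annotations, gene sets and ortholog maps.

All interval coordinates are 0-based half-open internally.  GFF3/GTF use
1-based inclusive coordinates on disk and are converted at the boundary;
BED12 is already 0-based half-open.  Downstream modules only ever see the
internal convention.
"""

from __future__ import annotations

import logging
import os
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils

log = logging.getLogger(__name__)

BIOTYPE_PROTEIN_CODING = "protein_coding"
BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_OTHER = "other"

#: disk spellings folded into the three internal biotype classes
_DEFAULT_BIOTYPE_MAP = {
    "protein_coding": BIOTYPE_PROTEIN_CODING,
    "protein-coding": BIOTYPE_PROTEIN_CODING,
    "mrna": BIOTYPE_PROTEIN_CODING,
    "lncrna": BIOTYPE_LNCRNA,
    "lincrna": BIOTYPE_LNCRNA,
    "lnc_rna": BIOTYPE_LNCRNA,
    "antisense": BIOTYPE_LNCRNA,
}


class AnnotationError(Exception):
    """Base class for annotation-layer failures."""


class ParseError(AnnotationError):
    """A line of an input file does not parse in the declared dialect."""


class OrphanRecordError(AnnotationError):
    """Transcripts reference parent genes absent from the file."""

    def __init__(self, orphan_ids: Sequence[str]):
        self.orphan_ids = list(orphan_ids)
        super().__init__(
            "transcripts with no parent gene: " + ", ".join(self.orphan_ids)
        )


class EmptyGeneSetError(AnnotationError):
    """A gene-set file contained no usable identifiers."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene as an interval on a chromosome.

    ``start``/``end`` are 0-based half-open; ``biotype`` is one of
    ``protein_coding``, ``lncRNA`` or ``other``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain on one chromosome.

    Exons are (start, end) pairs, 0-based half-open, sorted by start and
    pairwise non-overlapping regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        if len(self.exons) < 1:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneSet:
    """A named set of gene identifiers (e.g. a Zfin-style keyword list)."""

    name: str
    ids: set = field(default_factory=set)
    #: per-source membership kept when several sets are consolidated
    members_by_set: dict = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)


class OrthologMap:
    """Many-to-many cross-species gene pairing with two-way lookup."""

    def __init__(self, pairs: Iterable[tuple] = ()):
        self._fwd: dict = defaultdict(set)
        self._rev: dict = defaultdict(set)
        self.pairs: set = set()
        for q, t in pairs:
            self.add(q, t)

    def add(self, query_gene_id: str, target_gene_id: str) -> None:
        if query_gene_id == target_gene_id:
            raise ValueError(f"self-pair not allowed: {query_gene_id}")
        self.pairs.add((query_gene_id, target_gene_id))
        self._fwd[query_gene_id].add(target_gene_id)
        self._rev[target_gene_id].add(query_gene_id)

    def forward(self, query_gene_id: str) -> set:
        return set(self._fwd.get(query_gene_id, ()))

    def reverse(self, target_gene_id: str) -> set:
        return set(self._rev.get(target_gene_id, ()))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, OrthologMap) and self.pairs == other.pairs


def _normalize_biotype(raw: str | None, biotype_map: Mapping[str, str] | None) -> str:
    if raw is None:
        return BIOTYPE_OTHER
    if biotype_map and raw in biotype_map:
        return biotype_map[raw]
    return _DEFAULT_BIOTYPE_MAP.get(raw.lower(), BIOTYPE_OTHER)


def _validate_tabular(path: str, n_cols: int, dialect: str) -> None:
    """Cheap structural pre-pass so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {n_cols} tab-separated fields "
                    f"for {dialect}, got {len(fields)}"
                )
            if dialect in ("gff3", "gtf"):
                try:
                    int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer coordinates in {dialect} line"
                    ) from None


_TRANSCRIPT_FEATURETYPES = (
    "transcript",
    "mRNA",
    "lnc_RNA",
    "lincRNA",
    "ncRNA",
    "antisense_RNA",
)


def read_annotation(path, format="gff3", biotype_map=None):
    """Read a genome annotation into (genes, transcripts).

    Parameters
    ----------
    path : str
        Annotation file.
    format : {"gff3", "gtf", "bed12"}
        Dialect on disk.  GFF3/GTF must contain explicit gene and
        transcript/mRNA features with exon children (Ensembl-style).
    biotype_map : mapping, optional
        Overrides for folding raw ``gene_biotype``/``biotype`` attribute
        values into the internal classes.

    Returns
    -------
    (list of GeneRecord, list of TranscriptModel)
    """
    if format == "bed12":
        return _read_bed12(path)
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format: {format!r}")
    _validate_tabular(path, 9, format)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneRecord] = []
    gene_ids: set[str] = set()
    for f in db.features_of_type("gene"):
        raw_bt = None
        for key in ("gene_biotype", "biotype", "gene_type"):
            if key in f.attributes:
                raw_bt = f.attributes[key][0]
                break
        genes.append(
            GeneRecord(
                gene_id=f.id,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                biotype=_normalize_biotype(raw_bt, biotype_map),
            )
        )
        gene_ids.add(f.id)
    transcripts: list[TranscriptModel] = []
    orphans: list[str] = []
    for ftype in _TRANSCRIPT_FEATURETYPES:
        for f in db.features_of_type(ftype):
            parents = [g.id for g in db.parents(f, featuretype="gene")]
            if not parents:
                orphans.append(f.id)
                continue
            exons = sorted(
                ((e.start - 1, e.end) for e in db.children(f, featuretype="exon")),
            )
            if not exons:
                exons = [(f.start - 1, f.end)]
            transcripts.append(
                TranscriptModel(
                    transcript_id=f.id,
                    gene_id=parents[0],
                    chrom=f.seqid,
                    strand=f.strand if f.strand in "+-" else "+",
                    exons=tuple(exons),
                )
            )
    if orphans:
        raise OrphanRecordError(orphans)
    return genes, transcripts


def _read_bed12(path):
    """BED12 transcripts; genes synthesized one-per-transcript (no parent info)."""
    genes, transcripts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed BED12 numeric field") from None
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            gid = name + "_gene"
            genes.append(
                GeneRecord(gid, chrom, start, end, strand, BIOTYPE_OTHER)
            )
            transcripts.append(
                TranscriptModel(name, gid, chrom, strand, exons)
            )
    return genes, transcripts


def write_annotation(genes, transcripts, path, format="gff3"):
    """Write the internal model back to disk (GFF3 or flat TSV).

    Output is canonical: genes sorted by (chrom, start, gene_id), each gene
    followed by its transcripts and their exons, so read -> write is a
    byte-stable round trip on files the writer produced.
    """
    if format == "gff3":
        _write_gff3(genes, transcripts, path)
    elif format == "tsv":
        _write_tsv(genes, transcripts, path)
    else:
        raise ValueError(f"unknown output format: {format!r}")


def _atomic_open_lines(path, lines):
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_gff3(genes, transcripts, path):
    by_gene = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(
            f"{g.chrom}\tlncsynt\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};biotype={g.biotype}"
        )
        for t in sorted(by_gene.get(g.gene_id, ()), key=lambda t: t.transcript_id):
            lines.append(
                f"{t.chrom}\tlncsynt\ttranscript\t{t.exons[0][0] + 1}\t{t.exons[-1][1]}"
                f"\t.\t{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}"
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                lines.append(
                    f"{t.chrom}\tlncsynt\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
    _atomic_open_lines(path, lines)


def _write_tsv(genes, transcripts, path):
    lines = ["gene_id\tchrom\tstart\tend\tstrand\tbiotype"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(
            f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.biotype}"
        )
    _atomic_open_lines(path, lines)


def read_gene_set(path, name):
    """Read a one-id-per-line gene list; '#' comments and blanks ignored."""
    ids = set()
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok or tok.startswith("#"):
                continue
            n_lines += 1
            ids.add(tok)
    if not ids:
        raise EmptyGeneSetError(f"{path}: no gene identifiers found")
    log.info("gene set %s: %d lines, %d unique ids", name, n_lines, len(ids))
    return GeneSet(name=name, ids=ids)


def write_gene_set(gene_set, path):
    _atomic_open_lines(path, sorted(gene_set.ids))


def _looks_like_header(first, second) -> bool:
    lowered = (first.lower(), second.lower())
    return any(
        tok in ("query", "target", "query_gene_id", "target_gene_id", "gene_id")
        for tok in lowered
    )


def read_ortholog_map(path):
    """Read a 2-column TSV of (query_gene_id, target_gene_id) pairs.

    A header row is auto-detected from conventional column names.
    Many-to-many relations are preserved; lookups work in both directions.
    """
    omap = OrthologMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(*fields):
                continue
            omap.add(fields[0], fields[1])
    return omap


def write_ortholog_map(omap, path):
    lines = ["query_gene_id\ttarget_gene_id"]
    lines.extend(f"{q}\t{t}" for q, t in sorted(omap.pairs))
    _atomic_open_lines(path, lines)
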