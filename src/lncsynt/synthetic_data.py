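"""Synthetic paired genomes, gene sets, ortholog maps and bisulfite reads.

The generator emulates the input structure of a synteny-based lncRNA
discovery study: a query genome annotated with protein-coding and lncRNA
genes, a target genome derived from it by whole-block inversions, single-
gene translocations and ortholog loss, keyword-style trait gene sets, a
Mendelian-disease gene set, and a predicted-ortholog-transcript table.

Candidate lncRNAs are *planted*: their neighborhoods are shielded from
rearrangement and their features are forced to satisfy every funnel
criterion.  Decoys are constructed to violate exactly one named criterion
each ("conservation", "trait", "exon", "ortholog_tx"), so a recovery test
can attribute each elimination to the stage that should have caused it.
A full truth table accompanies every simulation.

All randomness flows from one integer seed, fanned out to per-component
streams via numpy SeedSequence spawn keys (layout=0, features=1, sets=2,
rearrangement=3, reads=4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .annotations_io import (
    BIOTYPE_LNCRNA,
    BIOTYPE_PROTEIN_CODING,
    GeneRecord,
    GeneSet,
    OrthologMap,
    TranscriptModel,
)
from .bisulfite_meth import STRAND_OB, STRAND_OT, AmpliconRef

ROLE_PLANTED = "planted"
ROLE_BACKGROUND = "background"
CRITERIA = ("conservation", "trait", "exon", "ortholog_tx")
#: funnel stage at which a decoy violating each criterion must disappear
DECOY_STAGE = {
    "conservation": "S1_conservation",
    "trait": "S2_trait_overlap",
    "exon": "S3_multiexonic",
    "ortholog_tx": "S4_single_ortholog",
}


class SimConfigError(ValueError):
    """Parameter combination makes the requested planting infeasible."""


@dataclass
class GenomeSimParams:
    seed: int = 0
    n_chromosomes: int = 10
    genes_per_chromosome: int = 120
    lncrna_fraction: float = 0.28
    mean_gene_length: int = 2000
    mean_gap: int = 1000
    exon_count_distribution: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.35, 3: 0.25}
    )
    ortholog_retention: float = 0.90
    inversion_rate: float = 0.05
    translocation_rate: float = 0.02
    paralog_rate: float = 0.03
    trait_set_sizes: dict = field(
        default_factory=lambda: {"heart": 250, "blood_vessels": 110, "endothelium": 30}
    )
    disease_fraction: float = 0.10
    n_planted_candidates: int = 10
    n_decoys_per_criterion: int = 3
    k_neighbors: int = 5

    def validate(self) -> None:
        for name in ("lncrna_fraction", "ortholog_retention", "inversion_rate",
                     "translocation_rate", "paralog_rate", "disease_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        probs = list(self.exon_count_distribution.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise SimConfigError("exon_count_distribution must be a probability map")
        if sum(self.trait_set_sizes.values()) < 2 * self.n_planted_candidates:
            raise SimConfigError(
                "trait sets too small to plant the requested candidates "
                f"(need >= {2 * self.n_planted_candidates} slots)"
            )
        if self.n_chromosomes < 2:
            raise SimConfigError("need at least 2 chromosomes")
        if (self.n_decoys_per_criterion > 0
                and self.n_chromosomes < min(self.k_neighbors, 2) + 1):
            raise SimConfigError("too few chromosomes to scatter decoy anchors")


@dataclass
class LncTruth:
    status: str
    trait_neighbor_count: int
    disease_neighbor_count: int
    max_exons: int
    ortholog_tx_count: int
    anchor_count: int
    role: str  # planted / decoy_<criterion> / background


@dataclass
class SimTruth:
    planted_candidate_ids: list
    #: decoy lncRNA id -> violated criterion name
    decoys: dict
    per_lncrna: dict  # id -> LncTruth


@dataclass
class SimulatedPair:
    params: GenomeSimParams
    query_genes: list
    query_transcripts: list
    target_genes: list
    target_transcripts: list
    orthologs: OrthologMap
    gene_sets: dict  # name -> GeneSet (trait sets + "mendelian_disease")
    ortholog_tx_counts: dict
    truth: SimTruth

    @property
    def trait_sets(self) -> list:
        return [v for k, v in sorted(self.gene_sets.items())
                if k != "mendelian_disease"]

    @property
    def disease_set(self) -> GeneSet:
        return self.gene_sets["mendelian_disease"]


def _rngs(seed: int, n: int = 5):
    base = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in base.spawn(n)]


def _make_exons(start: int, end: int, n: int, rng) -> tuple:
    """Split [start, end) into n exons separated by nonempty introns."""
    total = end - start
    if n == 1 or total < 2 * n + (n - 1):
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, total), size=2 * (n - 1), replace=False))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    return tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n))


def _gap_distance(a: GeneRecord, b: GeneRecord) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _nearest_pc(genes_on_chrom: Sequence[GeneRecord], lnc: GeneRecord, k: int):
    """Brute-force k nearest protein-coding genes (query-side truth)."""
    pcs = [g for g in genes_on_chrom if g.biotype == BIOTYPE_PROTEIN_CODING]
    pcs.sort(key=lambda g: (_gap_distance(g, lnc), g.start, g.gene_id))
    return pcs[:k]


def simulate_genome_pair(params: GenomeSimParams) -> SimulatedPair:
    """Generate a query/target genome pair with planted funnel candidates."""
    params.validate()
    rng_layout, rng_feat, rng_sets, rng_rearr, _ = _rngs(params.seed)

    # ---- query genome layout -------------------------------------------
    query_genes: List[GeneRecord] = []
    counter = 0
    for c in range(1, params.n_chromosomes + 1):
        chrom = f"q{c}"
        pos = 0
        for _ in range(params.genes_per_chromosome):
            pos += 200 + int(rng_layout.geometric(1.0 / params.mean_gap))
            length = 200 + int(rng_layout.geometric(1.0 / params.mean_gene_length))
            is_lnc = rng_layout.random() < params.lncrna_fraction
            counter += 1
            gid = f"q_{'lnc' if is_lnc else 'pc'}_{counter:04d}"
            query_genes.append(
                GeneRecord(
                    gene_id=gid,
                    chrom=chrom,
                    start=pos,
                    end=pos + length,
                    strand="+" if rng_layout.random() < 0.5 else "-",
                    biotype=BIOTYPE_LNCRNA if is_lnc else BIOTYPE_PROTEIN_CODING,
                )
            )
            pos += length

    by_chrom: Dict[str, list] = {}
    for g in query_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    lncs = [g for g in query_genes if g.biotype == BIOTYPE_LNCRNA]
    pcs = [g for g in query_genes if g.biotype == BIOTYPE_PROTEIN_CODING]

    # ---- roles: planted candidates and one-criterion decoys ------------
    neighbors = {
        l.gene_id: _nearest_pc(by_chrom[l.chrom], l, params.k_neighbors)
        for l in lncs
    }
    roles: Dict[str, str] = {}
    wanted = [(ROLE_PLANTED, params.n_planted_candidates)] + [
        (f"decoy_{c}", params.n_decoys_per_criterion) for c in CRITERIA
    ]
    order = sorted(lncs, key=lambda g: g.gene_id)
    rng_feat.shuffle(order)
    claimed: set = set()
    for role, n_needed in wanted:
        n_got = 0
        for l in order:
            if n_got == n_needed:
                break
            if l.gene_id in roles:
                continue
            nb = neighbors[l.gene_id]
            if len(nb) < params.k_neighbors:
                continue
            nb_ids = {g.gene_id for g in nb}
            if nb_ids & claimed:
                continue
            roles[l.gene_id] = role
            claimed |= nb_ids
            n_got += 1
        if n_got < n_needed:
            raise SimConfigError(
                f"could not place {n_needed} lncRNAs for role {role}; "
                "increase genes_per_chromosome or reduce planting"
            )
    planted = sorted(l for l, r in roles.items() if r == ROLE_PLANTED)
    decoys = {l: r.removeprefix("decoy_") for l, r in roles.items()
              if r != ROLE_PLANTED}

    # ---- transcripts (exon structure; forced for special lncRNAs) ------
    exon_counts = sorted(params.exon_count_distribution)
    exon_probs = [params.exon_count_distribution[k] for k in exon_counts]
    transcripts: List[TranscriptModel] = []
    max_exons: Dict[str, int] = {}
    for g in query_genes:
        if g.biotype == BIOTYPE_PROTEIN_CODING:
            n_ex = int(rng_feat.integers(2, 9))
        else:
            role = roles.get(g.gene_id, ROLE_BACKGROUND)
            if role == "decoy_exon":
                n_ex = 1
            elif role != ROLE_BACKGROUND:
                n_ex = 2 + int(rng_feat.random() < 0.3)
            else:
                n_ex = int(rng_feat.choice(exon_counts, p=exon_probs))
        exons = _make_exons(g.start, g.end, n_ex, rng_feat)
        transcripts.append(
            TranscriptModel(f"{g.gene_id}.t1", g.gene_id, g.chrom, g.strand, exons)
        )
        max_exons[g.gene_id] = len(exons)

    # ---- trait and disease gene sets -----------------------------------
    set_names = sorted(params.trait_set_sizes)
    sizes = np.array([params.trait_set_sizes[n] for n in set_names], dtype=float)
    weights = sizes / sizes.sum()
    trait_sets = {n: set() for n in set_names}
    blacklist: set = set()  # genes that must stay out of every trait set

    def _require_trait(gene_ids):
        for gid in gene_ids:
            primary = rng_sets.choice(set_names, p=weights)
            trait_sets[primary].add(gid)
            if len(set_names) > 1 and rng_sets.random() < 0.2:
                other = rng_sets.choice([n for n in set_names if n != primary])
                trait_sets[other].add(gid)

    for lid in sorted(roles):
        nb = neighbors[lid]
        role = roles[lid]
        if role == "decoy_trait":
            _require_trait([nb[0].gene_id])
            blacklist |= {g.gene_id for g in nb[1:]}
        else:
            n_req = 2 + (1 if (role == ROLE_PLANTED and rng_sets.random() < 0.5) else 0)
            _require_trait([g.gene_id for g in nb[:n_req]])

    all_pc_ids = sorted(g.gene_id for g in pcs)
    for name in set_names:
        pool = [g for g in all_pc_ids
                if g not in blacklist and g not in trait_sets[name]]
        deficit = params.trait_set_sizes[name] - len(trait_sets[name])
        if deficit > 0:
            picks = rng_sets.choice(pool, size=min(deficit, len(pool)), replace=False)
            trait_sets[name].update(str(p) for p in picks)

    n_disease = int(round(params.disease_fraction * len(all_pc_ids)))
    disease_ids = {
        str(x) for x in rng_sets.choice(all_pc_ids, size=n_disease, replace=False)
    }

    gene_sets = {n: GeneSet(name=n, ids=trait_sets[n]) for n in set_names}
    gene_sets["mendelian_disease"] = GeneSet(name="mendelian_disease", ids=disease_ids)
    trait_union = set().union(*trait_sets.values())

    # ---- ortholog transcript counts ------------------------------------
    ortholog_tx_counts: Dict[str, int] = {}
    for l in sorted(g.gene_id for g in lncs):
        role = roles.get(l, ROLE_BACKGROUND)
        if role == "decoy_ortholog_tx":
            ortholog_tx_counts[l] = 2
        elif role != ROLE_BACKGROUND:
            ortholog_tx_counts[l] = 1
        else:
            ortholog_tx_counts[l] = int(rng_feat.choice([0, 2, 3], p=[0.6, 0.3, 0.1]))

    # ---- target genome: inversion / translocation / loss ---------------
    protected_group: Dict[str, str] = {}  # pc gene id -> owning special lncRNA
    scatter_genes: Dict[str, list] = {}   # conservation-decoy id -> its neighbor ids
    for lid, role in roles.items():
        nb_ids = [g.gene_id for g in neighbors[lid]]
        if role == "decoy_conservation":
            scatter_genes[lid] = nb_ids
        else:
            for gid in nb_ids:
                protected_group[gid] = lid
    scatter_flat = {g for ids in scatter_genes.values() for g in ids}

    chrom_order: Dict[str, list] = {}
    held_out: Dict[str, GeneRecord] = {}
    for c in range(1, params.n_chromosomes + 1):
        lst = []
        for g in by_chrom[f"q{c}"]:
            if g.biotype != BIOTYPE_PROTEIN_CODING:
                continue
            if g.gene_id in scatter_flat:
                held_out[g.gene_id] = g
                continue
            if (g.gene_id not in protected_group
                    and rng_rearr.random() < 1.0 - params.ortholog_retention):
                continue  # ortholog lost
            lst.append(g)
        chrom_order[f"t{c}"] = lst

    flipped: set = set()
    for tchrom in sorted(chrom_order):
        lst = chrom_order[tchrom]
        i = 0
        while i < len(lst) - 1:
            if rng_rearr.random() < params.inversion_rate:
                blen = 2 + int(rng_rearr.geometric(1.0 / 3.0))
                j = min(len(lst), i + blen)
                block_ids = {g.gene_id for g in lst[i:j]}
                groups = {protected_group[g] for g in block_ids if g in protected_group}
                ok = all(
                    {gid for gid, owner in protected_group.items() if owner == grp
                     and any(gid == x.gene_id for x in lst)} <= block_ids
                    for grp in groups
                )
                if ok:
                    lst[i:j] = lst[i:j][::-1]
                    flipped ^= block_ids
                    i = j
                    continue
            i += 1

    moves = []
    for tchrom in sorted(chrom_order):
        for g in list(chrom_order[tchrom]):
            if (g.gene_id not in protected_group
                    and rng_rearr.random() < params.translocation_rate):
                chrom_order[tchrom].remove(g)
                moves.append(g)
    for g in moves:
        dest = f"t{int(rng_rearr.integers(1, params.n_chromosomes + 1))}"
        idx = int(rng_rearr.integers(0, len(chrom_order[dest]) + 1))
        chrom_order[dest].insert(idx, g)

    # scatter each conservation decoy's anchors onto distinct chromosomes
    for lid in sorted(scatter_genes):
        ids = scatter_genes[lid]
        n_dest = min(len(ids), params.n_chromosomes)
        dests = rng_rearr.choice(
            np.arange(1, params.n_chromosomes + 1), size=n_dest, replace=False
        )
        for gid, d in zip(ids[:n_dest], dests):
            g = held_out[gid]
            lst = chrom_order[f"t{int(d)}"]
            lst.insert(int(rng_rearr.integers(0, len(lst) + 1)), g)
        # any leftover neighbors (fewer chromosomes than neighbors) stay lost

    # paralog copies on random chromosomes (multi-ortholog noise)
    paralogs = []
    for tchrom in sorted(chrom_order):
        for g in chrom_order[tchrom]:
            if (g.gene_id not in protected_group and g.gene_id not in scatter_flat
                    and rng_rearr.random() < params.paralog_rate):
                paralogs.append(g)
    for g in paralogs:
        dest = f"t{int(rng_rearr.integers(1, params.n_chromosomes + 1))}"
        lst = chrom_order[dest]
        copy = GeneRecord(g.gene_id + "#p", g.chrom, g.start, g.end, g.strand,
                          g.biotype)
        lst.insert(int(rng_rearr.integers(0, len(lst) + 1)), copy)

    # ---- lay out target coordinates ------------------------------------
    target_genes: List[GeneRecord] = []
    target_transcripts: List[TranscriptModel] = []
    orthologs = OrthologMap()
    for tchrom in sorted(chrom_order):
        pos = 0
        for g in chrom_order[tchrom]:
            pos += 200 + int(rng_rearr.geometric(1.0 / params.mean_gap))
            length = g.end - g.start
            qid = g.gene_id.split("#")[0]
            tid = "t" + qid[1:] + ("#p" if g.gene_id.endswith("#p") else "")
            strand = g.strand
            if qid in flipped and not g.gene_id.endswith("#p"):
                strand = "+" if strand == "-" else "-"
            rec = GeneRecord(tid, tchrom, pos, pos + length, strand,
                             BIOTYPE_PROTEIN_CODING)
            target_genes.append(rec)
            target_transcripts.append(
                TranscriptModel(tid + ".t1", tid, tchrom, strand,
                                ((pos, pos + length),))
            )
            orthologs.add(qid, tid)
            pos += length

    # ---- truth table ----------------------------------------------------
    target_by_id = {g.gene_id: g for g in target_genes}
    per_lnc: Dict[str, LncTruth] = {}
    for l in lncs:
        nb = neighbors[l.gene_id]
        status, n_anchors = _brute_status(l, nb, orthologs, target_by_id)
        role = roles.get(l.gene_id, ROLE_BACKGROUND)
        nb_ids = {g.gene_id for g in nb}
        per_lnc[l.gene_id] = LncTruth(
            status=status,
            trait_neighbor_count=len(nb_ids & trait_union),
            disease_neighbor_count=len(nb_ids & disease_ids),
            max_exons=max_exons[l.gene_id],
            ortholog_tx_count=ortholog_tx_counts[l.gene_id],
            anchor_count=n_anchors,
            role=role,
        )

    return SimulatedPair(
        params=params,
        query_genes=query_genes,
        query_transcripts=transcripts,
        target_genes=target_genes,
        target_transcripts=target_transcripts,
        orthologs=orthologs,
        gene_sets=gene_sets,
        ortholog_tx_counts=ortholog_tx_counts,
        truth=SimTruth(
            planted_candidate_ids=planted,
            decoys=decoys,
            per_lncrna=per_lnc,
        ),
    )


def _brute_status(lnc, nb, orthologs, target_by_id):
    """Direct conservation check used for the truth table.

    Walks the neighborhood in query order, projects unambiguous anchors,
    and classifies by counting and monotonicity — written independently of
    the synteny module's call path.
    """
    per_neighbor = []
    for g in nb:
        recs = [target_by_id[t] for t in sorted(orthologs.forward(g.gene_id))
                if t in target_by_id]
        if recs:
            per_neighbor.append((g, recs))
    votes: Dict[str, int] = {}
    for _, recs in per_neighbor:
        for r in recs:
            votes[r.chrom] = votes.get(r.chrom, 0) + 1
    anchors = []
    if votes:
        best = max(votes.values())
        major = min(c for c, v in votes.items() if v == best)
        for g, recs in per_neighbor:
            if len(recs) == 1:
                anchors.append((g, recs[0]))
            else:
                on = [r for r in recs if r.chrom == major]
                if len(on) == 1:
                    anchors.append((g, on[0]))
    if len(anchors) < 2:
        return "unmappable", len(anchors)
    chrom_counts: Dict[str, int] = {}
    for _, r in anchors:
        chrom_counts[r.chrom] = chrom_counts.get(r.chrom, 0) + 1
    top = max(chrom_counts.values())
    if top < 2:
        return "not_conserved", len(anchors)
    chrom = min(c for c, v in chrom_counts.items() if v == top)
    on_chrom = [(g, r) for g, r in anchors if r.chrom == chrom]
    on_chrom.sort(key=lambda pair: (pair[0].start, pair[0].gene_id))
    mids = [(r.start + r.end) / 2 for _, r in on_chrom]
    inc = all(a < b for a, b in zip(mids, mids[1:]))
    dec = all(a > b for a, b in zip(mids, mids[1:]))
    return ("collinear" if inc or dec else "syntenic"), len(on_chrom)


# ---------------------------------------------------------------------------
# bisulfite read simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class BisulfiteTruth:
    rates: dict
    n_reads: int
    read_length: int
    error_rate: float
    conversion_failure: float


def make_amplicon(seed: int, length: int = 240, n_cpgs: int = 8,
                  name: str = "amplicon") -> AmpliconRef:
    """A random amplicon whose only CpG dinucleotides are planted at
    roughly even spacing (>= 10 bp apart, away from the ends)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seq = list(rng.choice(_BASES, size=length))
    for i in range(length - 1):  # strip accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    positions = np.linspace(15, length - 15, n_cpgs).astype(int)
    for p in positions:  # plant CG with a 1-based C at p
        seq[p - 1] = "C"
        seq[p] = "G"
        if p >= 2 and seq[p - 2] == "C":
            seq[p - 2] = "A"
        if p + 1 < length and seq[p + 1] == "G":
            seq[p + 1] = "T"
    return AmpliconRef.from_sequence(name, "".join(seq))


def simulate_bisulfite_reads(
    amplicon: AmpliconRef,
    rates: dict,
    coverage: int = 500,
    read_length: Optional[int] = None,
    error_rate: float = 0.0,
    conversion_failure: float = 0.0,
    seed: int = 0,
):
    """Simulate directional bisulfite reads from one amplicon.

    ``rates`` maps 1-based CpG cytosine positions to per-molecule
    methylation probabilities; ``coverage`` is the expected per-base depth
    (with full-length reads, exactly the read count).  Returns
    ([(read_id, sequence), ...], BisulfiteTruth).
    """
    L = len(amplicon.seq)
    if read_length is None:
        read_length = L
    if read_length > L:
        raise SimConfigError("read_length exceeds amplicon length")
    bad = set(rates) - set(amplicon.cpg_positions)
    if bad:
        raise SimConfigError(f"rates keyed by non-CpG positions: {sorted(bad)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    n_reads = max(1, int(round(coverage * L / read_length)))
    seq = amplicon.seq
    cpgs = amplicon.cpg_positions
    cpg_c = set(cpgs)
    cpg_g = {p + 1 for p in cpgs}
    reads = []
    for i in range(n_reads):
        strand = STRAND_OT if rng.random() < 0.5 else STRAND_OB
        off = int(rng.integers(0, L - read_length + 1))
        meth = {p for p in cpgs if rng.random() < rates.get(p, 0.0)}
        out = []
        for j in range(off, off + read_length):
            pos = j + 1
            b = seq[j]
            if strand == STRAND_OT and b == "C":
                protect = (pos in meth) if pos in cpg_c else \
                    (rng.random() < conversion_failure)
                out.append("C" if protect else "T")
            elif strand == STRAND_OB and b == "G":
                if pos in cpg_g:
                    protect = (pos - 1) in meth
                else:
                    protect = rng.random() < conversion_failure
                out.append("G" if protect else "A")
            else:
                out.append(b)
        if error_rate > 0:
            for j in range(read_length):
                if rng.random() < error_rate:
                    out[j] = str(rng.choice(_BASES[_BASES != out[j]]))
        reads.append((f"read{i:05d}_{strand}", "".join(out)))
    truth = BisulfiteTruth(
        rates=dict(rates),
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        conversion_failure=conversion_failure,
    )
    return reads, truth
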