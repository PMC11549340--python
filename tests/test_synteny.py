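from itertools import permutations

import pytest

from lncsynt.annotations_io import GeneRecord, OrthologMap
from lncsynt.neighborhood import NeighborContext, Neighbor, extract_neighbors
from lncsynt.synteny import (
    Anchor,
    STATUS_COLLINEAR,
    STATUS_NOT_CONSERVED,
    STATUS_SYNTENIC,
    STATUS_UNMAPPABLE,
    call_synteny,
    resolve_anchors,
)


def _context_with_n_neighbors(n):
    """n protein-coding neighbors straddling a central lncRNA: half
    upstream, half downstream, in query order n0 < n1 < ... < n(n-1)."""
    half = n // 2
    neighbors = []
    for i in range(n):
        if i < half:
            side, dist = "upstream", (half - i) * 1000
        else:
            side, dist = "downstream", (i - half + 1) * 1000
        neighbors.append(Neighbor(f"n{i}", dist, side))
    return NeighborContext(
        lncrna_id="L", chrom="q1", lncrna_start=50_000, lncrna_end=50_500,
        neighbors=tuple(sorted(neighbors, key=lambda x: x.distance)),
    )


def _anchors_for(positions, chroms=None):
    """Anchor i carries query neighbor n_i to target midpoint positions[i]."""
    out = []
    for i, p in enumerate(positions):
        chrom = chroms[i] if chroms else "t1"
        out.append(Anchor(f"n{i}", f"T{i}", chrom, p * 100, p * 100 + 10))
    return out


def brute_force_status(positions):
    inc = all(a < b for a, b in zip(positions, positions[1:]))
    dec = all(a > b for a, b in zip(positions, positions[1:]))
    return STATUS_COLLINEAR if (inc or dec) else STATUS_SYNTENIC


class TestResolveAnchors:
    def test_identity_genome_anchors_every_neighbor(self):
        genes = [
            GeneRecord("A", "chr1", 100, 200, "+", "protein_coding"),
            GeneRecord("B", "chr1", 300, 400, "+", "protein_coding"),
            GeneRecord("L", "chr1", 450, 600, "+", "lncRNA"),
            GeneRecord("C", "chr1", 1000, 1100, "+", "protein_coding"),
        ]
        ctx = extract_neighbors(genes, "L", k=5)
        omap = OrthologMap((g.gene_id, "t" + g.gene_id) for g in genes)
        target = [
            GeneRecord("t" + g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
            for g in genes
        ]
        anchors = resolve_anchors(ctx, omap, target)
        assert {a.query_gene_id for a in anchors} == {"A", "B", "C"}
        assert all(a.target_chrom == "chr1" for a in anchors)

    def test_majority_chromosome_consensus_drops_minority_paralog(self):
        ctx = _context_with_n_neighbors(3)
        omap = OrthologMap([("n0", "X"), ("n0", "Y"), ("n1", "P"), ("n2", "Q")])
        target = [
            GeneRecord("X", "chr5", 100, 200, "+", "protein_coding"),
            GeneRecord("Y", "chr9", 100, 200, "+", "protein_coding"),
            GeneRecord("P", "chr5", 300, 400, "+", "protein_coding"),
            GeneRecord("Q", "chr5", 500, 600, "+", "protein_coding"),
        ]
        anchors = resolve_anchors(ctx, omap, target)
        assert {a.target_gene_id for a in anchors} == {"X", "P", "Q"}

    def test_empty_ortholog_map_gives_no_anchors(self):
        ctx = _context_with_n_neighbors(4)
        assert resolve_anchors(ctx, OrthologMap(), []) == []

    def test_missing_target_record_skipped_not_fatal(self):
        ctx = _context_with_n_neighbors(2)
        omap = OrthologMap([("n0", "X"), ("n1", "ghost")])
        target = [GeneRecord("X", "t1", 0, 10, "+", "protein_coding")]
        anchors = resolve_anchors(ctx, omap, target)
        assert [a.target_gene_id for a in anchors] == ["X"]


class TestCallSynteny:
    @pytest.mark.parametrize("n", range(2, 8))
    def test_exhaustive_permutation_oracle(self, n):
        """Every ordering of n distinct target positions must classify
        exactly as the brute-force strict-monotonicity check says."""
        ctx = _context_with_n_neighbors(n)
        base = list(range(10, 10 * (n + 1), 10))
        for perm in permutations(base):
            call = call_synteny(_anchors_for(perm), ctx)
            assert call.status == brute_force_status(perm)
            if call.status == STATUS_COLLINEAR:
                expected = "+" if perm[0] < perm[1] else "-"
                assert call.orientation == expected

    def test_exactly_two_of_six_orderings_of_three_are_collinear(self):
        ctx = _context_with_n_neighbors(3)
        n_coll = sum(
            call_synteny(_anchors_for(p), ctx).status == STATUS_COLLINEAR
            for p in permutations((10, 20, 30))
        )
        assert n_coll == 2

    def test_mirror_symmetry_flips_orientation(self):
        ctx = _context_with_n_neighbors(4)
        for perm in permutations((10, 20, 30, 40)):
            fwd = call_synteny(_anchors_for(perm), ctx)
            mirrored = [1000 - p for p in perm]
            rev = call_synteny(_anchors_for(mirrored), ctx)
            assert fwd.status == rev.status
            if fwd.status == STATUS_COLLINEAR:
                assert {fwd.orientation, rev.orientation} == {"+", "-"}

    def test_scattered_anchors_not_conserved(self):
        ctx = _context_with_n_neighbors(2)
        anchors = _anchors_for([10, 20], chroms=["t1", "t2"])
        assert call_synteny(anchors, ctx, min_anchors=2).status == STATUS_NOT_CONSERVED

    def test_fewer_than_quorum_is_unmappable(self):
        ctx = _context_with_n_neighbors(2)
        assert call_synteny(_anchors_for([10])[:1], ctx).status == STATUS_UNMAPPABLE
        assert call_synteny([], ctx).status == STATUS_UNMAPPABLE

    def test_max_span_rejects_megabase_scatter(self):
        ctx = _context_with_n_neighbors(3)
        anchors = _anchors_for([10, 20, 30_000])
        assert call_synteny(anchors, ctx).status == STATUS_COLLINEAR
        assert call_synteny(anchors, ctx, max_span=100_000).status == STATUS_NOT_CONSERVED

    def test_adding_order_violating_anchor_degrades_monotonically(self):
        """collinear can degrade to syntenic, never the reverse."""
        ctx = _context_with_n_neighbors(4)
        collinear_3 = _anchors_for([10, 20, 30])[:3]
        assert call_synteny(collinear_3, ctx).status == STATUS_COLLINEAR
        spoiled = collinear_3 + [Anchor("n3", "T3", "t1", 2500, 2510)]
        assert call_synteny(spoiled, ctx).status == STATUS_SYNTENIC
        # and no extension of an order-violating triple is ever collinear
        broken = _anchors_for([10, 30, 20])
        for extra_mid in (500, 2500, 4500):
            extended = broken + [Anchor("n3", "T3", "t1", extra_mid, extra_mid + 10)]
            assert call_synteny(extended, ctx).status == STATUS_SYNTENIC

    def test_inferred_interval_is_flanking_gap_on_identity_genome(self):
        genes = [
            GeneRecord("A", "chr1", 100, 200, "+", "protein_coding"),
            GeneRecord("B", "chr1", 300, 400, "+", "protein_coding"),
            GeneRecord("L", "chr1", 450, 600, "+", "lncRNA"),
            GeneRecord("C", "chr1", 1000, 1100, "+", "protein_coding"),
        ]
        ctx = extract_neighbors(genes, "L", k=5)
        omap = OrthologMap((g.gene_id, "t" + g.gene_id) for g in genes)
        target = [
            GeneRecord("t" + g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
            for g in genes
        ]
        call = call_synteny(resolve_anchors(ctx, omap, target), ctx)
        assert call.status == STATUS_COLLINEAR
        assert call.orientation == "+"
        # gap between flanking anchors B (ends 400) and C (starts 1000)
        assert call.inferred_interval == (400, 1000)
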