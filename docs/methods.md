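# Methods

## Data model and coordinates

All intervals are 0-based half-open internally; GFF3/GTF files (1-based
inclusive) are converted at the I/O boundary, BED12 is taken as-is, and the
GFF3 writer emits a canonical ordering (genes by chromosome, start, id) so
read → write round-trips are byte-stable on files the writer produced.
Biotypes are folded into three classes — `protein_coding`, `lncRNA`,
`other` — via the `gene_biotype`/`biotype`/`gene_type` attributes or a
caller-supplied mapping; `other` genes are carried through I/O but ignored
by the discovery stages. Chromosome names are compared as exact strings.
Transcript coordinates, in contrast, are 1-based and 5′→3′ along the
strand, because that is how lesions are described in molecular genetics
("a 12-bp deletion at position 594").

## Neighborhood extraction

The neighborhood of a lncRNA is its k nearest protein-coding genes on the
same chromosome (default k = 5 total; a per-side mode is available),
ranked by interval-gap distance
`max(0, max(startA, startB) − min(endA, endB))`. Strand is ignored: an
antisense gene overlapping the lncRNA is a neighbor with distance 0. Ties
break by smaller gene start, then id, making the result deterministic and
permutation-invariant. One corner case: two half-open intervals that abut
share no base yet have gap 0; we classify gap 0 as `overlapping` so that
distance 0 and side `overlapping` remain synonymous.

## Synteny and collinearity

Each neighbor with an ortholog contributes an anchor in the target genome.
Many-to-many orthologs are resolved by majority-chromosome consensus: the
chromosome carrying most candidate anchors wins (lexicographically smallest
name on a tie), a multi-ortholog neighbor keeps its ortholog on that
chromosome only if unique, and is otherwise dropped. Anchor position is the
ortholog's midpoint, robust to length differences.

With fewer than `min_anchors` (default 2) anchors the locus is
`unmappable`; with anchors present but no chromosome reaching the quorum,
`not_conserved`. Otherwise the anchors of the majority chromosome are
ordered by the query-genome order of their source neighbors and the call is
`collinear` iff the midpoint sequence is strictly monotonic — increasing
means orientation `+`, decreasing a whole-block inversion (`-`) — else
`syntenic`. With exactly 2 anchors, monotonicity holds vacuously; the
anchor count is reported so consumers can demand ≥ 3. Partial-order
(longest-increasing-subsequence) collinearity is deliberately out of scope.
The inferred orthologous interval is the target gap between the two anchors
flanking the lncRNA in query order, the overlapping anchor's own span when
the lncRNA lies inside a neighbor, and the whole anchor span when the
lncRNA is not flanked on both sides. An optional `max_span` rejects
megabase-scattered "synteny".

## The candidate funnel

Stages run in a fixed order: S1 conservation (status in
{collinear, syntenic}), S2 trait overlap (≥ 2 of the k neighbors in the
consolidated trait set; the distinct trait genes among all S1 survivors'
neighbors are reported alongside), S3 multiexonic (gene-level maximum
transcript exon count ≥ 2), S4 exactly one predicted ortholog transcript
(an exact-count test against a user-supplied table; `None` disables it),
S5 ranking by Mendelian-disease neighbor count with trait-count and then
id as tie-breaks. Since S2–S4 are pure intersections, the final set is
order-independent but the per-stage counts are not; the report records the
order used. Survivor lists are kept sorted so reports are invariant under
input permutation.

Two published descriptions of the single-neighbor rule conflict (prioritize
vs exclude single-neighbor loci); this implementation excludes loci with
fewer than `min_trait_neighbors` = 2 trait neighbors, the reading consistent
with the printed survivor counts. Exon counting is per gene (maximum over
transcripts), since a per-transcript reading is not determinable from the
published counts. The disease set is an input, not a constant, because no
specific catalog snapshot is reproducible.

## Transcript-coordinate bookkeeping

`annotate_deletion` projects a genomic deletion through the exon chain and
counts only exonic bases, reporting the first and last deleted transcript
base. Because an inclusive-end and an open-end rendering of the same lesion
differ by one (594–605 vs 594–606 for a 12-bp deletion starting at 594),
both are emitted rather than silently reinterpreting either convention.

## Bisulfite methylation calling

Reads are placed on the amplicon by exhaustively scoring every offset on
both bisulfite strands with bisulfite-aware matching (reference C vs read T
is not a mismatch on the original-top strand, reference G vs read A not on
the original-bottom strand); the fewest-mismatch placement wins, ties going
to the lowest offset and OT before OB. Reads whose best placement exceeds
`max_mismatch_rate` (default 0.1) are discarded. A CpG call reads the C
itself on OT and the paired G (position +1) on OB; anything other than C/T
(resp. G/A) is `ambiguous` and excluded from percentages, never imputed.
Conversion efficiency is the converted fraction over covered non-CpG
cytosines, where true methylation is assumed absent. Alignment is ungapped
by design — a targeted amplicon needs no indel model — and PBAT-style
complementary strands are not modeled (directional library assumed); both
are documented limitations, not switches.

## Assay quantifications

ΔΔCt uses replicate-mean Cts before exponentiation (standard Livak
practice), with actb as the default reference. Percent input applies the
log2(1/fraction) dilution correction; the input fraction is a required
argument since it is protocol-specific. Segregation testing is a Pearson
chi-square against an arbitrary ratio (default 1:2:1), delegated to
scipy.stats.chisquare with df = categories − 1. `fraction_percent` uses
round-half-to-even at the stated digits.

## Synthetic data generator

The generator emulates the input structure of a two-genome lncRNA synteny
study at desk scale. Defaults ("paper_shaped"): 10 chromosomes × 120 genes,
28% lncRNA, geometric-like gene lengths (mean 2 kb) and gaps (mean 1 kb),
lncRNA exon counts drawn from {1: 0.40, 2: 0.35, 3: 0.25}, ortholog
retention 0.90, per-block inversion rate 0.05 (geometric block length,
mean ≈ 5), per-gene translocation rate 0.02, paralog rate 0.03, three trait
sets of 250/110/30 protein-coding genes (partially overlapping), a 10%
Mendelian-disease set, 10 planted candidates and 3 decoys per criterion.
The genome size and set sizes are roughly an order of magnitude below a
vertebrate annotation so that hundreds of randomized replicates run in
seconds; rates were chosen once as plausible for the diverged-vertebrate
comparison the pipeline addresses.

The target genome copies query gene order, then deletes unprotected
orthologs, inverts whole blocks (skipping blocks that would split a
protected neighborhood — containing one entirely is allowed and flips its
orientation), translocates single genes, and adds paralog copies on random
chromosomes. Planted candidates have shielded neighborhoods and features
forced to satisfy every funnel criterion; each decoy violates exactly one
named criterion (anchors scattered one-per-chromosome for conservation
decoys; exactly one trait neighbor, with the rest blacklisted from trait
fill; a single-exon transcript; an ortholog-transcript count of 2).
Background lncRNAs receive ortholog-transcript counts in {0, 2, 3},
mimicking catalogs in which a unique predicted ortholog transcript is the
exception; this also makes planted recovery exact by construction, which
is the point of the truth table — recovery tests validate stage logic and
stage attribution, not the field performance of the funnel on real
annotations. Real data differ in ways the generator does not model:
sequence-level evolution, gene-density heterogeneity, assembly errors,
many-to-many ortholog ambiguity beyond simple paralog copies, and
biologically correlated trait/disease annotation. Passing recovery tests
therefore demonstrates correctness of the procedure, not expected yield on
a real genome pair.

Bisulfite read simulation draws, per molecule, a methylation state for
every CpG from its per-CpG rate, leaves unmethylated cytosines unconverted
with probability `conversion_failure`, applies uniform substitution errors,
and emits directional OT/OB reads at uniform offsets; `coverage` is the
expected per-base depth (the read count, when reads span the amplicon).
Amplicons for testing are constructed with only planted CpGs so per-CpG
truths are unambiguous.

All randomness flows from one integer seed fanned out to per-component
streams via numpy `SeedSequence.spawn` (layout, features, sets,
rearrangement, reads), so outputs are byte-identical across processes for
a given seed.

## Numerical and testing choices

Randomized oracle comparisons (neighborhood brute force, funnel
set-comprehension oracle, exhaustive permutation checks up to 7 anchors,
bisulfite all-offsets scorer) use small instances — 4 chromosomes × 30
genes, 120-mer amplicons — sized so the full suite runs in seconds while
still exercising every code path; the default scenario used for recovery
checks is the ~1200-gene configuration above. Methylation-recovery checks
use depth 1000 with 8 CpGs per amplicon; at that depth the binomial
standard error at 80% methylation is ≈ 1.3 points, so the 2-point recovery
check is a ~1.6σ bound per CpG and is verified at the suite's fixed seed.

## Known limitations

- Collinearity is all-or-nothing per neighborhood; no chaining or
  LIS-style partial synteny.
- The ortholog-transcript count path depends on a user-supplied table; the
  fallback of counting target transcripts in the inferred interval is
  supported at the API level but not exercised by the default scenario.
- The bisulfite caller is amplicon-scale only (exhaustive scan is quadratic
  in sequence length).
- The generator's trait sets are unstructured id samples; no ontology or
  expression realism.
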