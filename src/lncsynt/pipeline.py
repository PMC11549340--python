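"""End-to-end discovery run: neighborhoods -> synteny -> funnel.

Thin glue shared by the command-line interface and scripted analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotations_io import BIOTYPE_LNCRNA, GeneRecord, GeneSet, OrthologMap, TranscriptModel
from .funnel import FunnelConfig, consolidate_trait_sets, run_funnel
from .neighborhood import extract_neighbors
from .synteny import call_synteny, resolve_anchors


@dataclass
class DiscoveryResult:
    contexts: list
    calls: list
    trait: GeneSet
    report: object
    candidates: list


def run_discovery(
    query_genes: Sequence[GeneRecord],
    query_transcripts: Sequence[TranscriptModel],
    target_genes: Sequence[GeneRecord],
    orthologs: OrthologMap,
    trait_sets: Sequence[GeneSet],
    disease: GeneSet,
    ortholog_tx_counts: Mapping[str, int],
    config: FunnelConfig = None,
    min_anchors: int = 2,
    max_span: Optional[int] = None,
) -> DiscoveryResult:
    """Run the full candidate-discovery funnel over one genome pair."""
    config = config or FunnelConfig()
    lnc_ids = sorted(
        g.gene_id for g in query_genes if g.biotype == BIOTYPE_LNCRNA
    )
    contexts, calls = [], []
    for lid in lnc_ids:
        ctx = extract_neighbors(query_genes, lid, k=config.k)
        anchors = resolve_anchors(ctx, orthologs, target_genes)
        contexts.append(ctx)
        calls.append(call_synteny(anchors, ctx, min_anchors=min_anchors,
                                  max_span=max_span))
    trait = consolidate_trait_sets(list(trait_sets))
    report, candidates = run_funnel(
        contexts, calls, query_transcripts, trait, disease,
        ortholog_tx_counts, config,
    )
    return DiscoveryResult(contexts=contexts, calls=calls, trait=trait,
                           report=report, candidates=candidates)


def discover_simulated(pair, config: FunnelConfig = None, **kwargs) -> DiscoveryResult:
    """Convenience wrapper running the funnel on a SimulatedPair."""
    return run_discovery(
        pair.query_genes,
        pair.query_transcripts,
        pair.target_genes,
        pair.orthologs,
        pair.trait_sets,
        pair.disease_set,
        pair.ortholog_tx_counts,
        config=config,
        **kwargs,
    )
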