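"""Independent brute-force reference implementations used only by tests."""


def brute_force_funnel(contexts, calls, transcripts, trait, disease,
                       tx_counts, config):
    """Direct set-comprehension funnel, independent of funnel.run_funnel.

    Returns (stage_survivor_lists, neighbor_overlap_count, ranked_candidates).
    """
    ids = sorted(c.lncrna_id for c in contexts)
    status = {c.lncrna_id: c.status for c in calls}
    nb = {c.lncrna_id: [n.gene_id for n in c.neighbors] for c in contexts}
    max_ex = {}
    for t in transcripts:
        max_ex[t.gene_id] = max(max_ex.get(t.gene_id, 0), len(t.exons))

    def n_trait(i):
        return len([g for g in nb[i] if g in trait.ids])

    def n_disease(i):
        return len([g for g in nb[i] if g in disease.ids])

    s1 = [i for i in ids if status[i] in config.allowed_statuses]
    overlap = len({g for i in s1 for g in nb[i] if g in trait.ids})
    s2 = [i for i in s1 if n_trait(i) >= config.min_trait_neighbors]
    s3 = [i for i in s2 if max_ex.get(i, 0) >= config.min_exons]
    if config.required_ortholog_transcripts is None:
        s4 = list(s3)
    else:
        s4 = [i for i in s3
              if tx_counts.get(i, 0) == config.required_ortholog_transcripts]
    ranked = sorted(s4, key=lambda i: (-n_disease(i), -n_trait(i), i))
    if config.top_n is not None:
        ranked = ranked[: config.top_n]
    return [ids, s1, s2, s3, s4, sorted(ranked)], overlap, ranked


def assert_funnel_matches_oracle(result, transcripts, disease, tx_counts, config):
    """Compare a DiscoveryResult against the brute-force funnel."""
    stages, overlap, ranked = brute_force_funnel(
        result.contexts, result.calls, transcripts, result.trait, disease,
        tx_counts, config,
    )
    report = result.report
    assert report.neighbor_overlap_count == overlap
    for stage, expected_survivors, expected_in in zip(
        report.stages, stages[1:], stages[:-1]
    ):
        assert stage.n_in == len(expected_in)
        assert stage.n_out == len(expected_survivors)
        assert sorted(stage.surviving_ids) == sorted(expected_survivors)
        assert stage.n_out <= stage.n_in
    assert [c.lncrna_id for c in result.candidates] == ranked
    assert [c.rank for c in result.candidates] == list(range(1, len(ranked) + 1))
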