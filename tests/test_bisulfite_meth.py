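import numpy as np
import pytest

from lncsynt.bisulfite_meth import (
    AlphabetError,
    AmpliconRef,
    assign_read,
    bisulfite_convert,
    call_profile,
)
from lncsynt.synthetic_data import make_amplicon, simulate_bisulfite_reads

from conftest import SEED


class TestBisulfiteConvert:
    def test_unmethylated_c_becomes_t_on_top_strand(self):
        assert bisulfite_convert("ACGT", "OT", set()) == "ATGT"

    def test_methylated_position_protected(self):
        assert bisulfite_convert("ACGT", "OT", {2}) == "ACGT"

    def test_bottom_strand_converts_g(self):
        assert bisulfite_convert("ACGT", "OB", set()) == "ACAT"
        assert bisulfite_convert("ACGT", "OB", {3}) == "ACGT"

    def test_conversion_is_idempotent_on_random_sequences(self):
        rng = np.random.default_rng(SEED)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            for strand in ("OT", "OB"):
                once = bisulfite_convert(seq, strand, set())
                assert bisulfite_convert(once, strand, set()) == once

    def test_non_dna_rejected(self):
        with pytest.raises(AlphabetError):
            bisulfite_convert("ACGN", "OT", set())


class TestAmpliconRef:
    def test_cpg_positions_enumerated(self):
        ref = AmpliconRef.from_sequence("a", "AACGTTTTCGTTTTTTTTTTTT")
        assert ref.cpg_positions == (3, 9)

    def test_generated_amplicon_has_only_planted_cpgs(self):
        ref = make_amplicon(SEED, length=240, n_cpgs=8)
        assert len(ref.cpg_positions) == 8
        # recomputation from sequence agrees
        again = AmpliconRef.from_sequence("x", ref.seq)
        assert again.cpg_positions == ref.cpg_positions


class TestAssignRead:
    def setup_method(self):
        self.ref = make_amplicon(SEED, length=120, n_cpgs=4)

    def test_fully_methylated_read_all_calls_methylated(self):
        read = bisulfite_convert(self.ref.seq, "OT", set(self.ref.cpg_positions))
        a = assign_read(read, self.ref)
        assert (a.offset, a.strand, a.mismatches) == (0, "OT", 0)
        assert [c for _, c in a.calls] == ["methylated"] * 4

    def test_unmethylated_read_is_not_mismatched(self):
        read = bisulfite_convert(self.ref.seq, "OT", set())
        a = assign_read(read, self.ref)
        assert a.mismatches == 0
        assert [c for _, c in a.calls] == ["unmethylated"] * 4

    def test_bottom_strand_read_assigned_ob(self):
        read = bisulfite_convert(self.ref.seq, "OB", set())
        a = assign_read(read, self.ref)
        assert a.strand == "OB"
        assert [c for _, c in a.calls] == ["unmethylated"] * 4

    def test_hopeless_read_returns_none(self):
        assert assign_read("A" * 60, self.ref, max_mismatch_rate=0.05) is None

    def test_agrees_with_brute_force_scorer_on_noisy_reads(self):
        rng = np.random.default_rng(SEED)
        rates = {p: 0.5 for p in self.ref.cpg_positions}
        reads, _ = simulate_bisulfite_reads(
            self.ref, rates, coverage=120, read_length=60,
            error_rate=0.02, seed=SEED,
        )

        def brute(read):
            best = None
            for rank, strand in enumerate(("OT", "OB")):
                ok = {"C": "T"} if strand == "OT" else {"G": "A"}
                for off in range(len(self.ref.seq) - len(read) + 1):
                    window = self.ref.seq[off : off + len(read)]
                    mm = sum(
                        1 for r, c in zip(read, window)
                        if r != c and ok.get(c) != r
                    )
                    key = (mm, off, rank)
                    if best is None or key < best:
                        best = key
            return best

        n_checked = 0
        for rid, seq in reads[:200]:
            a = assign_read(seq, self.ref, max_mismatch_rate=0.1, read_id=rid)
            mm, off, rank = brute(seq)
            if mm > int(0.1 * len(seq)):
                assert a is None
                continue
            assert (a.mismatches, a.offset, a.strand) == (mm, off, ("OT", "OB")[rank])
            n_checked += 1
        assert n_checked > 100


class TestCallProfile:
    def setup_method(self):
        self.ref = make_amplicon(SEED, length=120, n_cpgs=4)

    def test_saturated_methylation_reads_give_100_percent(self):
        read = bisulfite_convert(self.ref.seq, "OT", set(self.ref.cpg_positions))
        prof = call_profile([assign_read(read, self.ref)] * 10, self.ref)
        assert all(r.percent == 100.0 for r in prof.rows)
        assert all(r.n_methylated == 10 for r in prof.rows)

    def test_no_reads_gives_all_na(self):
        prof = call_profile([], self.ref)
        assert all(r.percent is None for r in prof.rows)
        assert prof.conversion_efficiency is None

    def test_call_conservation_between_reads_and_profile(self):
        rates = {p: 0.5 for p in self.ref.cpg_positions}
        reads, _ = simulate_bisulfite_reads(
            self.ref, rates, coverage=50, read_length=60, error_rate=0.05,
            seed=SEED,
        )
        assignments = [a for a in (assign_read(s, self.ref) for _, s in reads) if a]
        prof = call_profile(assignments, self.ref)
        per_read = sum(len(a.calls) for a in assignments)
        per_cpg = sum(
            r.n_methylated + r.n_unmethylated + r.n_ambiguous for r in prof.rows
        )
        assert per_read == per_cpg

    def test_binomial_recovery_at_depth_500(self):
        rates = {p: 0.8 for p in self.ref.cpg_positions}
        reads, _ = simulate_bisulfite_reads(self.ref, rates, coverage=500, seed=SEED)
        assignments = [assign_read(s, self.ref) for _, s in reads]
        prof = call_profile(assignments, self.ref)
        tol = 3 * 100 * np.sqrt(0.8 * 0.2 / 500)  # ~5.4 points
        for row in prof.rows:
            assert abs(row.percent - 80.0) < tol

    def test_conversion_efficiency_tracks_failure_rate(self):
        rates = {p: 1.0 for p in self.ref.cpg_positions}
        effs = []
        for failure in (0.10, 0.01, 0.0):
            reads, _ = simulate_bisulfite_reads(
                self.ref, rates, coverage=200, conversion_failure=failure,
                seed=SEED,
            )
            prof = call_profile(
                [assign_read(s, self.ref) for _, s in reads], self.ref
            )
            effs.append(prof.conversion_efficiency)
        assert effs[0] < effs[1] < effs[2] == 1.0
        assert abs(effs[0] - 0.9) < 0.02
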