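"""Alignment to the reference backbone, coverage, quality-aware pileups."""

import numpy as np
import pytest

from ampdiv.mapping_pileup import (
    Scoring,
    align_read,
    build_pileup,
    coverage_stats,
)
from ampdiv.preprocess import Read
from ampdiv.reference_model import revcomp
from ampdiv.synthetic_reads import ErrorModel454, build_haplotype_pool, simulate_reads


def _read(bases, quals=None, direction=None):
    if quals is None:
        quals = np.full(len(bases), 40)
    return Read(read_id="r", bases=bases, quals=quals, direction=direction)


def _gotoh_oracle(read, ref, sc: Scoring):
    """Independent full-matrix affine-gap DP (score only).

    Same model: read globally aligned, free reference end-gaps, gap of
    length k costs open + k*extend.
    """
    m, n = len(read), len(ref)
    NEG = float("-inf")
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    V = [[NEG] * (n + 1) for _ in range(m + 1)]
    Z = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(1, m + 1):
        V[i][0] = sc.gap_open + i * sc.gap_extend
        H[i][0] = V[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
            Z[i][j] = max(H[i][j - 1] + sc.gap_open + sc.gap_extend,
                          Z[i][j - 1] + sc.gap_extend)
            V[i][j] = max(H[i - 1][j] + sc.gap_open + sc.gap_extend,
                          V[i - 1][j] + sc.gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + s, Z[i][j], V[i][j])
    return max(H[m])


class TestAlignRead:
    def test_identical_prefix_all_match(self, mytb):
        read = _read(mytb.sequence[:80])
        aln = align_read(read, mytb)
        assert aln.op_string == "M" * 80
        assert (aln.ref_start, aln.ref_end) == (1, 80)
        assert aln.identity == 1.0

    def test_internal_segment_free_end_gaps(self, mytb):
        read = _read(mytb.sequence[50:150])
        aln = align_read(read, mytb)
        assert (aln.ref_start, aln.ref_end) == (51, 150)
        assert aln.identity == 1.0

    def test_single_substitution_identity(self, mytb):
        seg = mytb.sequence[:100]
        mutated = seg[:40] + ("A" if seg[40] != "A" else "C") + seg[41:]
        aln = align_read(_read(mutated), mytb)
        assert aln.identity == pytest.approx(99 / 100)
        assert aln.op_string.count("X") == 1
        assert aln.op_string[40] == "X"

    def test_reverse_read_same_span_and_ops(self, mytb):
        fwd = _read(mytb.sequence[20:140])
        rev = _read(revcomp(mytb.sequence[20:140]), direction="reverse")
        a, b = align_read(fwd, mytb), align_read(rev, mytb)
        assert (a.ref_start, a.ref_end, a.op_string) == \
            (b.ref_start, b.ref_end, b.op_string)
        assert b.strand == "-"

    def test_nonspecific_read_excluded(self, mytb):
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert align_read(_read(junk), mytb, min_identity=0.8) is None

    def test_deletion_and_insertion_ops_consume_correctly(self, mytb):
        seg = mytb.sequence[:90]
        with_del = seg[:30] + seg[33:]           # 3-base deletion
        aln = align_read(_read(with_del), mytb)
        assert aln.op_string.count("D") == 3
        assert aln.ref_end - aln.ref_start + 1 == \
            sum(1 for o in aln.op_string if o in "MXD")
        assert sum(1 for o in aln.op_string if o in "MXI") == len(with_del)

    def test_score_matches_independent_dp_oracle(self, mytb):
        """100 random error-injected reads score identically under an
        independent full-matrix DP."""
        rng = np.random.default_rng(17)
        sc = Scoring()
        ref = mytb.sequence[:120]
        for _ in range(100):
            start = int(rng.integers(0, 40))
            ln = int(rng.integers(30, 70))
            read = list(mytb.sequence[start:start + ln])
            for _e in range(int(rng.integers(0, 5))):
                k = int(rng.integers(0, len(read)))
                op = rng.integers(3)
                if op == 0:
                    read[k] = "ACGT"[rng.integers(4)]
                elif op == 1 and len(read) > 10:
                    del read[k]
                else:
                    read.insert(k, "ACGT"[rng.integers(4)])
            read = "".join(read)
            aln = align_read(_read(read), mytb, sc, min_identity=0.0)
            assert aln.score == pytest.approx(_gotoh_oracle(read, mytb.sequence, sc))


class TestCoverage:
    def test_closed_form(self, mytb):
        reads = [_read(mytb.sequence[i:i + 100]) for i in range(10)]
        alns = [align_read(r, mytb) for r in reads]
        cov = coverage_stats(alns, mytb)
        assert cov.average_coverage == pytest.approx(10 * 100 / mytb.length)

    def test_empty_alignments_zero(self, mytb):
        assert coverage_stats([], mytb).average_coverage == 0.0

    def test_simulation_matches_expectation(self, mytm, panel):
        """Coverage within 5% of n * mean_read_len / L for clean reads."""
        truth = build_haplotype_pool(mytm, 0, [], seed=1, sample_id="Pa")
        model = ErrorModel454(substitution_rate=0.0,
                              homopolymer_indel_rate=(0.0,) * 8,
                              junk_read_fraction=0.0)
        reads, _ = simulate_reads(truth, panel, 800, model, seed=2)
        from ampdiv.preprocess import demultiplex
        assigned = demultiplex(reads, panel).assigned
        alns = [align_read(r, mytm) for r in assigned]
        cov = coverage_stats([a for a in alns if a], mytm)
        mean_len = np.mean([len(r) for r in assigned])
        expected = 800 * mean_len / mytm.length
        assert abs(cov.average_coverage - expected) / expected < 0.05


class TestPileup:
    def test_quality_gates(self, mytb):
        """A base below q20, or with an 11-base window mean below 15, is
        excluded from quality-passing counts but kept in raw counts."""
        seg = mytb.sequence[:50]
        ok = _read(seg, np.full(50, 30))
        low_base = _read(seg, np.concatenate([np.full(10, 30), [19],
                                              np.full(39, 30)]))
        low_window = _read(seg, np.concatenate([np.full(10, 2), [30],
                                                np.full(39, 2)]))
        alns = [align_read(r, mytb) for r in (ok, low_base, low_window)]
        pile = build_pileup(alns, mytb, qual_min=20, neighborhood_min=15,
                            neighborhood_radius=5)
        col = pile[10]
        assert col.raw_counts[seg[10]] == 3
        assert col.allele_counts[seg[10]] == 1  # only the clean read passes

    def test_depth_conservation(self, mytb, panel):
        truth = build_haplotype_pool(mytb, 2, [0.2, 0.3], seed=5, sample_id="Pa")
        reads, _ = simulate_reads(truth, panel, 300,
                                  ErrorModel454.noiseless(), seed=6)
        from ampdiv.preprocess import demultiplex
        assigned = demultiplex(reads, panel).assigned
        alns = [align_read(r, mytb) for r in assigned]
        pile = build_pileup(alns, mytb)
        total_matched = sum(
            sum(1 for o in a.op_string if o in "MX") for a in alns)
        assert sum(c.depth for c in pile) == total_matched

    def test_error_free_pileup_reproduces_haplotype_fractions(self, mytb, panel):
        truth = build_haplotype_pool(mytb, 1, [0.25], seed=7, sample_id="Pa")
        reads, sidecar = simulate_reads(truth, panel, 400,
                                        ErrorModel454.noiseless(), seed=8)
        from ampdiv.preprocess import demultiplex
        assigned = demultiplex(reads, panel).assigned
        alns = [align_read(r, mytb) for r in assigned]
        pile = build_pileup(alns, mytb)
        snc = truth.true_sncs[0]
        col = pile[snc.position - 1]
        n_hap = (sidecar["haplotype_id"] == "hap1").sum()
        assert col.allele_counts[snc.alt_base] == n_hap
        assert col.depth == len(assigned)
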