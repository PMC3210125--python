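"""Genuine-SNC calling, codon merging, omega, summaries."""

import numpy as np
import pytest

from ampdiv.mapping_pileup import PileupColumn, align_read, build_pileup
from ampdiv.preprocess import Read, demultiplex
from ampdiv.snc_analysis import (
    call_sncs,
    merge_and_classify,
    omega_from_counts,
    pool_changes,
    pool_sncs,
    round_half_up,
    snc_maps,
    summarize,
)
from ampdiv.synthetic_reads import ErrorModel454, build_haplotype_pool, simulate_reads


def _column(amp, pos, counts, ref=None):
    ref = ref or amp.sequence[pos - 1]
    full = {b: counts.get(b, 0) for b in "ACGT"}
    return PileupColumn(
        amplicon_id=amp.amplicon_id, position=pos, ref_base=ref,
        depth=sum(full.values()), allele_counts=full, raw_counts=dict(full),
        deletions=0,
    )


class TestCallSncs:
    def test_depth_29_not_called(self, mytb):
        pos = mytb.cds_start
        ref = mytb.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        cols = [_column(mytb, pos, {ref: 26, alt: 3})]          # depth 29
        assert call_sncs(cols, mytb, min_depth=30, min_freq=0.03) == []
        cols = [_column(mytb, pos, {ref: 27, alt: 3})]          # depth 30
        assert len(call_sncs(cols, mytb)) == 1

    def test_three_percent_threshold_at_depth_1000(self, mytb):
        pos = mytb.cds_start
        ref = mytb.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        low = [_column(mytb, pos, {ref: 971, alt: 29})]
        assert call_sncs(low, mytb) == []
        ok = [_column(mytb, pos, {ref: 970, alt: 30})]
        called = call_sncs(ok, mytb)
        assert len(called) == 1 and called[0].frequency == pytest.approx(0.03)

    def test_multiallelic_column_one_snc_per_alt(self, mytb):
        pos = mytb.cds_start
        ref = mytb.sequence[pos - 1]
        alts = [b for b in "ACGT" if b != ref]
        cols = [_column(mytb, pos, {ref: 80, alts[0]: 10, alts[1]: 10})]
        called = call_sncs(cols, mytb)
        assert sorted(s.alt_base for s in called) == sorted(alts[:2])

    def test_monotonic_in_thresholds(self, mytb, panel):
        truth = build_haplotype_pool(mytb, 4, [0.04, 0.1, 0.2, 0.3], seed=1,
                                     sample_id="Pa")
        reads, _ = simulate_reads(truth, panel, 1200, ErrorModel454(), seed=2)
        from ampdiv.preprocess import length_filter, mott_trim
        kept, _ = length_filter([mott_trim(r) for r in
                                 demultiplex(reads, panel).assigned])
        alns = [a for a in (align_read(r, mytb) for r in kept) if a]
        pile = build_pileup(alns, mytb)
        n_default = len(call_sncs(pile, mytb, 30, 0.03))
        assert len(call_sncs(pile, mytb, 100, 0.03)) <= n_default
        assert len(call_sncs(pile, mytb, 30, 0.08)) <= n_default
        assert len(call_sncs(pile, mytb, 30, 0.5)) <= n_default

    def test_max_freq_flags_suspect_reference_columns(self, mytb):
        pos = mytb.cds_start
        ref = mytb.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        cols = [_column(mytb, pos, {alt: 100})]  # fixed difference
        called = call_sncs(cols, mytb, max_freq=0.98)
        assert len(called) == 1 and called[0].suspect_reference
        called_off = call_sncs(cols, mytb)       # flag off by default
        assert not called_off[0].suspect_reference

    def test_truth_recovery_on_clean_deep_data(self, mytb, panel):
        """5% truth allele on clean 500x data: exactly the true SNCs."""
        truth = build_haplotype_pool(mytb, 3, [0.05, 0.15, 0.4], seed=3,
                                     sample_id="Pa")
        reads, _ = simulate_reads(truth, panel, 500,
                                  ErrorModel454.noiseless(), seed=4)
        assigned = demultiplex(reads, panel).assigned
        alns = [align_read(r, mytb) for r in assigned]
        called = call_sncs(build_pileup(alns, mytb), mytb)
        assert {(s.amplicon_position, s.alt_base) for s in called} == \
            {(t.position, t.alt_base) for t in truth.true_sncs}


def _snc_at(amp, pos, alt, **kw):
    defaults = dict(
        amp_id=amp.amp_id, amplicon_id=amp.amplicon_id,
        position=amp.transcript_position(pos), amplicon_position=pos,
        ref_base=amp.sequence[pos - 1], alt_base=alt, alt_count=50, depth=500,
        frequency=0.1, region="mature", in_cds=True,
    )
    defaults.update(kw)
    from ampdiv.snc_analysis import SNC
    return SNC(**defaults)


class TestMergeClassify:
    def test_two_sncs_in_one_codon_merge(self, mytb):
        s, e = mytb.codon_span(mytb.cds_codon_start + 4)
        ref = mytb.sequence
        alt1 = "A" if ref[s - 1] != "A" else "G"
        alt2 = "C" if ref[s] != "C" else "G"
        merged = merge_and_classify(
            [_snc_at(mytb, s, alt1), _snc_at(mytb, s + 1, alt2)], mytb)
        assert len(merged) == 1
        ch = merged[0]
        assert ch.alt_codon[0] == alt1 and ch.alt_codon[1] == alt2
        assert ch.alt_codon[2] == ref[s + 1]
        assert len(ch.component_sncs) == 2

    def test_synonymous_and_nonsynonymous_classification(self, panel):
        # find a codon where we can construct GCT->GCC (Ala->Ala, silent)
        # and TGT->AGT (Cys->Ser) style changes on real panel codons
        amp = panel.amplicons["MytB"]
        for codon_idx in amp.covered_codon_indices():
            ref_codon = amp.ref_codon(codon_idx)
            s, _ = amp.codon_span(codon_idx)
            if ref_codon == "GCT":
                merged = merge_and_classify([_snc_at(amp, s + 2, "C")], amp)
                assert merged[0].synonymous and merged[0].alt_aa == "A"
            if ref_codon == "TGT":
                merged = merge_and_classify([_snc_at(amp, s, "A")], amp)
                assert not merged[0].synonymous
                assert (merged[0].ref_aa, merged[0].alt_aa) == ("C", "S")

    def test_flank_sncs_not_merged(self, mytb):
        flank_pos = mytb.cds_start - 2
        assert flank_pos >= 1
        snc = _snc_at(mytb, flank_pos, "A" if mytb.sequence[flank_pos - 1] != "A"
                      else "C", in_cds=False, region="flank")
        assert merge_and_classify([snc], mytb) == []


class TestSummarize:
    def test_omega_worked_examples(self):
        assert round_half_up(omega_from_counts(25, 10), 1) == 0.7
        assert omega_from_counts(15, 0) == 0.0
        assert omega_from_counts(11, 11) is None  # bracket case

    def test_summary_counts_and_display(self, mytb):
        changes = []
        for i, codon in enumerate(list(mytb.covered_codon_indices())[:5]):
            s, _ = mytb.codon_span(codon)
            ref = mytb.sequence[s - 1]
            alt = "A" if ref != "A" else "G"
            changes.extend(merge_and_classify([_snc_at(mytb, s, alt)], mytb))
        sncs = [c.component_sncs[0] for c in changes]
        summary = summarize(changes, sncs, "MytB", "Pa", covered_codons=96)
        assert summary.ns_count + summary.syn_count == summary.snc_cds == 5
        assert summary.frequency == pytest.approx(5 / 96)
        if summary.syn_count == 0:
            assert summary.omega is None
            assert summary.omega_display == f"[{summary.ns_count}]"
        else:
            assert summary.omega == summary.ns_count / summary.syn_count

    def test_covered_codons_must_be_positive(self):
        with pytest.raises(ValueError):
            summarize([], [], "MytB", "Pa", covered_codons=0)

    def test_rounding_half_up(self):
        assert round_half_up(0.2583, 2) == 0.26
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(0.67, 1) == 0.7


class TestPooling:
    def test_overlapping_amplicons_union_on_transcript_frame(self, panel):
        """The same transcript SNC seen by both overlapping amplicons of one
        AMP counts once after pooling."""
        a1, a2 = panel.amplicons["MytA-1"], panel.amplicons["MytA-2"]
        # transcript position covered by both amplicons, inside both cds
        lo = max(a1.transcript_position(a1.cds_start),
                 a2.transcript_position(a2.cds_start))
        hi = min(a1.transcript_position(a1.cds_end),
                 a2.transcript_position(a2.cds_end))
        tpos = (lo + hi) // 2
        p1 = tpos - a1.transcript_start + 1
        p2 = tpos - a2.transcript_start + 1
        assert a1.sequence[p1 - 1] == a2.sequence[p2 - 1]
        alt = "A" if a1.sequence[p1 - 1] != "A" else "C"
        s1, s2 = _snc_at(a1, p1, alt), _snc_at(a2, p2, alt)
        assert s1.key() == s2.key()
        pooled = pool_sncs([[s1], [s2]])
        assert len(pooled) == 1

    def test_snc_map_frame(self, mytb):
        s, _ = mytb.codon_span(mytb.cds_codon_start + 2)
        alt = "A" if mytb.sequence[s - 1] != "A" else "G"
        changes = merge_and_classify([_snc_at(mytb, s, alt)], mytb)
        frame = snc_maps({"Pa": changes}, "MytB", mytb.region_bounds)
        assert len(frame) == 1
        assert frame.iloc[0]["type"] in ("synonymous", "non_synonymous")
        assert frame.iloc[0]["region"] == "signal"
        assert snc_maps({}, "MytB").empty
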