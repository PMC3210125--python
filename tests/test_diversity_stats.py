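"""Read clustering, peptide enumeration, SNC set partitions, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest

from ampdiv.diversity_stats import (
    anova_tukey,
    cluster_reads,
    common_exclusive,
    enumerate_peptides,
    mean_sd_by_amp,
)
from ampdiv.preprocess import Read
from ampdiv.reference_model import revcomp, translate_cds
from ampdiv.synthetic_reads import ErrorModel454, build_haplotype_pool, simulate_reads


def _read(bases, direction=None):
    return Read(read_id="r", bases=bases, quals=np.full(len(bases), 40),
                direction=direction)


class TestClusterReads:
    def test_identical_reads_one_cluster(self, mytb):
        reads = [_read(mytb.sequence[:120])] * 5
        clusters = cluster_reads(reads, mytb, "Pa")
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_reference_identical_kind(self, mytb):
        ref_read = _read(mytb.sequence[10:150])
        seq = mytb.sequence[10:150]
        var_read = _read(seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:])
        clusters = cluster_reads([ref_read, var_read], mytb, "Pa")
        kinds = sorted(c.kind for c in clusters)
        assert kinds == ["reference_identical", "variant"]

    def test_reverse_reads_cluster_with_sense(self, mytb):
        seq = mytb.sequence[10:150]
        fwd = _read(seq)
        rev = _read(revcomp(seq), direction="reverse")
        clusters = cluster_reads([fwd, rev], mytb, "Pa")
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_size_conservation(self, mytb, panel):
        truth = build_haplotype_pool(mytb, 2, [0.2, 0.3], seed=1, sample_id="Pa")
        reads, _ = simulate_reads(truth, panel, 500, ErrorModel454(), seed=2)
        from ampdiv.preprocess import demultiplex
        assigned = demultiplex(reads, panel).assigned
        clusters = cluster_reads(assigned, mytb, "Pa")
        assert sum(c.size for c in clusters) == len(assigned)


class TestEnumeratePeptides:
    def test_silent_variants_collapse_to_one_peptide(self, mytb, panel):
        """Clusters differing only at silent third positions yield 1 peptide."""
        base = mytb.sequence
        # find a codon with a synonymous third-position alternative
        from ampdiv.reference_model import CODON_TABLE
        for codon_idx in mytb.covered_codon_indices():
            s, e = mytb.codon_span(codon_idx)
            ref_codon = mytb.ref_codon(codon_idx)
            for b in "ACGT":
                alt_codon = ref_codon[:2] + b
                if b != ref_codon[2] and CODON_TABLE[alt_codon] == CODON_TABLE[ref_codon]:
                    variant = base[: e - 1] + b + base[e:]
                    clusters = cluster_reads(
                        [_read(base)] * 3 + [_read(variant)] * 3, mytb, "Pa")
                    peptides = enumerate_peptides(clusters, mytb, min_cov=3)
                    assert len(peptides) == 1
                    assert peptides[0].total_support == 6
                    return
        pytest.fail("no synonymous third-position alternative found")

    def test_low_coverage_clusters_excluded(self, mytb):
        clusters = cluster_reads([_read(mytb.sequence)] * 2, mytb, "Pa")
        assert enumerate_peptides(clusters, mytb, min_cov=3) == []

    def test_cysteine_loss_flagged(self, mytb):
        cys_codon_idx = mytb.cysteine_positions[0]
        s, _ = mytb.codon_span(cys_codon_idx)
        assert mytb.ref_codon(cys_codon_idx) in ("TGT", "TGC")
        variant = mytb.sequence[: s - 1] + "A" + mytb.sequence[s:]  # TGT->AGT
        clusters = cluster_reads([_read(variant)] * 3, mytb, "Pa")
        peptides = enumerate_peptides(clusters, mytb, min_cov=3)
        assert len(peptides) == 1
        assert not peptides[0].cysteine_array_retained
        ok = enumerate_peptides(
            cluster_reads([_read(mytb.sequence)] * 3, mytb, "Pa"), mytb)
        assert ok[0].cysteine_array_retained

    def test_k_coding_haplotypes_give_k_peptides(self, mytb, panel):
        """Zero-error full-length reads from k peptide-distinct haplotypes
        (reference plus non-synonymous variants) yield exactly k peptides."""
        rng = np.random.default_rng(5)
        while True:
            truth = build_haplotype_pool(mytb, 2, [0.3, 0.3],
                                         seed=int(rng.integers(1 << 30)),
                                         sample_id="Pa")
            peps = {translate_cds(h[mytb.cds_start - 1:mytb.cds_end],
                                  mytb.cds_frame_offset)
                    for h, _ in truth.haplotypes}
            if len(peps) == 3:  # all three haplotypes peptide-distinct
                break
        reads, _ = simulate_reads(truth, panel, 120,
                                  ErrorModel454.noiseless(), seed=6)
        from ampdiv.preprocess import demultiplex
        assigned = demultiplex(reads, panel).assigned
        clusters = cluster_reads(assigned, mytb, "Pa")
        peptides = enumerate_peptides(clusters, mytb, min_cov=3)
        assert len(peptides) == 3
        assert peps == {p.peptide for p in peptides}

    def test_peptide_count_bounded_by_deep_clusters(self, mytb, panel):
        truth = build_haplotype_pool(mytb, 3, [0.1, 0.2, 0.3], seed=7,
                                     sample_id="Pa")
        reads, _ = simulate_reads(truth, panel, 400, ErrorModel454(), seed=8)
        from ampdiv.preprocess import demultiplex, length_filter, mott_trim
        kept, _ = length_filter([mott_trim(r) for r in
                                 demultiplex(reads, panel).assigned])
        clusters = cluster_reads(kept, mytb, "Pa")
        peptides = enumerate_peptides(clusters, mytb, min_cov=3)
        deep = [c for c in clusters if c.size >= 3]
        assert len(peptides) <= len(deep)


class TestCommonExclusive:
    def test_identical_sets(self):
        sets = {"Pa": {1, 2, 3}, "Vi": {1, 2, 3}}
        rep = common_exclusive(sets)
        assert rep.common == {1, 2, 3}
        assert all(not v for v in rep.exclusive.values())
        assert rep.percent_common == {"Pa": 100.0, "Vi": 100.0}

    def test_disjoint_sets(self):
        rep = common_exclusive({"Pa": {1}, "Vi": {2}})
        assert rep.common == set()
        assert rep.exclusive == {"Pa": {1}, "Vi": {2}}

    def test_three_way_partition_matches_construction(self):
        common = {("a", i, "A") for i in range(10)}
        pa_only = {("a", 100 + i, "C") for i in range(3)}
        vi_only = {("a", 200 + i, "C") for i in range(4)}
        pa_vi = {("a", 300 + i, "G") for i in range(2)}   # shared, not universal
        sets = {
            "Pa": common | pa_only | pa_vi,
            "Vi": common | vi_only | pa_vi,
            "Ve": common,
        }
        rep = common_exclusive(sets)
        assert rep.common == common
        assert rep.exclusive["Pa"] == pa_only
        assert rep.exclusive["Vi"] == vi_only
        assert rep.exclusive["Ve"] == set()
        assert rep.shared_partial == pa_vi
        # full partition of the union
        n = (len(rep.common) + sum(map(len, rep.exclusive.values()))
             + len(rep.shared_partial))
        assert n == len(rep.union)
        assert rep.percent_common["Pa"] == pytest.approx(100 * 10 / 15)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            common_exclusive({})


def _freq_table(spec, seed=0, n_samples=6):
    rng = np.random.default_rng(seed)
    rows = []
    for amp, (mean, sd) in spec.items():
        for i in range(n_samples):
            rows.append({"amp_id": amp, "sample_id": f"S{i}",
                         "frequency": mean + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_all_equal_single_group(self):
        table = _freq_table({"A": (0.2, 0.0), "B": (0.2, 0.0), "C": (0.2, 0.0)})
        g = anova_tukey(table)
        assert not g.rejected
        assert g.groups == [["A", "B", "C"]]

    def test_separated_groups_discriminated(self):
        """Two AMP groups separated by ~10 within-group SDs split into two
        Tukey subsets."""
        table = _freq_table({"A": (0.10, 0.01), "B": (0.10, 0.01),
                             "C": (0.30, 0.01), "D": (0.30, 0.01)}, seed=1)
        g = anova_tukey(table)
        assert g.rejected and g.anova_p < 0.001
        assert g.groups is not None and len(g.groups) == 2
        assert sorted(g.groups[0]) == ["C", "D"]   # ordered by mean, desc
        assert sorted(g.groups[1]) == ["A", "B"]

    def test_input_order_invariance(self):
        table = _freq_table({"A": (0.10, 0.01), "B": (0.30, 0.01),
                             "C": (0.31, 0.01)}, seed=2)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert anova_tukey(table).groups == anova_tukey(shuffled).groups

    def test_published_frequency_columns_reject_null(self):
        """The reported per-sample frequency table rejects equal variability
        across AMPs at alpha = 0.001."""
        from ampdiv.published import published_counts
        table = published_counts().rename(columns={"frequency": "frequency"})
        g = anova_tukey(table[["amp_id", "sample_id", "frequency"]])
        assert g.rejected and g.anova_p < 0.001
        # mytilins B/C least variable, myticin C / defensin most variable
        order = [a for grp in g.groups for a in grp]
        assert order[-1] == "MytlC"

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(_freq_table({"A": (0.1, 0.01)}))


class TestMeanSd:
    def test_published_mytc_mean(self):
        """MytC per-sample frequencies average to the reported 0.26."""
        table = pd.DataFrame({
            "amp_id": ["MytC"] * 6,
            "sample_id": list("abcdef"),
            "frequency": [0.27, 0.33, 0.23, 0.26, 0.24, 0.22],
        })
        out = mean_sd_by_amp(table)
        assert out.loc[0, "mean_display"] == "0.26"
        assert out.loc[0, "sd_display"] == "0.04"

    def test_constant_vector_sd_zero(self):
        table = pd.DataFrame({"amp_id": ["A"] * 4, "sample_id": list("abcd"),
                              "frequency": [0.2] * 4})
        assert mean_sd_by_amp(table).loc[0, "sd"] == 0.0

    def test_single_sample_rejected(self):
        table = pd.DataFrame({"amp_id": ["A"], "sample_id": ["s"],
                              "frequency": [0.2]})
        with pytest.raises(ValueError):
            mean_sd_by_amp(table)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            vals = rng.random(int(rng.integers(2, 12)))
            table = pd.DataFrame({"amp_id": "A", "sample_id": range(len(vals)),
                                  "frequency": vals})
            out = mean_sd_by_amp(table)
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert out.loc[0, "mean"] == pytest.approx(mean, abs=1e-12)
            assert out.loc[0, "sd"] == pytest.approx(sd, abs=1e-12)
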