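"""Transcript-variant diversity statistics.

* exact clustering of identical reads (same length, 100% identity) into
  reference-identical vs variant clusters;
* virtual translation of clusters covered at least 3x, with silent-change
  redundancy removed, to enumerate non-redundant peptide variants and check
  cysteine-array retention;
* partition of SNC sets into common vs sample-exclusive changes;
* variability grouping of the AMPs: one-way ANOVA (alpha = 0.001) on the
  per-sample SNC frequencies followed by all-pairs Tukey HSD (alpha = 0.05)
  and a compact homogeneous-subset partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping_pileup import Scoring, align_read
from .preprocess import Read
from .reference_model import ReferenceAmplicon, translate_cds


@dataclass
class ReadCluster:
    amp_id: str
    sample_id: str
    representative: str
    size: int
    kind: str  # reference_identical | variant


@dataclass
class PeptideVariant:
    amp_id: str
    sample_id: str
    peptide: str
    supporting_clusters: list[ReadCluster]
    total_support: int
    cysteine_array_retained: bool
    partial: bool = False


def cluster_reads(
    reads: Sequence[Read],
    reference: ReferenceAmplicon,
    sample_id: str,
) -> list[ReadCluster]:
    """Group reads with identical length and sequence (sense orientation).

    A cluster is ``reference_identical`` when its sequence occurs verbatim
    in the reference amplicon, else ``variant``.
    """
    groups: dict[str, int] = {}
    for r in reads:
        seq = r.bases if r.direction != "reverse" else _revcomp(r.bases)
        groups[seq] = groups.get(seq, 0) + 1
    clusters = []
    for seq, size in sorted(groups.items(), key=lambda kv: (-kv[1], kv[0])):
        kind = "reference_identical" if seq in reference.sequence else "variant"
        clusters.append(ReadCluster(
            amp_id=reference.amp_id, sample_id=sample_id,
            representative=seq, size=size, kind=kind,
        ))
    return clusters


def _revcomp(seq: str) -> str:
    from .reference_model import revcomp
    return revcomp(seq)


def enumerate_peptides(
    clusters: Sequence[ReadCluster],
    amplicon: ReferenceAmplicon,
    min_cov: int = 3,
    min_identity: float = 0.8,
) -> list[PeptideVariant]:
    """Translate clusters covered >= ``min_cov`` and collapse redundancy.

    Each cluster representative is aligned to the reference to fix the
    reading frame; translation spans the fully covered cds codons of the
    cluster (codons with gaps render 'X').  Peptides identical after
    translation are merged (silent substitutions removed); the count of
    distinct peptides is the headline diversity statistic.  A variant is
    flagged when any covered cysteine-array position is no longer cysteine.
    """
    by_peptide: dict[tuple[str, int], list[ReadCluster]] = {}
    meta: dict[tuple[str, int], dict] = {}
    for cluster in clusters:
        if cluster.size < min_cov:
            continue
        read = Read(read_id="cluster", bases=cluster.representative,
                    quals=np.full(len(cluster.representative), 40))
        aln = align_read(read, amplicon, Scoring(), min_identity=min_identity)
        if aln is None:
            continue
        peptide, first_codon, covered = _translate_cluster(aln, amplicon)
        if not peptide:
            continue
        partial = covered < amplicon.covered_codons
        key = (peptide, first_codon)
        by_peptide.setdefault(key, []).append(cluster)
        if key not in meta:
            retained = all(
                peptide[c - first_codon] == "C"
                for c in amplicon.cysteine_positions
                if 0 <= c - first_codon < len(peptide)
            )
            meta[key] = {"retained": retained, "partial": partial,
                         "first_codon": first_codon}
    out = []
    for (peptide, first_codon), members in sorted(by_peptide.items()):
        out.append(PeptideVariant(
            amp_id=amplicon.amp_id,
            sample_id=members[0].sample_id,
            peptide=peptide,
            supporting_clusters=members,
            total_support=sum(c.size for c in members),
            cysteine_array_retained=meta[(peptide, first_codon)]["retained"],
            partial=meta[(peptide, first_codon)]["partial"],
        ))
    return out


def _translate_cluster(aln, amplicon: ReferenceAmplicon):
    """Translate the aligned cluster over its fully covered cds codons."""
    # gapped read laid over reference coordinates ('-' where deleted)
    over: dict[int, str] = {}
    pos = aln.ref_start
    rp = 0
    for op in aln.op_string:
        if op in "MX":
            over[pos] = aln.read_bases[rp]
            rp += 1
            pos += 1
        elif op == "I":
            rp += 1
        else:
            over[pos] = "-"
            pos += 1
    aas = []
    first_codon = None
    for codon_idx in amplicon.covered_codon_indices():
        s, e = amplicon.codon_span(codon_idx)
        bases = [over.get(p) for p in range(s, e + 1)]
        if any(b is None for b in bases):
            if first_codon is not None:
                break  # stop at the first uncovered codon past the start
            continue
        if first_codon is None:
            first_codon = codon_idx
        codon = "".join(bases)
        aas.append("X" if "-" in codon else translate_cds(codon))
    return "".join(aas), (first_codon or 0), len(aas)


@dataclass
class CommonExclusiveReport:
    """Set partition of SNC keys across a sample collection."""

    common: set
    exclusive: dict[str, set]
    shared_partial: set
    union: set
    percent_common: dict[str, float]


def common_exclusive(snc_sets: dict[str, set]) -> CommonExclusiveReport:
    """Common (present in all samples) vs exclusive (single-sample) SNCs.

    ``percent_common[s]`` is the share of sample s's SNCs that are common to
    every sample in the collection.
    """
    if not snc_sets:
        raise ValueError("empty sample collection")
    sets = {s: set(v) for s, v in snc_sets.items()}
    union = set().union(*sets.values())
    common = set.intersection(*sets.values())
    exclusive = {}
    for s, v in sets.items():
        others = set().union(*(w for t, w in sets.items() if t != s)) if len(sets) > 1 else set()
        exclusive[s] = v - others
    shared_partial = union - common - set().union(*exclusive.values())
    percent_common = {
        s: (100.0 * len(common) / len(v)) if v else float("nan")
        for s, v in sets.items()
    }
    return CommonExclusiveReport(
        common=common, exclusive=exclusive, shared_partial=shared_partial,
        union=union, percent_common=percent_common,
    )


@dataclass
class DiversityGrouping:
    anova_F: float
    anova_p: float
    alpha_anova: float
    tukey_alpha: float
    rejected: bool
    groups: Optional[list[list[str]]]   # homogeneous subsets, ordered by mean
    means: dict[str, float]
    undefined: bool = False


def anova_tukey(
    freq_table: pd.DataFrame,
    alpha_anova: float = 0.001,
    alpha_tukey: float = 0.05,
) -> DiversityGrouping:
    """One-way ANOVA (AMP as factor, per-sample frequencies as replicates)
    followed, on rejection, by all-pairs Tukey HSD and a greedy
    homogeneous-subset partition ordered by mean frequency.

    ``freq_table`` is long-form with columns amp_id, sample_id, frequency.
    """
    required = {"amp_id", "sample_id", "frequency"}
    if not required <= set(freq_table.columns):
        raise ValueError(f"freq_table needs columns {sorted(required)}")
    amps = sorted(freq_table["amp_id"].unique())
    if len(amps) < 2:
        raise ValueError("need at least 2 AMPs")
    groups_data = [freq_table.loc[freq_table["amp_id"] == a, "frequency"].to_numpy()
                   for a in amps]
    if any(len(g) < 2 for g in groups_data):
        raise ValueError("need at least 2 samples per AMP")
    means = {a: float(np.mean(g)) for a, g in zip(amps, groups_data)}

    pooled_within_var = np.concatenate([g - g.mean() for g in groups_data]).var()
    if pooled_within_var == 0.0 and len({g.mean() for g in groups_data}) <= 1:
        return DiversityGrouping(
            anova_F=float("nan"), anova_p=float("nan"),
            alpha_anova=alpha_anova, tukey_alpha=alpha_tukey,
            rejected=False, groups=[sorted(amps)], means=means, undefined=True,
        )

    F, p = sps.f_oneway(*groups_data)
    if not p < alpha_anova:
        return DiversityGrouping(
            anova_F=float(F), anova_p=float(p),
            alpha_anova=alpha_anova, tukey_alpha=alpha_tukey,
            rejected=False, groups=[sorted(amps, key=lambda a: -means[a])],
            means=means,
        )

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(
        endog=freq_table["frequency"].to_numpy(),
        groups=freq_table["amp_id"].to_numpy(),
        alpha=alpha_tukey,
    )
    different = set()
    tbl = res.summary().data[1:]
    for g1, g2, _meandiff, _padj, _lo, _hi, reject in tbl:
        if reject:
            different.add(frozenset((str(g1), str(g2))))

    ordered = sorted(amps, key=lambda a: (-means[a], a))
    groups: list[list[str]] = []
    current: list[str] = []
    for amp in ordered:
        if all(frozenset((amp, other)) not in different for other in current):
            current.append(amp)
        else:
            groups.append(current)
            current = [amp]
    if current:
        groups.append(current)
    return DiversityGrouping(
        anova_F=float(F), anova_p=float(p),
        alpha_anova=alpha_anova, tukey_alpha=alpha_tukey,
        rejected=True, groups=groups, means=means,
    )


def mean_sd_by_amp(freq_table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Per-AMP mean and sample SD (n-1) of the per-sample frequencies."""
    grouped = freq_table.groupby("amp_id")["frequency"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"SD undefined with a single sample for {bad}")
    out = pd.DataFrame({
        "mean": grouped.mean(),
        "sd": grouped.std(ddof=1),
        "n": counts,
    }).reset_index()
    out["mean_display"] = out["mean"].map(lambda x: f"{_hup(x, ndigits):.2f}")
    out["sd_display"] = out["sd"].map(lambda x: f"{_hup(x, ndigits):.2f}")
    return out


def _hup(x: float, nd: int) -> float:
    from .snc_analysis import round_half_up
    return round_half_up(x, nd)


def clusters_to_frame(clusters_by_key: dict[tuple[str, str], list[ReadCluster]],
                      peptides_by_key: dict[tuple[str, str], list[PeptideVariant]]
                      ) -> pd.DataFrame:
    """Per-AMP x sample diversity table: total clusters, % with >=1 SNC,
    non-redundant peptides."""
    rows = []
    for (amp, sample), clusters in sorted(clusters_by_key.items()):
        total = len(clusters)
        n_variant = sum(1 for c in clusters if c.kind == "variant")
        peptides = peptides_by_key.get((amp, sample), [])
        rows.append({
            "amp_id": amp,
            "sample_id": sample,
            "total_clusters": total,
            "pct_with_snc": (100.0 * n_variant / total) if total else float("nan"),
            "non_redundant_peptides": len(peptides),
            "pct_cysteine_retained": (
                100.0 * sum(p.cysteine_array_retained for p in peptides) / len(peptides)
                if peptides else float("nan")
            ),
        })
    return pd.DataFrame(rows)
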