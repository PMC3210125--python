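"""Genuine-SNC calling, codon merging, synonymous/non-synonymous
classification, omega and per-codon SNC frequency.

A single nucleotide change (SNC) is "genuine" when the quality-passing
pileup column reaches the minimum depth (default 30x) and the alternate
allele reaches the minimum frequency (default 3%); base-quality and
neighborhood-quality gates are applied upstream when the pileup is built.
SNCs sharing a codon are merged into one codon change, classified by
virtual translation, and summarized per AMP x sample:

* omega = non-synonymous / synonymous codon changes (a raw count ratio, not
  an opportunity-normalised dN/dS); with zero synonymous changes omega is
  undefined and reported bracketed, e.g. ``[11]``;
* SNC frequency per base of the cds = merged cds changes / covered codons
  (the per-nucleotide variant is also emitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iproduct
from typing import Iterable, Optional, Sequence

import pandas as pd

from .mapping_pileup import PileupColumn
from .reference_model import (
    ReferenceAmplicon,
    locate_region,
    translate_cds,
    CODON_TABLE,
)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding used for report formatting."""
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class SNC:
    """A genuine single nucleotide change.

    ``position`` is the 1-based coordinate on the parent AMP transcript
    frame (shared by overlapping amplicons); ``amplicon_position`` is the
    coordinate on the amplicon itself.
    """

    amp_id: str
    amplicon_id: str
    position: int
    amplicon_position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    frequency: float
    region: str
    in_cds: bool
    suspect_reference: bool = False

    def key(self) -> tuple[str, int, str]:
        """Identity on the shared AMP coordinate frame (for pooling/sets)."""
        return (self.amp_id, self.position, self.alt_base)


@dataclass(frozen=True)
class MergedCodonChange:
    amp_id: str
    codon_index: int         # 1-based precursor residue index
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    component_sncs: tuple[SNC, ...]

    def key(self) -> tuple[str, int, str]:
        return (self.amp_id, self.codon_index, self.alt_codon)


@dataclass
class VariantCallSummary:
    """Per AMP x sample variant-calling summary (one report row)."""

    amp_id: str
    sample_id: str
    snc_total: int           # whole precursor transcript, incl. flanks
    snc_cds: int             # merged codon changes within the cds
    ns_count: int
    syn_count: int
    omega: Optional[float]   # None when syn_count == 0 (reported bracketed)
    covered_codons: int
    frequency: float         # snc_cds / covered_codons (unrounded)
    frequency_per_nt: float  # snc_cds / (3 * covered_codons)

    @property
    def omega_display(self) -> str:
        if self.omega is None:
            return f"[{self.ns_count}]"
        return f"{round_half_up(self.omega, 1):.1f}"

    @property
    def frequency_display(self) -> str:
        return f"{round_half_up(self.frequency, 2):.2f}"


def omega_from_counts(snc_cds: int, ns_count: int) -> Optional[float]:
    """Omega from a (merged cds changes, non-synonymous changes) pair."""
    syn = snc_cds - ns_count
    if syn < 0:
        raise ValueError("ns_count exceeds snc_cds")
    if syn == 0:
        return None
    return ns_count / syn


def call_sncs(
    pileup: Sequence[PileupColumn],
    amplicon: ReferenceAmplicon,
    min_depth: int = 30,
    min_freq: float = 0.03,
    max_freq: Optional[float] = None,
) -> list[SNC]:
    """Call genuine SNCs from a quality-gated pileup.

    Only substitutions are called (indels never produce SNCs).  Depth and
    frequency use quality-passing observations.  If ``max_freq`` is set,
    near-fixed columns (possible reference errors, like a variant present in
    every read) are *flagged* ``suspect_reference`` rather than dropped.
    """
    out: list[SNC] = []
    for col in pileup:
        qp_depth = sum(col.allele_counts.values())
        if qp_depth < min_depth:
            continue
        for alt, count in col.allele_counts.items():
            if alt == col.ref_base or count == 0:
                continue
            freq = count / qp_depth
            if freq < min_freq:
                continue
            region = locate_region(amplicon, col.position)
            in_cds = amplicon.codon_index(col.position) is not None
            out.append(SNC(
                amp_id=amplicon.amp_id,
                amplicon_id=amplicon.amplicon_id,
                position=amplicon.transcript_position(col.position),
                amplicon_position=col.position,
                ref_base=col.ref_base,
                alt_base=alt,
                alt_count=count,
                depth=qp_depth,
                frequency=freq,
                region=region,
                in_cds=in_cds,
                suspect_reference=(max_freq is not None and freq >= max_freq),
            ))
    return out


def merge_and_classify(
    sncs: Iterable[SNC], amplicon: ReferenceAmplicon
) -> list[MergedCodonChange]:
    """Merge cds SNCs by codon and classify by virtual translation.

    SNCs outside the covered cds are ignored here (they pass through to the
    precursor totals unmerged).  Multi-allelic positions yield one merged
    change per alternate allele, each combined with the other positions'
    single alternates.
    """
    by_codon: dict[int, list[SNC]] = {}
    for snc in sncs:
        codon = amplicon.codon_index(snc.amplicon_position)
        if codon is None:
            continue
        if codon not in amplicon.covered_codon_indices():
            continue  # partially covered edge codon: not classifiable
        by_codon.setdefault(codon, []).append(snc)

    changes: list[MergedCodonChange] = []
    for codon, members in sorted(by_codon.items()):
        start, _end = amplicon.codon_span(codon)
        ref_codon = amplicon.ref_codon(codon)
        by_offset: dict[int, list[SNC]] = {}
        for snc in members:
            by_offset.setdefault(snc.amplicon_position - start, []).append(snc)
        if len(by_offset) > 3:
            raise RuntimeError(
                f"more than 3 positions claim codon {codon} of "
                f"{amplicon.amplicon_id}"
            )
        # one merged change per combination of alternates (one per position)
        for combo in _iproduct(*by_offset.values()):
            alt = list(ref_codon)
            for snc in combo:
                alt[snc.amplicon_position - start] = snc.alt_base
            alt_codon = "".join(alt)
            ref_aa = CODON_TABLE[ref_codon]
            alt_aa = CODON_TABLE[alt_codon]
            changes.append(MergedCodonChange(
                amp_id=amplicon.amp_id,
                codon_index=codon,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                synonymous=(ref_aa == alt_aa),
                component_sncs=tuple(combo),
            ))
    return changes


def pool_sncs(snc_lists: Iterable[Sequence[SNC]]) -> list[SNC]:
    """Union SNCs from overlapping amplicons of one AMP on the shared
    transcript coordinate frame (first occurrence wins)."""
    seen: dict[tuple, SNC] = {}
    for sncs in snc_lists:
        for snc in sncs:
            seen.setdefault(snc.key(), snc)
    return sorted(seen.values(), key=lambda s: (s.position, s.alt_base))


def pool_changes(change_lists: Iterable[Sequence[MergedCodonChange]]
                 ) -> list[MergedCodonChange]:
    """Union merged codon changes across amplicons of one AMP."""
    seen: dict[tuple, MergedCodonChange] = {}
    for changes in change_lists:
        for ch in changes:
            seen.setdefault(ch.key(), ch)
    return sorted(seen.values(), key=lambda c: (c.codon_index, c.alt_codon))


def summarize(
    changes: Sequence[MergedCodonChange],
    sncs: Sequence[SNC],
    amp_id: str,
    sample_id: str,
    covered_codons: int,
) -> VariantCallSummary:
    """Build the per-AMP x sample summary row.

    ``changes`` and ``sncs`` must already be pooled per AMP (see
    :func:`pool_changes` / :func:`pool_sncs`); ``covered_codons`` is the
    union of fully covered cds codons across the AMP's amplicons.
    """
    if covered_codons <= 0:
        raise ValueError("covered_codons must be positive")
    ns = sum(1 for c in changes if not c.synonymous)
    syn = sum(1 for c in changes if c.synonymous)
    snc_cds = ns + syn
    return VariantCallSummary(
        amp_id=amp_id,
        sample_id=sample_id,
        snc_total=len(sncs),
        snc_cds=snc_cds,
        ns_count=ns,
        syn_count=syn,
        omega=None if syn == 0 else ns / syn,
        covered_codons=covered_codons,
        frequency=snc_cds / covered_codons,
        frequency_per_nt=snc_cds / (3 * covered_codons),
    )


def summaries_to_frame(summaries: Sequence[VariantCallSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "amp_id": s.amp_id,
            "sample_id": s.sample_id,
            "snc_total": s.snc_total,
            "snc_cds": s.snc_cds,
            "frequency": s.frequency_display,
            "ns_sncs": s.ns_count,
            "syn_sncs": s.syn_count,
            "omega": s.omega_display,
            "covered_codons": s.covered_codons,
        })
    return pd.DataFrame(rows)


def sncs_to_frame(sncs: Sequence[SNC], sample_id: str) -> pd.DataFrame:
    rows = []
    for s in sncs:
        rows.append({
            "amp_id": s.amp_id,
            "sample_id": sample_id,
            "amplicon_id": s.amplicon_id,
            "position": s.position,
            "ref": s.ref_base,
            "alt": s.alt_base,
            "frequency": round(s.frequency, 6),
            "depth": s.depth,
            "region": s.region,
            "in_cds": s.in_cds,
            "suspect_reference": s.suspect_reference,
        })
    return pd.DataFrame(rows, columns=[
        "amp_id", "sample_id", "amplicon_id", "position", "ref", "alt",
        "frequency", "depth", "region", "in_cds", "suspect_reference",
    ])


def snc_maps(
    changes_by_sample: dict[str, Sequence[MergedCodonChange]],
    amp_id: str,
    bounds=None,
) -> pd.DataFrame:
    """Positional map of codon changes (synonymous vs non-synonymous),
    region-annotated — tabular form of the per-AMP substitution figures."""
    rows = []
    for sample, changes in sorted(changes_by_sample.items()):
        for ch in changes:
            if ch.amp_id != amp_id:
                continue
            region = bounds.label_of(ch.codon_index) if bounds is not None else ""
            rows.append({
                "amp_id": amp_id,
                "sample_id": sample,
                "codon_index": ch.codon_index,
                "change": f"{ch.ref_aa}{ch.codon_index}{ch.alt_aa}",
                "type": "synonymous" if ch.synonymous else "non_synonymous",
                "region": region,
            })
    return pd.DataFrame(rows, columns=[
        "amp_id", "sample_id", "codon_index", "change", "type", "region",
    ])


def plot_snc_map(map_frame: pd.DataFrame, amplicon: ReferenceAmplicon, path):
    """Render a substitution map: empty markers synonymous, filled markers
    non-synonymous, along the precursor with region shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.2))
    b = amplicon.region_bounds
    spans = {"signal": b.signal, "mature": b.mature}
    if b.c_terminal is not None:
        spans["c_terminal"] = b.c_terminal
    colors = {"signal": "#dddddd", "mature": "#bcd9ea", "c_terminal": "#e8d5b5"}
    for name, (lo, hi) in spans.items():
        ax.axvspan(lo - 0.5, hi + 0.5, color=colors[name], alpha=0.6, label=name)
    samples = sorted(map_frame["sample_id"].unique())
    for yi, sample in enumerate(samples):
        sub = map_frame[map_frame["sample_id"] == sample]
        for _, row in sub.iterrows():
            filled = row["type"] == "non_synonymous"
            ax.plot(row["codon_index"], yi, marker="o", ms=6,
                    mfc=("black" if filled else "white"), mec="black")
    ax.set_yticks(range(len(samples)))
    ax.set_yticklabels(samples)
    ax.set_xlabel("precursor residue")
    ax.set_title(f"{amplicon.amp_id}: codon changes (filled = non-synonymous)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
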