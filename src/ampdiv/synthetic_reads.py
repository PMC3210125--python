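"""454-style barcoded amplicon read simulator with ground truth.

Emulates bidirectional pyrosequencing of barcoded amplicon pools:

* each read is ``adaptor + barcode + primer + template``, drawn from a
  haplotype pool on the sense or antisense strand;
* per-base qualities follow a position-decay profile and substitution
  errors are injected with probability ``10^(-q/10)`` of the *recorded*
  quality, so qualities and error rates are mutually consistent;
* indel errors concentrate at homopolymer runs with a rate that is
  non-decreasing in run length (the hallmark 454 failure mode);
* a configurable fraction of junk reads (short, low-quality) emulates the
  ~15% of raw reads that quality filters discard.

A truth sidecar records, per read, the emitting haplotype, direction and
every injected error, so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import Read
from .reference_model import ReferenceAmplicon, ReferencePanel, revcomp

_BASES = "ACGT"


@dataclass(frozen=True)
class TrueSNC:
    """A planted substitution: amplicon position (1-based), ref/alt base,
    expected allele frequency among reads covering the position."""

    position: int
    ref_base: str
    alt_base: str
    frequency: float


@dataclass
class HaplotypeTruth:
    """Ground truth for one amplicon x sample pool.

    ``haplotypes`` are whole-amplicon sequences with frequencies summing to
    one; each differs from the reference only at listed SNC positions
    (substitutions only).  With ``linkage='independent'`` the pool holds the
    reference only and sites are applied independently per emitted read.
    """

    amplicon_id: str
    sample_id: str
    haplotypes: list[tuple[str, float]]
    true_sncs: list[TrueSNC]
    linkage: str = "haplotypic"

    def __post_init__(self):
        total = sum(f for _, f in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if self.linkage not in ("haplotypic", "independent"):
            raise ValueError(f"bad linkage {self.linkage!r}")


@dataclass
class ErrorModel454:
    """Tunable 454 error model.

    ``homopolymer_indel_rate[r-1]`` is the per-occurrence probability of an
    indel at a maximal homopolymer run of length ``r`` (the last entry
    applies to runs of 8+); it must be non-decreasing.  ``read_length`` is
    (mean, sd, min, max) of the template portion, i.e. after the
    adaptor+barcode+primer prefix.  Defaults are calibrated so that on a
    full-length (440 bp) amplicon the demultiplexed, quality-trimmed reads
    average ~226 bp and ~15% of reads are junk.
    """

    substitution_rate: float = 0.004
    homopolymer_indel_rate: tuple[float, ...] = (
        0.0002, 0.0006, 0.002, 0.006, 0.015, 0.03, 0.05, 0.08,
    )
    read_length: tuple[float, float, int, int] = (226.0, 40.0, 110, 420)
    junk_read_fraction: float = 0.15
    quality_floor: float = 0.4     # error-weight at read start (relative)
    quality_slope: float = 1.2     # error-weight growth over one mean length
    quality_noise_sigma: float = 0.4
    qual_range: tuple[int, int] = (2, 40)

    def __post_init__(self):
        probs = (self.substitution_rate, self.junk_read_fraction,
                 *self.homopolymer_indel_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        rates = self.homopolymer_indel_rate
        if any(a > b for a, b in zip(rates, rates[1:])):
            raise ValueError("homopolymer indel rate must be non-decreasing")

    @classmethod
    def noiseless(cls) -> "ErrorModel454":
        """Error-free model emitting full-length templates (exact copies)."""
        return cls(
            substitution_rate=0.0,
            homopolymer_indel_rate=(0.0,) * 8,
            read_length=(1e6, 0.0, 10**6, 10**6),
            junk_read_fraction=0.0,
        )

    def indel_rate(self, run_length: int) -> float:
        idx = min(run_length, len(self.homopolymer_indel_rate)) - 1
        return self.homopolymer_indel_rate[idx]


def observable_span(amp: ReferenceAmplicon) -> tuple[int, int]:
    """Amplicon positions covered by neither primer (1-based inclusive).

    Variants under the primers are unobservable: reads carry the primer
    oligo sequence there, and the prefix is clipped at demultiplexing.
    """
    return len(amp.fwd_primer) + 1, amp.length - len(amp.rev_primer)


def build_haplotype_pool(
    ref: ReferenceAmplicon,
    n_variant_sites: int,
    freq_spec: Sequence[float],
    linkage: str = "haplotypic",
    seed: int = 0,
    sample_id: str = "S1",
    cds_only: bool = True,
    exclude_positions: Sequence[int] = (),
) -> HaplotypeTruth:
    """Plant ``n_variant_sites`` substitutions at the given frequencies.

    In haplotypic mode each site rides its own whole-amplicon haplotype
    (plus the reference at the residual frequency); in independent mode
    sites are assigned per-read at draw time.  Sites are restricted to the
    primer-free region, and to the covered cds when ``cds_only``.
    """
    if len(freq_spec) != n_variant_sites:
        raise ValueError("freq_spec length must equal n_variant_sites")
    if any(not 0.0 < f < 1.0 for f in freq_spec):
        raise ValueError("allele frequencies must be in (0, 1)")
    if linkage == "haplotypic" and sum(freq_spec) >= 1.0:
        raise ValueError("haplotypic frequencies must sum to < 1")

    lo, hi = observable_span(ref)
    if cds_only:
        lo = max(lo, ref.cds_start + ref.cds_frame_offset)
        hi = min(hi, ref.cds_end)
    candidates = [p for p in range(lo, hi + 1) if p not in set(exclude_positions)]
    if n_variant_sites > len(candidates):
        raise ValueError(
            f"{n_variant_sites} sites requested but only {len(candidates)} "
            "positions available"
        )
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(candidates, size=n_variant_sites, replace=False))
    sncs = []
    for pos, freq in zip(positions, freq_spec):
        ref_base = ref.sequence[pos - 1]
        alts = [b for b in _BASES if b != ref_base]
        sncs.append(TrueSNC(
            position=int(pos),
            ref_base=ref_base,
            alt_base=alts[rng.integers(3)],
            frequency=float(freq),
        ))

    if linkage == "haplotypic":
        haplotypes = [(ref.sequence, 1.0 - sum(freq_spec))]
        for snc in sncs:
            seq = (ref.sequence[: snc.position - 1] + snc.alt_base
                   + ref.sequence[snc.position:])
            haplotypes.append((seq, snc.frequency))
    else:
        haplotypes = [(ref.sequence, 1.0)]
    return HaplotypeTruth(
        amplicon_id=ref.amplicon_id,
        sample_id=sample_id,
        haplotypes=haplotypes,
        true_sncs=sncs,
        linkage=linkage,
    )


def merge_pools(common: HaplotypeTruth, exclusive: HaplotypeTruth,
                reference: str) -> HaplotypeTruth:
    """Combine a population-wide (common) pool with a sample-exclusive pool.

    Both must be haplotypic single-site pools on the same amplicon; the
    merged pool carries one haplotype per site and the reference at the
    residual frequency.  Emulates the study structure in which most genuine
    variants are shared by every sample and a minority is sample-specific.
    """
    if common.amplicon_id != exclusive.amplicon_id:
        raise ValueError("pools are on different amplicons")
    if common.linkage != "haplotypic" or exclusive.linkage != "haplotypic":
        raise ValueError("merge_pools requires haplotypic pools")
    sncs = sorted(common.true_sncs + exclusive.true_sncs,
                  key=lambda t: t.position)
    if len({t.position for t in sncs}) != len(sncs):
        raise ValueError("common and exclusive pools share a position")
    total = sum(t.frequency for t in sncs)
    if total >= 1.0:
        raise ValueError("merged frequencies must sum to < 1")
    haplotypes = [(reference, 1.0 - total)]
    for t in sncs:
        haplotypes.append((
            reference[: t.position - 1] + t.alt_base + reference[t.position:],
            t.frequency,
        ))
    return HaplotypeTruth(
        amplicon_id=common.amplicon_id,
        sample_id=exclusive.sample_id,
        haplotypes=haplotypes,
        true_sncs=sncs,
        linkage="haplotypic",
    )


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs as (start index, length)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


def _draw_qualities(model: ErrorModel454, n: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-base (qualities, error probabilities) consistent with each other.

    Error probabilities follow a position-decay weight normalised per read
    so the mean equals ``substitution_rate``; recorded qualities are the
    rounded phred transform and the returned probabilities are recomputed
    from the *recorded* integer qualities.
    """
    qlo, qhi = model.qual_range
    if model.substitution_rate == 0.0:
        q = np.full(n, qhi, dtype=np.int16)
        return q, np.zeros(n)
    pos = np.arange(n)
    w = model.quality_floor + model.quality_slope * pos / model.read_length[0]
    sigma = model.quality_noise_sigma
    noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n)
    e = model.substitution_rate * (w / w.mean()) * noise
    q = np.clip(np.round(-10.0 * np.log10(e)), qlo, qhi).astype(np.int16)
    return q, np.power(10.0, -q.astype(float) / 10.0)


def simulate_reads(
    truth: HaplotypeTruth,
    panel: ReferencePanel,
    n_reads: int,
    model: Optional[ErrorModel454] = None,
    seed: int = 0,
    read_prefix: str = "",
) -> tuple[list[Read], pd.DataFrame]:
    """Emit ``n_reads`` barcoded reads from a haplotype pool.

    Returns the reads (FASTQ-ready) and a truth sidecar with one row per
    read: haplotype, direction, junk flag and every injected error with its
    amplicon coordinate.  Deterministic for a fixed seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    model = model or ErrorModel454()
    amp = panel.amplicons[truth.amplicon_id]
    rng = np.random.default_rng(seed)

    bc_f = panel.barcode_map[(truth.sample_id, amp.amplicon_id, "forward")]
    bc_r = panel.barcode_map[(truth.sample_id, amp.amplicon_id, "reverse")]
    # the synthesized strand carries the primer oligo; reads show the
    # reference bases at the primer site regardless of haplotype
    plen_f, plen_r = len(amp.fwd_primer), len(amp.rev_primer)
    prefix_f = panel.adaptor_a + bc_f + amp.sequence[:plen_f]
    prefix_r = panel.adaptor_b + bc_r + revcomp(amp.sequence[-plen_r:])

    hap_seqs = [h for h, _ in truth.haplotypes]
    hap_freqs = np.array([f for _, f in truth.haplotypes])
    mean_len, sd_len, min_len, max_len = model.read_length
    L = amp.length

    reads: list[Read] = []
    rows = []
    for i in range(n_reads):
        is_junk = rng.random() < model.junk_read_fraction
        forward = rng.random() < 0.5
        if truth.linkage == "haplotypic":
            hidx = int(rng.choice(len(hap_seqs), p=hap_freqs))
            hap = hap_seqs[hidx]
            hap_id = f"hap{hidx}" if hidx else "ref"
        else:
            hap = truth.haplotypes[0][0]
            applied = []
            for snc in truth.true_sncs:
                if rng.random() < snc.frequency:
                    hap = hap[: snc.position - 1] + snc.alt_base + hap[snc.position:]
                    applied.append(snc.position)
            hap_id = "mosaic:" + ",".join(map(str, applied)) if applied else "ref"

        if forward:
            template_full = hap[plen_f:]
            ref_pos = list(range(plen_f + 1, L + 1))
            prefix = prefix_f
        else:
            template_full = revcomp(hap)[plen_r:]
            ref_pos = list(range(L - plen_r, 0, -1))
            prefix = prefix_r

        if is_junk:
            tlen = int(rng.uniform(5, 65)) if rng.random() < 0.88 else int(rng.uniform(70, 95))
            tlen = min(tlen, len(template_full))
            bases = prefix + template_full[:tlen]
            quals = np.concatenate([
                np.full(len(prefix), 25, dtype=np.int16),
                rng.integers(2, 9, size=tlen).astype(np.int16),
            ])
            reads.append(Read(read_id=_rid(read_prefix, truth, i), bases=bases, quals=quals))
            rows.append(_row(read_prefix, truth, i, hap_id, forward, True, 0, 0, 0, "", ""))
            continue

        if sd_len > 0:
            tlen = int(np.clip(round(rng.normal(mean_len, sd_len)), min_len, max_len))
        else:
            tlen = int(min_len)
        tlen = min(tlen, len(template_full))
        tmpl = list(template_full[:tlen])
        tpos = ref_pos[:tlen]

        # homopolymer indels (sequencing noise only; never truth variants)
        n_ins = n_del = 0
        indel_notes = []
        if any(r > 0 for r in model.homopolymer_indel_rate):
            shift = 0
            for start, run in _homopolymer_runs("".join(tmpl)):
                p = model.indel_rate(run)
                if p > 0 and rng.random() < p:
                    at = start + run - 1 + shift
                    if not 0 <= at < len(tmpl):
                        continue
                    if rng.random() < 0.5:
                        tmpl.insert(at, tmpl[at])
                        tpos.insert(at, tpos[at])
                        n_ins += 1
                        shift += 1
                        indel_notes.append(f"{tpos[at]}:ins")
                    else:
                        indel_notes.append(f"{tpos[at]}:del")
                        del tmpl[at], tpos[at]
                        n_del += 1
                        shift -= 1

        bases = list(prefix) + tmpl
        quals, err_p = _draw_qualities(model, len(bases), rng)
        n_sub = 0
        sub_notes = []
        if model.substitution_rate > 0:
            hits = np.nonzero(rng.random(len(bases)) < err_p)[0]
            for h in hits:
                old = bases[h]
                alts = [b for b in _BASES if b != old]
                bases[h] = alts[rng.integers(3)]
                n_sub += 1
                if h >= len(prefix):
                    sub_notes.append(f"{tpos[h - len(prefix)]}:{old}>{bases[h]}")
                else:
                    sub_notes.append(f"prefix{h}:{old}>{bases[h]}")

        reads.append(Read(read_id=_rid(read_prefix, truth, i),
                          bases="".join(bases), quals=quals))
        rows.append(_row(read_prefix, truth, i, hap_id, forward, False,
                         n_sub, n_ins, n_del,
                         ";".join(sub_notes), ";".join(indel_notes)))

    sidecar = pd.DataFrame(rows, columns=[
        "read_id", "sample_id", "amplicon_id", "haplotype_id", "direction",
        "is_junk", "read_len", "n_sub", "n_ins", "n_del",
        "sub_positions", "indel_positions",
    ])
    sidecar["read_len"] = [len(r) for r in reads]
    return reads, sidecar


def _rid(prefix: str, truth: HaplotypeTruth, i: int) -> str:
    base = f"{truth.amplicon_id}.{truth.sample_id}.{i:06d}"
    return f"{prefix}{base}" if prefix else base


def _row(prefix, truth, i, hap_id, forward, junk, n_sub, n_ins, n_del, subs, indels):
    return {
        "read_id": _rid(prefix, truth, i),
        "sample_id": truth.sample_id,
        "amplicon_id": truth.amplicon_id,
        "haplotype_id": hap_id,
        "direction": "forward" if forward else "reverse",
        "is_junk": junk,
        "read_len": 0,
        "n_sub": n_sub,
        "n_ins": n_ins,
        "n_del": n_del,
        "sub_positions": subs,
        "indel_positions": indels,
    }


def simulate_study(
    panel: ReferencePanel,
    pools: dict[tuple[str, str], HaplotypeTruth],
    n_reads_per_pool: int,
    model: Optional[ErrorModel454] = None,
    seed: int = 0,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate several (sample, amplicon) pools and shuffle reads together."""
    rng = np.random.default_rng(seed)
    all_reads: list[Read] = []
    sidecars = []
    for key in sorted(pools):
        truth = pools[key]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        reads, sidecar = simulate_reads(truth, panel, n_reads_per_pool,
                                        model=model, seed=sub_seed)
        all_reads.extend(reads)
        sidecars.append(sidecar)
    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[int(k)] for k in order]
    sidecar = pd.concat(sidecars, ignore_index=True)
    return all_reads, sidecar
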