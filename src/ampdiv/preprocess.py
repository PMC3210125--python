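"""Read preprocessing: barcode demultiplexing, quality trimming, length filter.

Reads carry a 5' prefix of sequencing adaptor (19 nt) + sample barcode
(5 nt) + gene-specific primer.  Demultiplexing matches that prefix on both
orientations, assigns (sample, amplicon, direction) on a best unique match,
and clips the prefix.  Quality trimming is the modified-Mott algorithm:
keep the contiguous segment maximizing the running sum of
``error_limit - 10^(-q/10)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .reference_model import IUPAC, ReferencePanel, revcomp

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {c: sum(_BASE_BITS[b] for b in bases) for c, bases in IUPAC.items()}


@dataclass
class Read:
    """A sequencing read with per-base phred qualities (0-60)."""

    read_id: str
    bases: str
    quals: np.ndarray
    assigned_sample: Optional[str] = None
    assigned_amplicon: Optional[str] = None
    direction: Optional[str] = None

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError(f"{self.read_id}: phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Read":
        return replace(self, bases=revcomp(self.bases), quals=self.quals[::-1].copy())


# ---------------------------------------------------------------------------
# FASTQ / FASTA+QUAL I/O (Sanger phred+33)
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(33 + int(x)) for x in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{q}\n")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().strip()
            fh.readline()
            quals = fh.readline().strip()
            reads.append(Read(
                read_id=header.strip()[1:].split()[0],
                bases=bases,
                quals=np.frombuffer(quals.encode(), dtype=np.uint8).astype(np.int16) - 33,
            ))
    return reads


def write_fasta_qual(reads: Iterable[Read], fasta_path: str | Path,
                     qual_path: str | Path) -> None:
    """454-native FASTA + QUAL writer."""
    with open(fasta_path, "w") as fa, open(qual_path, "w") as qu:
        for r in reads:
            fa.write(f">{r.read_id}\n{r.bases}\n")
            qu.write(f">{r.read_id}\n{' '.join(str(int(x)) for x in r.quals)}\n")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class DemuxKey:
    sample: str
    amplicon: str
    direction: str
    prefix_bits: np.ndarray     # IUPAC bitmask per prefix position
    adaptor_len: int
    barcode_len: int
    primer_len: int

    @property
    def prefix_len(self) -> int:
        return self.adaptor_len + self.barcode_len + self.primer_len


@dataclass
class DemuxResult:
    assigned: list[Read]
    unassigned: list[Read]
    counts: dict = field(default_factory=dict)


def _seq_bits(seq: str) -> np.ndarray:
    return np.array([_CODE_BITS.get(c, 0) for c in seq.upper()], dtype=np.uint8)


def _build_keys(panel: ReferencePanel) -> list[DemuxKey]:
    keys = []
    for (sample, amplicon, direction), bc in sorted(panel.barcode_map.items()):
        amp = panel.amplicons[amplicon]
        adaptor = panel.adaptor_a if direction == "forward" else panel.adaptor_b
        primer = amp.fwd_primer if direction == "forward" else amp.rev_primer
        keys.append(DemuxKey(
            sample=sample, amplicon=amplicon, direction=direction,
            prefix_bits=_seq_bits(adaptor + bc + primer),
            adaptor_len=len(adaptor), barcode_len=len(bc), primer_len=len(primer),
        ))
    return keys


def _match_one(bases_bits: np.ndarray, keys: list[DemuxKey], max_mismatch: int,
               primer_max_mismatch: int, adaptor_max_mismatch: int):
    """Return (key, total_mismatches) for the best unique match, else None."""
    best = None
    best_mm = None
    tied = False
    n = len(bases_bits)
    for key in keys:
        L = key.prefix_len
        if n < L:
            continue
        mism = (bases_bits[:L] & key.prefix_bits) == 0
        a = key.adaptor_len
        b = a + key.barcode_len
        mm_ad = int(mism[:a].sum())
        if mm_ad > adaptor_max_mismatch:
            continue
        mm_bc = int(mism[a:b].sum())
        if mm_bc > max_mismatch:
            continue
        mm_pr = int(mism[b:].sum())
        if mm_pr > primer_max_mismatch:
            continue
        total = mm_ad + mm_bc + mm_pr
        if best_mm is None or total < best_mm:
            best, best_mm, tied = key, total, False
        elif total == best_mm:
            tied = True
    if best is None or tied:
        return None
    return best, best_mm


def demultiplex(
    reads: Sequence[Read],
    panel: ReferencePanel,
    max_mismatch: int = 0,
    primer_max_mismatch: int = 2,
    adaptor_max_mismatch: int = 2,
) -> DemuxResult:
    """Assign reads to (sample, amplicon, direction) by their 5' prefix.

    Both orientations are tried, so a reverse-complemented copy of a read
    receives the identical assignment.  The matched adaptor+barcode+primer
    prefix is clipped from assigned reads; ties and non-matches land in the
    unassigned bin.
    """
    keys = _build_keys(panel)
    assigned: list[Read] = []
    unassigned: list[Read] = []
    for read in reads:
        hit = _match_one(_seq_bits(read.bases), keys, max_mismatch,
                         primer_max_mismatch, adaptor_max_mismatch)
        oriented = read
        if hit is None:
            oriented = read.reverse_complement()
            hit = _match_one(_seq_bits(oriented.bases), keys, max_mismatch,
                             primer_max_mismatch, adaptor_max_mismatch)
        if hit is None:
            unassigned.append(read)
            continue
        key, _ = hit
        L = key.prefix_len
        assigned.append(replace(
            oriented,
            bases=oriented.bases[L:],
            quals=oriented.quals[L:].copy(),
            assigned_sample=key.sample,
            assigned_amplicon=key.amplicon,
            direction=key.direction,
        ))
    counts = {
        "input": len(reads),
        "assigned": len(assigned),
        "unassigned": len(unassigned),
    }
    return DemuxResult(assigned=assigned, unassigned=unassigned, counts=counts)


# ---------------------------------------------------------------------------
# Modified-Mott quality trimming
# ---------------------------------------------------------------------------

def mott_segment(quals: np.ndarray, error_limit: float) -> tuple[int, int]:
    """Best segment [start, end) under the modified-Mott score.

    Per-base score is ``error_limit - 10^(-q/10)``; the returned half-open
    interval maximizes the segment sum.  Ties break to the smallest end,
    then the smallest start; an all-negative read yields the empty (0, 0).
    """
    scores = error_limit - np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    best_sum = 0.0
    best = (0, 0)
    min_p, min_i = 0.0, 0
    for j in range(1, len(prefix)):
        val = prefix[j] - min_p
        if val > best_sum:
            best_sum = val
            best = (min_i, j)
        if prefix[j] < min_p:
            min_p, min_i = prefix[j], j
    return best


def mott_trim(read: Read, error_limit: float = 0.05) -> Read:
    """Quality-trim a read to its best modified-Mott segment."""
    if not 0 < error_limit < 1:
        raise ValueError("error_limit must be in (0, 1)")
    s, e = mott_segment(read.quals, error_limit)
    return replace(read, bases=read.bases[s:e], quals=read.quals[s:e].copy())


def length_filter(reads: Sequence[Read], min_len: int = 100
                  ) -> tuple[list[Read], list[Read]]:
    """Partition reads by post-trim length."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in reads if len(r) >= min_len]
    discarded = [r for r in reads if len(r) < min_len]
    return kept, discarded
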