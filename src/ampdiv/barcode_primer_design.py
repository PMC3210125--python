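"""Barcode-set generation and fusion-primer validation.

Multiplexed amplicon pyrosequencing tags each PCR with a short 5' barcode
(MID) placed between the sequencing adaptor and the gene-specific primer.
To survive homopolymer-prone flow-space base calling, barcodes must contain
no homopolymer run (here: no two identical adjacent bases) and differ
pairwise by at least two substitutions so that a single sequencing error
cannot re-assign a read to another sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .reference_model import IUPAC, revcomp

_BASES = "ACGT"


class BarcodeCapacityError(ValueError):
    """Requested more barcodes than the constraints admit."""

    def __init__(self, requested: int, achieved: int, k: int, min_dist: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"cannot construct {requested} barcodes of length {k} with pairwise "
            f"Hamming distance >= {min_dist}: achieved maximum is {achieved}"
        )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def has_homopolymer(seq: str) -> bool:
    """True if any two identical bases are adjacent."""
    return any(a == b for a, b in zip(seq, seq[1:]))


def homopolymer_free_kmers(k: int) -> list[str]:
    """All k-mers over ACGT without adjacent identical bases (4*3^(k-1))."""
    return ["".join(p) for p in product(_BASES, repeat=k)
            if not has_homopolymer("".join(p))]


def generate_barcode_set(
    k: int,
    n: Optional[int] = None,
    min_dist: int = 2,
    seed: int = 0,
) -> list[str]:
    """Construct barcodes: distinct k-mers, homopolymer-free, pairwise
    Hamming distance >= ``min_dist``.

    A seeded shuffle of the candidate space followed by greedy selection
    yields a maximal set; the result is deterministic and order-stable for a
    fixed seed.  If ``n`` is given and infeasible, a
    :class:`BarcodeCapacityError` reports the achieved (greedy) maximum.
    With ``n=None`` the full greedy-maximal set is returned.
    """
    if k < 1 or min_dist < 1 or (n is not None and n < 1):
        raise ValueError("k, min_dist and n must be positive")
    candidates = homopolymer_free_kmers(k)
    rng = np.random.default_rng(seed)
    rng.shuffle(candidates)
    chosen: list[str] = []
    for cand in candidates:
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
            if n is not None and len(chosen) == n:
                return chosen
    if n is not None and len(chosen) < n:
        raise BarcodeCapacityError(n, len(chosen), k, min_dist)
    return chosen


def validate_barcode_set(barcodes: Sequence[str], min_dist: int = 2) -> bool:
    """Exhaustive re-validation of a barcode set (pairwise check)."""
    if len(set(barcodes)) != len(barcodes):
        return False
    for bc in barcodes:
        if has_homopolymer(bc) or not set(bc) <= set(_BASES):
            return False
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if hamming(a, b) < min_dist:
                return False
    return True


@dataclass(frozen=True)
class FusionPrimer:
    """adaptor + barcode + gene-specific primer, 5'->3'."""

    adaptor: str
    barcode: str
    gene_primer: str
    direction: str  # forward | reverse

    def __post_init__(self):
        if len(self.adaptor) != 19:
            raise ValueError(f"adaptor must be a 19-mer, got {len(self.adaptor)}")
        if has_homopolymer(self.barcode):
            raise ValueError(f"barcode {self.barcode!r} contains a homopolymer run")
        if not set(self.barcode) <= set(_BASES):
            raise ValueError(f"barcode {self.barcode!r} has non-ACGT bases")
        if not set(self.gene_primer.upper()) <= set(IUPAC):
            raise ValueError("gene primer contains non-IUPAC characters")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")

    @property
    def sequence(self) -> str:
        return self.adaptor + self.barcode + self.gene_primer


def assemble_fusion_primer(
    adaptor: str, barcode: str, gene_primer: str, direction: str
) -> FusionPrimer:
    return FusionPrimer(adaptor.upper(), barcode.upper(), gene_primer.upper(), direction)


def _expand_first(seq: str) -> str:
    """Replace IUPAC codes by their first expansion (for advisory Tm only)."""
    return "".join(IUPAC[c][0] for c in seq.upper())


def melting_temperature(primer: str) -> float:
    """Nearest-neighbor Tm estimate (advisory, never a hard gate).

    Degenerate positions are collapsed to one representative base before the
    thermodynamic sum, so the value is approximate for degenerate primers.
    """
    from Bio.SeqUtils import MeltingTemp as mt

    return float(mt.Tm_NN(_expand_first(primer)))


def longest_complementary_run(a: str, b: str) -> int:
    """Length of the longest contiguous antiparallel complementary duplex
    between two oligos = longest common substring of ``a`` and revcomp(b).
    Concrete bases only (IUPAC collapsed to first expansion).
    """
    a = _expand_first(a)
    b = revcomp(_expand_first(b))
    n, m = len(a), len(b)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


@dataclass
class PrimerPairReport:
    """Report-only validation of a fusion-primer pair."""

    amplicon_len: int
    length_ok: bool
    tm_fwd: float
    tm_rev: float
    self_run_fwd: int
    self_run_rev: int
    cross_run: int
    run_threshold: int
    flags: list[str] = field(default_factory=list)


def check_primer_pair(
    fwd: FusionPrimer,
    rev: FusionPrimer,
    amplicon_len: int,
    run_threshold: int = 8,
    max_amplicon_len: int = 440,
) -> PrimerPairReport:
    """Advisory checks on a primer pair: amplicon length cap, Tm estimates,
    and the longest self-/cross-complementary runs (dimer propensity).
    """
    report = PrimerPairReport(
        amplicon_len=amplicon_len,
        length_ok=amplicon_len <= max_amplicon_len,
        tm_fwd=melting_temperature(fwd.gene_primer),
        tm_rev=melting_temperature(rev.gene_primer),
        self_run_fwd=longest_complementary_run(fwd.sequence, fwd.sequence),
        self_run_rev=longest_complementary_run(rev.sequence, rev.sequence),
        cross_run=longest_complementary_run(fwd.sequence, rev.sequence),
        run_threshold=run_threshold,
    )
    if not report.length_ok:
        report.flags.append(
            f"amplicon length {amplicon_len} exceeds {max_amplicon_len} bp cap"
        )
    if report.self_run_fwd >= run_threshold:
        report.flags.append(f"forward self-dimer run {report.self_run_fwd}")
    if report.self_run_rev >= run_threshold:
        report.flags.append(f"reverse self-dimer run {report.self_run_rev}")
    if report.cross_run >= run_threshold:
        report.flags.append(f"cross-dimer run {report.cross_run}")
    return report
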