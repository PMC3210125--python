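"""Semi-global alignment to the reference backbone, coverage, and
quality-aware pileups.

Reads (already demultiplexed, primer-clipped and trimmed) are aligned with
an affine-gap Gotoh dynamic program: the read is aligned end-to-end while
reference overhangs are free, which fits amplicon reads that start at a
primer boundary and stop mid-amplicon.  Reverse reads are aligned as their
reverse complement.  A gap of length k costs ``gap_open + k * gap_extend``.

Pileup columns keep two allele tallies: raw counts and "quality-passing"
counts, where an observation only passes if its own base quality reaches
``qual_min`` AND the mean quality in a +-``neighborhood_radius`` window on
the read reaches ``neighborhood_min``.  Genuine-SNC calling downstream uses
only quality-passing counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import Read
from .reference_model import ReferenceAmplicon

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}

NEG = -1e18


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """A read-to-amplicon alignment.

    ``op_string`` is over M (match), X (mismatch), I (insertion: read base
    absent from reference) and D (deletion: reference base absent from
    read); it consumes the full aligned read and the reference span
    [ref_start, ref_end].  ``read_bases``/``read_quals`` are stored in
    reference (sense) orientation.
    """

    read_id: str
    amplicon_id: str
    ref_start: int
    ref_end: int
    op_string: str
    strand: str
    identity: float
    score: float
    read_bases: str
    read_quals: np.ndarray


@dataclass
class PileupColumn:
    amplicon_id: str
    position: int
    ref_base: str
    depth: int
    allele_counts: dict[str, int]   # quality-passing only
    raw_counts: dict[str, int]
    deletions: int


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(b, 4) for b in seq], dtype=np.int8)


@njit(cache=True)
def _gotoh(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = read.shape[0], ref.shape[0]
    H = np.full((m + 1, n + 1), NEG)
    V = np.full((m + 1, n + 1), NEG)   # vertical: consumes read (insertion)
    Z = np.full((m + 1, n + 1), NEG)   # horizontal: consumes ref (deletion)
    # pointers: H: 0 diag, 1 horiz, 2 vert; V/Z: 0 open, 1 extend
    pH = np.zeros((m + 1, n + 1), dtype=np.int8)
    pV = np.zeros((m + 1, n + 1), dtype=np.int8)
    pZ = np.zeros((m + 1, n + 1), dtype=np.int8)
    for j in range(n + 1):
        H[0, j] = 0.0                  # free leading reference overhang
    for i in range(1, m + 1):
        V[i, 0] = gap_open + i * gap_extend
        H[i, 0] = V[i, 0]
        pH[i, 0] = 2
        pV[i, 0] = 1
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = match if ri == ref[j - 1] else mismatch
            if ri > 3 or ref[j - 1] > 3:
                s = mismatch
            diag = H[i - 1, j - 1] + s
            zo = H[i, j - 1] + gap_open + gap_extend
            ze = Z[i, j - 1] + gap_extend
            if zo >= ze:
                Z[i, j] = zo
                pZ[i, j] = 0
            else:
                Z[i, j] = ze
                pZ[i, j] = 1
            vo = H[i - 1, j] + gap_open + gap_extend
            ve = V[i - 1, j] + gap_extend
            if vo >= ve:
                V[i, j] = vo
                pV[i, j] = 0
            else:
                V[i, j] = ve
                pV[i, j] = 1
            # tie preference: diagonal, then deletion (ref gap left-packed),
            # then insertion
            best = diag
            ptr = 0
            if Z[i, j] > best:
                best = Z[i, j]
                ptr = 1
            if V[i, j] > best:
                best = V[i, j]
                ptr = 2
            H[i, j] = best
            pH[i, j] = ptr
    # best end column on the last read row (leftmost on ties)
    bj = 0
    bs = H[m, 0]
    for j in range(1, n + 1):
        if H[m, j] > bs:
            bs = H[m, j]
            bj = j
    return bs, bj, pH, pV, pZ


def align_read(
    read: Read,
    amplicon: ReferenceAmplicon,
    scoring: Scoring = Scoring(),
    min_identity: float = 0.8,
) -> Optional[Alignment]:
    """Align one read to its amplicon; returns ``None`` for non-specific
    (identity below the floor) or empty reads.

    Reads flagged ``direction='reverse'`` are reverse-complemented first, so
    all alignments are reported on the sense strand.
    """
    if len(read) == 0:
        return None
    strand = "-" if read.direction == "reverse" else "+"
    oriented = read.reverse_complement() if strand == "-" else read
    renc = _encode(oriented.bases)
    tenc = _encode(amplicon.sequence)
    score, bj, pH, pV, pZ = _gotoh(
        renc, tenc, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    ops = []
    i, j = len(renc), bj
    state = 0  # 0 in H, 1 in Z, 2 in V
    while i > 0:
        if state == 0:
            state = pH[i, j]
            if state == 0:
                ops.append("M" if (renc[i - 1] == tenc[j - 1] and renc[i - 1] <= 3)
                           else "X")
                i -= 1
                j -= 1
        elif state == 1:
            ops.append("D")
            nxt = pZ[i, j]
            j -= 1
            state = 0 if nxt == 0 else 1
        else:
            ops.append("I")
            nxt = pV[i, j]
            i -= 1
            state = 0 if nxt == 0 else 2
    # strip any leading deletions left in the buffer (they would represent
    # reference bases before the read start; the free overhang makes them
    # unreachable, but guard anyway)
    while ops and ops[-1] == "D":
        ops.pop()
        j += 1
    op_string = "".join(reversed(ops))
    ref_start = j + 1
    ref_end = ref_start + sum(1 for o in op_string if o in "MXD") - 1
    matches = op_string.count("M")
    identity = matches / len(op_string) if op_string else 0.0
    if identity < min_identity:
        return None
    return Alignment(
        read_id=read.read_id,
        amplicon_id=amplicon.amplicon_id,
        ref_start=ref_start,
        ref_end=ref_end,
        op_string=op_string,
        strand=strand,
        identity=identity,
        score=float(score),
        read_bases=oriented.bases,
        read_quals=oriented.quals,
    )


@dataclass
class CoverageStats:
    amplicon_id: str
    average_coverage: float
    depth: np.ndarray  # per-position read depth (M/X observations)


def coverage_stats(alignments: Sequence[Alignment],
                   amplicon: ReferenceAmplicon) -> CoverageStats:
    """Average base coverage = total aligned read bases / reference length."""
    depth = np.zeros(amplicon.length, dtype=np.int64)
    total_bases = 0
    for aln in alignments:
        total_bases += sum(1 for o in aln.op_string if o in "MXI")
        pos = aln.ref_start - 1
        for op in aln.op_string:
            if op in "MX":
                depth[pos] += 1
                pos += 1
            elif op == "D":
                pos += 1
    return CoverageStats(
        amplicon_id=amplicon.amplicon_id,
        average_coverage=total_bases / amplicon.length if amplicon.length else 0.0,
        depth=depth,
    )


def _window_means(quals: np.ndarray, radius: int) -> np.ndarray:
    """Mean quality in a +-radius window around each read position."""
    n = len(quals)
    if n == 0:
        return quals.astype(float)
    c = np.concatenate([[0.0], np.cumsum(quals.astype(float))])
    idx = np.arange(n)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def build_pileup(
    alignments: Sequence[Alignment],
    amplicon: ReferenceAmplicon,
    qual_min: int = 20,
    neighborhood_min: int = 15,
    neighborhood_radius: int = 5,
) -> list[PileupColumn]:
    """Quality-aware pileup over the amplicon.

    Insertions are excluded from columns; deletions are tallied separately.
    """
    if qual_min < 0 or neighborhood_min < 0:
        raise ValueError("quality thresholds must be >= 0")
    L = amplicon.length
    raw = np.zeros((4, L), dtype=np.int64)
    qp = np.zeros((4, L), dtype=np.int64)
    dels = np.zeros(L, dtype=np.int64)
    for aln in alignments:
        quals = aln.read_quals
        wmeans = _window_means(quals, neighborhood_radius)
        rp = 0             # read cursor
        pos = aln.ref_start - 1
        for op in aln.op_string:
            if op in "MX":
                b = _ENC.get(aln.read_bases[rp], 4)
                if b <= 3:
                    raw[b, pos] += 1
                    if quals[rp] >= qual_min and wmeans[rp] >= neighborhood_min:
                        qp[b, pos] += 1
                rp += 1
                pos += 1
            elif op == "I":
                rp += 1
            else:  # D
                dels[pos] += 1
                pos += 1
    columns = []
    for p in range(L):
        columns.append(PileupColumn(
            amplicon_id=amplicon.amplicon_id,
            position=p + 1,
            ref_base=amplicon.sequence[p],
            depth=int(raw[:, p].sum()),
            allele_counts={b: int(qp[i, p]) for i, b in enumerate(_BASES)},
            raw_counts={b: int(raw[i, p]) for i, b in enumerate(_BASES)},
            deletions=int(dels[p]),
        ))
    return columns


def pileup_to_frame(columns: Sequence[PileupColumn]) -> pd.DataFrame:
    rows = []
    for c in columns:
        row = {"amplicon_id": c.amplicon_id, "position": c.position,
               "ref_base": c.ref_base, "depth": c.depth, "del": c.deletions}
        for b in _BASES:
            row[b] = c.raw_counts[b]
            row[f"qp_{b}"] = c.allele_counts[b]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_pileup(df: pd.DataFrame) -> list[PileupColumn]:
    return [
        PileupColumn(
            amplicon_id=r["amplicon_id"], position=int(r["position"]),
            ref_base=r["ref_base"], depth=int(r["depth"]),
            allele_counts={b: int(r[f"qp_{b}"]) for b in _BASES},
            raw_counts={b: int(r[b]) for b in _BASES},
            deletions=int(r["del"]),
        )
        for r in df.to_dict("records")
    ]


def sam_export(alignments: Sequence[Alignment], panel_amplicons,
               path) -> None:
    """Minimal SAM export (one reference contig per amplicon)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for aid, amp in sorted(panel_amplicons.items()):
            fh.write(f"@SQ\tSN:{aid}\tLN:{amp.length}\n")
        for a in alignments:
            cigar = _ops_to_cigar(a.op_string)
            flag = 16 if a.strand == "-" else 0
            qual = "".join(chr(33 + int(q)) for q in a.read_quals)
            fh.write(f"{a.read_id}\t{flag}\t{a.amplicon_id}\t{a.ref_start}\t60\t"
                     f"{cigar}\t*\t0\t0\t{a.read_bases}\t{qual}\n")


def _ops_to_cigar(ops: str) -> str:
    out = []
    prev, run = None, 0
    for o in ops + "$":
        o = {"M": "M", "X": "M", "I": "I", "D": "D"}.get(o, o)
        if o == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{run}{prev}")
            prev, run = o, 1
    return "".join(out) if out else "*"
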