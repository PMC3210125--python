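"""Synthetic demonstration panel: 13 amplicons over 9 mussel AMP precursors.

The real reference amplicons are not redistributed; this module builds a
*synthetic stand-in* panel with the published structural features of the
nine AMP isotypes (precursor and mature-peptide lengths, 8-cysteine arrays
— 12 for mytimycin — signal/mature/C-terminal region layout, the missing
C-terminal extension of the truncated defensin, and two partially
overlapping amplicons for the longer or more variable coding sequences) so
that every downstream stage can be exercised end-to-end.

The panel is generated deterministically: sequences are random sense-strand
codons (no internal stops) with TGT/TGC at the cysteine-array positions,
flanked by short untranslated stretches that host the gene-specific primers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .barcode_primer_design import generate_barcode_set
from .reference_model import (
    CODON_TABLE,
    ReferenceAmplicon,
    ReferencePanel,
    RegionBounds,
    revcomp,
    write_panel,
)

_PANEL_SEED = 20111107
_FLANK = 25          # UTR-like flank on each side of the cds, nt
_PRIMER_LEN = 20

# (precursor aa, mature aa, n cysteines, signal aa) per isotype; mature
# lengths and cysteine counts follow the published isotype features.
_AMP_SPECS = {
    "MytA":  (96, 40, 8, 21),
    "MytB":  (96, 40, 8, 21),
    "MytC":  (100, 40, 8, 22),
    "MytlB": (103, 34, 8, 22),
    "MytlC": (100, 34, 8, 22),
    "MytlD": (97, 34, 8, 21),
    "MytM":  (152, 54, 12, 22),
    "MGD1":  (82, 39, 8, 21),
    "MGDt":  (61, 38, 8, 23),   # no C-terminal extension
}

# AMPs amplified as two partially overlapping amplicons (longer or highly
# variable cds); the rest use a single amplicon.
_TWO_AMPLICON = ("MytA", "MytC", "MytlB", "MytlC")

# One degenerate position is introduced into the forward primer of these
# AMPs to exercise IUPAC-aware primer matching.
_DEGENERATE_PRIMER = ("MytlC", "MGD1", "MGDt")

_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_CYS_CODONS = ("TGT", "TGC")

DEMO_SAMPLES = ("Pa", "Vi", "Ve")

_IUPAC_SUPERSET = {"A": "R", "G": "R", "C": "Y", "T": "Y"}


def _make_cds(rng: np.random.Generator, aa_len: int, cys_positions: tuple[int, ...]) -> str:
    codons = []
    for i in range(1, aa_len + 1):
        if i in cys_positions:
            codons.append(_CYS_CODONS[rng.integers(2)])
        else:
            codons.append(_SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _cys_array(mature_lo: int, mature_hi: int, n: int) -> tuple[int, ...]:
    # evenly spread through the mature peptide
    span = mature_hi - mature_lo
    return tuple(mature_lo + round(span * (i + 1) / (n + 1)) for i in range(n))


def _window_cds_meta(w_start: int, w_end: int, tc_start: int, tc_end: int):
    """Derive (cds_start, cds_end, frame_offset, codon_start) in amplicon
    coordinates for a transcript window [w_start, w_end] overlapping the
    transcript cds [tc_start, tc_end]."""
    ov_s, ov_e = max(w_start, tc_start), min(w_end, tc_end)
    if ov_s > ov_e:
        raise ValueError("window does not cover any cds")
    k = ov_s - tc_start            # 0-based nt offset into the cds
    offset = (3 - k % 3) % 3
    first_codon = k // 3 + 1 if offset == 0 else k // 3 + 2
    usable = ov_e - (ov_s + offset) + 1
    n_codons = usable // 3
    if n_codons < 1:
        raise ValueError("window covers no complete codon")
    cds_end_t = ov_s + offset + 3 * n_codons - 1
    return (ov_s - w_start + 1, cds_end_t - w_start + 1, offset, first_codon)


def demo_panel(seed: int = _PANEL_SEED) -> ReferencePanel:
    """Build the deterministic 13-amplicon demonstration panel."""
    rng = np.random.default_rng(seed)
    amplicons: dict[str, ReferenceAmplicon] = {}

    for amp_id, (aa_len, mature_len, n_cys, sig_len) in _AMP_SPECS.items():
        mature_lo, mature_hi = sig_len + 1, sig_len + mature_len
        cterm = None if mature_hi == aa_len else (mature_hi + 1, aa_len)
        bounds = RegionBounds(signal=(1, sig_len), mature=(mature_lo, mature_hi),
                              c_terminal=cterm)
        cys = _cys_array(mature_lo, mature_hi, n_cys)
        cds = _make_cds(rng, aa_len, cys)
        transcript = _random_dna(rng, _FLANK) + cds + _random_dna(rng, _FLANK)
        tc_start, tc_end = _FLANK + 1, _FLANK + len(cds)
        L = len(transcript)

        if L <= 440 and amp_id not in _TWO_AMPLICON:
            windows = [(1, L)]
        elif amp_id in _TWO_AMPLICON:
            # two overlapping windows covering the whole transcript
            mid = L // 2
            windows = [(1, min(mid + 40, L)), (max(1, mid - 40 - 19), L)]
        else:
            # cds longer than the amplicon cap (mytimycin-like): cover the
            # first 440 bases, leaving the cds tail unsequenced
            windows = [(1, 440)]

        for w_i, (w_s, w_e) in enumerate(windows, start=1):
            seq = transcript[w_s - 1 : w_e]
            cds_s, cds_e, off, codon_start = _window_cds_meta(w_s, w_e, tc_start, tc_end)
            fwd = seq[:_PRIMER_LEN]
            rev = revcomp(seq[-_PRIMER_LEN:])
            if amp_id in _DEGENERATE_PRIMER:
                fwd = fwd[:10] + _IUPAC_SUPERSET[fwd[10]] + fwd[11:]
            aid = f"{amp_id}-{w_i}" if len(windows) > 1 else amp_id
            amplicons[aid] = ReferenceAmplicon(
                amplicon_id=aid,
                amp_id=amp_id,
                sequence=seq,
                cds_start=cds_s,
                cds_end=cds_e,
                cds_frame_offset=off,
                region_bounds=bounds,
                cysteine_positions=cys,
                fwd_primer=fwd,
                rev_primer=rev,
                cds_codon_start=codon_start,
                transcript_start=w_s,
            )

    barcodes = generate_barcode_set(k=5, n=len(DEMO_SAMPLES) * len(amplicons),
                                    min_dist=2, seed=seed)
    barcode_map: dict[tuple[str, str, str], str] = {}
    i = 0
    for sample in DEMO_SAMPLES:
        for aid in sorted(amplicons):
            # one barcode per primer pair, shared by both directions
            barcode_map[(sample, aid, "forward")] = barcodes[i]
            barcode_map[(sample, aid, "reverse")] = barcodes[i]
            i += 1

    adaptor_a = _random_dna(np.random.default_rng(seed + 1), 19)
    adaptor_b = _random_dna(np.random.default_rng(seed + 2), 19)
    return ReferencePanel(
        amplicons=amplicons,
        barcode_map=barcode_map,
        adaptor_a=adaptor_a,
        adaptor_b=adaptor_b,
    )


def write_demo_panel(path: str | Path, seed: int = _PANEL_SEED) -> Path:
    """Materialise the demo panel as a panel directory."""
    return write_panel(demo_panel(seed), path)
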