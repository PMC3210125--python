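"""Reference amplicon panel: data model, I/O, translation and region bookkeeping.

An amplicon panel describes the sequences that were PCR-amplified from the
AMP precursor transcripts, together with the coordinate metadata needed for
codon-aware downstream analysis:

* where the covered portion of the coding sequence (cds) sits on the
  amplicon, and in which reading frame;
* the precursor region annotation (signal peptide, mature peptide,
  C-terminal extension) in amino-acid coordinates;
* the conserved cysteine array of the mature peptide;
* gene-specific primers and the per-sample barcode map used for
  demultiplexing.

Coordinates are 1-based inclusive on the sense strand of the amplified
transcript throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAX_AMPLICON_LEN = 440  # PCR product length cap imposed by ~250 bp read length

AMP_IDS = ("MytA", "MytB", "MytC", "MytlB", "MytlC", "MytlD", "MytM", "MGD1", "MGDt")

_DNA = set("ACGT")

# IUPAC degeneracy, used for primers only (references must be concrete).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_codon_table() -> dict[str, str]:
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


CODON_TABLE = _build_codon_table()


def translate_cds(seq: str, frame_offset: int = 0) -> str:
    """Translate a nucleotide sequence with the standard genetic code.

    ``frame_offset`` bases are skipped before the first codon.  Codons
    containing ``N`` translate to ``'X'``; stop codons render ``'*'`` and
    translation continues (read clusters are reported as-is); a trailing
    partial codon is dropped.  Empty input yields an empty peptide.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError(f"frame_offset must be 0-2, got {frame_offset}")
    seq = seq.upper()[frame_offset:]
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            if set(codon) <= set("ACGTN"):
                aa = "X"
            else:
                raise ValueError(f"invalid codon {codon!r}")
        out.append(aa)
    return "".join(out)


class PanelError(ValueError):
    """Raised when a panel file violates a structural invariant."""


@dataclass(frozen=True)
class RegionBounds:
    """Precursor region spans in 1-based amino-acid coordinates.

    ``c_terminal`` may be ``None`` (MGDt-style precursors lack a C-terminal
    extension).  The three spans must partition [1, precursor length]
    contiguously and without overlap.
    """

    signal: tuple[int, int]
    mature: tuple[int, int]
    c_terminal: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.signal[0] != 1:
            raise PanelError("signal peptide must start at residue 1")
        if self.mature[0] != self.signal[1] + 1:
            raise PanelError("mature peptide must follow signal peptide directly")
        if self.c_terminal is not None and self.c_terminal[0] != self.mature[1] + 1:
            raise PanelError("C-terminal extension must follow mature peptide directly")
        for lo, hi in self._spans():
            if lo > hi:
                raise PanelError(f"empty/inverted region span ({lo}, {hi})")

    def _spans(self):
        spans = [self.signal, self.mature]
        if self.c_terminal is not None:
            spans.append(self.c_terminal)
        return spans

    @property
    def precursor_length(self) -> int:
        return self._spans()[-1][1]

    def label_of(self, aa_index: int) -> str:
        """Region label for a precursor residue index; 'flank' if outside."""
        if self.signal[0] <= aa_index <= self.signal[1]:
            return "signal"
        if self.mature[0] <= aa_index <= self.mature[1]:
            return "mature"
        if self.c_terminal is not None and self.c_terminal[0] <= aa_index <= self.c_terminal[1]:
            return "c_terminal"
        return "flank"


@dataclass(frozen=True)
class ReferenceAmplicon:
    """One amplified reference sequence with its coordinate metadata.

    ``cds_start``/``cds_end`` delimit the covered cds portion on the
    amplicon; ``cds_frame_offset`` bases past ``cds_start`` reach the first
    complete codon, and that codon is residue ``cds_codon_start`` of the
    precursor.  ``transcript_start`` places amplicon base 1 on the parent
    AMP transcript so overlapping amplicons of one AMP share a coordinate
    frame.
    """

    amplicon_id: str
    amp_id: str
    sequence: str
    cds_start: int
    cds_end: int
    cds_frame_offset: int
    region_bounds: RegionBounds
    cysteine_positions: tuple[int, ...]
    fwd_primer: str
    rev_primer: str
    cds_codon_start: int = 1
    transcript_start: int = 1

    def __post_init__(self):
        if self.amp_id not in AMP_IDS:
            raise PanelError(f"{self.amplicon_id}: unknown amp_id {self.amp_id!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= _DNA:
            bad = sorted(set(seq) - _DNA)
            raise PanelError(f"{self.amplicon_id}: non-ACGT bases in reference: {bad}")
        if self.length > MAX_AMPLICON_LEN:
            raise PanelError(
                f"{self.amplicon_id}: length {self.length} exceeds the "
                f"{MAX_AMPLICON_LEN} bp amplicon cap"
            )
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise PanelError(f"{self.amplicon_id}: cds span outside amplicon")
        if not 0 <= self.cds_frame_offset <= 2:
            raise PanelError(f"{self.amplicon_id}: cds_frame_offset must be 0-2")
        if (self.cds_end - self.cds_start + 1 - self.cds_frame_offset) % 3 != 0:
            raise PanelError(
                f"{self.amplicon_id}: covered cds is not a whole number of codons"
            )
        for p in self.fwd_primer, self.rev_primer:
            if not set(p.upper()) <= set(IUPAC):
                raise PanelError(f"{self.amplicon_id}: invalid primer base in {p!r}")
        n_cys = len(self.cysteine_positions)
        expected = 12 if self.amp_id == "MytM" else 8
        if n_cys != expected:
            raise PanelError(
                f"{self.amplicon_id}: cysteine array has {n_cys} entries, "
                f"expected {expected} for {self.amp_id}"
            )
        lo, hi = self.region_bounds.mature
        for c in self.cysteine_positions:
            if not lo <= c <= hi:
                raise PanelError(
                    f"{self.amplicon_id}: cysteine position {c} outside mature span"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def covered_codons(self) -> int:
        """Number of complete codons of the cds covered by this amplicon."""
        return (self.cds_end - self.cds_start + 1 - self.cds_frame_offset) // 3

    def codon_index(self, position: int) -> Optional[int]:
        """Precursor codon (residue) index of an amplicon position.

        Returns ``None`` outside the covered cds.  Leading partial-codon
        bases (before the frame offset) map onto the preceding, partially
        covered codon.
        """
        if not self.cds_start <= position <= self.cds_end:
            return None
        rel = position - self.cds_start - self.cds_frame_offset
        return self.cds_codon_start + (rel // 3)

    def codon_span(self, codon_index: int) -> tuple[int, int]:
        """Amplicon positions (start, end) of a fully covered codon."""
        k = codon_index - self.cds_codon_start
        if k < 0 or k >= self.covered_codons:
            raise ValueError(f"codon {codon_index} not fully covered")
        start = self.cds_start + self.cds_frame_offset + 3 * k
        return start, start + 2

    def ref_codon(self, codon_index: int) -> str:
        s, e = self.codon_span(codon_index)
        return self.sequence[s - 1 : e]

    def transcript_position(self, position: int) -> int:
        """Map an amplicon position onto the parent transcript frame."""
        return self.transcript_start + position - 1

    def covered_codon_indices(self) -> range:
        return range(self.cds_codon_start, self.cds_codon_start + self.covered_codons)

    def translated_reference(self) -> str:
        """Virtual translation of the covered cds portion."""
        return translate_cds(
            self.sequence[self.cds_start - 1 : self.cds_end], self.cds_frame_offset
        )


def locate_region(amplicon: ReferenceAmplicon, transcript_pos: int) -> str:
    """Classify an amplicon position as flank/signal/mature/c_terminal.

    Positions outside the covered cds (including partial-codon edges that
    fall before the first or after the last completely covered codon) are
    labelled ``'flank'``.
    """
    if not 1 <= transcript_pos <= amplicon.length:
        raise ValueError(
            f"position {transcript_pos} outside [1, {amplicon.length}]"
        )
    codon = amplicon.codon_index(transcript_pos)
    if codon is None:
        return "flank"
    return amplicon.region_bounds.label_of(codon)


@dataclass
class ReferencePanel:
    """A validated set of reference amplicons plus demultiplexing metadata."""

    amplicons: dict[str, ReferenceAmplicon]
    barcode_map: dict[tuple[str, str, str], str]  # (sample, amplicon, direction)
    adaptor_a: str
    adaptor_b: str

    def __post_init__(self):
        for name, adaptor in (("A", self.adaptor_a), ("B", self.adaptor_b)):
            if len(adaptor) != 19 or not set(adaptor) <= _DNA:
                raise PanelError(f"adaptor {name} must be a 19-mer over ACGT")
        seen: dict[tuple[str, str], set[str]] = {}
        for (sample, amplicon, direction), bc in self.barcode_map.items():
            if direction not in ("forward", "reverse"):
                raise PanelError(f"bad direction {direction!r}")
            if amplicon not in self.amplicons:
                raise PanelError(f"barcode references unknown amplicon {amplicon!r}")
            key = (direction, bc)
            owner = seen.setdefault(key, set())
            owner.add((sample, amplicon))
            if len(owner) > 1:
                raise PanelError(
                    f"duplicate barcode {bc!r} in {direction} set: {sorted(owner)}"
                )

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _, _ in self.barcode_map})

    @property
    def amp_ids(self) -> list[str]:
        return sorted({a.amp_id for a in self.amplicons.values()},
                      key=AMP_IDS.index)

    def by_amp(self, amp_id: str) -> list[ReferenceAmplicon]:
        return [a for a in self.amplicons.values() if a.amp_id == amp_id]

    def covered_codons_per_amp(self) -> dict[str, int]:
        """Union of fully covered cds codons per AMP, across its amplicons."""
        out = {}
        for amp in self.amp_ids:
            codons: set[int] = set()
            for a in self.by_amp(amp):
                codons.update(a.covered_codon_indices())
            out[amp] = len(codons)
        return out


# ---------------------------------------------------------------------------
# Panel I/O: FASTA + sidecar TSVs + adaptor JSON in one directory.
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "amplicon_id", "amp_id", "cds_start", "cds_end", "cds_frame_offset",
    "cds_codon_start", "transcript_start", "signal_start", "signal_end",
    "mature_start", "mature_end", "cterm_start", "cterm_end",
    "cysteine_positions", "fwd_primer", "rev_primer",
]


def load_panel(path: str | Path) -> ReferencePanel:
    """Load a panel directory (reference.fasta, amplicons.tsv, barcodes.tsv,
    adaptors.json) and validate every invariant.
    """
    path = Path(path)
    fasta = path / "reference.fasta"
    meta_path = path / "amplicons.tsv"
    bc_path = path / "barcodes.tsv"
    ad_path = path / "adaptors.json"
    for p in (fasta, meta_path, bc_path, ad_path):
        if not p.exists():
            raise PanelError(f"panel file missing: {p}")

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise PanelError(f"amplicons.tsv missing columns: {missing_cols}")

    amplicons: dict[str, ReferenceAmplicon] = {}
    for row in meta.to_dict("records"):
        aid = row["amplicon_id"]
        if aid not in seqs:
            raise PanelError(f"no FASTA sequence for metadata row {aid!r}")
        cterm = None
        if row["cterm_start"] != "":
            cterm = (int(row["cterm_start"]), int(row["cterm_end"]))
        bounds = RegionBounds(
            signal=(int(row["signal_start"]), int(row["signal_end"])),
            mature=(int(row["mature_start"]), int(row["mature_end"])),
            c_terminal=cterm,
        )
        cys = tuple(int(x) for x in row["cysteine_positions"].split(",") if x)
        amplicons[aid] = ReferenceAmplicon(
            amplicon_id=aid,
            amp_id=row["amp_id"],
            sequence=seqs[aid],
            cds_start=int(row["cds_start"]),
            cds_end=int(row["cds_end"]),
            cds_frame_offset=int(row["cds_frame_offset"]),
            region_bounds=bounds,
            cysteine_positions=cys,
            fwd_primer=row["fwd_primer"].upper(),
            rev_primer=row["rev_primer"].upper(),
            cds_codon_start=int(row["cds_codon_start"]),
            transcript_start=int(row["transcript_start"]),
        )
    orphans = sorted(set(seqs) - set(amplicons))
    if orphans:
        raise PanelError(f"FASTA records without metadata: {orphans}")

    bcs = pd.read_csv(bc_path, sep="\t", dtype=str)
    barcode_map = {
        (r["sample_id"], r["amplicon_id"], r["direction"]): r["barcode"].upper()
        for r in bcs.to_dict("records")
    }
    if len(barcode_map) != len(bcs):
        raise PanelError("duplicate (sample, amplicon, direction) rows in barcodes.tsv")

    adaptors = json.loads(ad_path.read_text())
    return ReferencePanel(
        amplicons=amplicons,
        barcode_map=barcode_map,
        adaptor_a=adaptors["A"].upper(),
        adaptor_b=adaptors["B"].upper(),
    )


def write_panel(panel: ReferencePanel, path: str | Path) -> Path:
    """Write a panel back to its directory dialect (inverse of load_panel)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(a.sequence), id=aid, description="")
        for aid, a in sorted(panel.amplicons.items())
    ]
    with open(path / "reference.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")

    rows = []
    for aid, a in sorted(panel.amplicons.items()):
        b = a.region_bounds
        rows.append({
            "amplicon_id": aid,
            "amp_id": a.amp_id,
            "cds_start": a.cds_start,
            "cds_end": a.cds_end,
            "cds_frame_offset": a.cds_frame_offset,
            "cds_codon_start": a.cds_codon_start,
            "transcript_start": a.transcript_start,
            "signal_start": b.signal[0],
            "signal_end": b.signal[1],
            "mature_start": b.mature[0],
            "mature_end": b.mature[1],
            "cterm_start": "" if b.c_terminal is None else b.c_terminal[0],
            "cterm_end": "" if b.c_terminal is None else b.c_terminal[1],
            "cysteine_positions": ",".join(map(str, a.cysteine_positions)),
            "fwd_primer": a.fwd_primer,
            "rev_primer": a.rev_primer,
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
        path / "amplicons.tsv", sep="\t", index=False
    )

    bc_rows = [
        {"sample_id": s, "amplicon_id": a, "direction": d, "barcode": bc}
        for (s, a, d), bc in sorted(panel.barcode_map.items())
    ]
    pd.DataFrame(bc_rows, columns=["sample_id", "amplicon_id", "direction", "barcode"]
                 ).to_csv(path / "barcodes.tsv", sep="\t", index=False)

    (path / "adaptors.json").write_text(
        json.dumps({"A": panel.adaptor_a, "B": panel.adaptor_b}, indent=0) + "\n"
    )
    return path
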