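"""Bench quantitation utilities: equimolar amplicon pooling and peptide
physico-chemical properties.

``molecules_per_ul`` implements the molecule-count formula used to dilute
each amplicon to a common molarity before emulsion PCR:

    molecules/ul = C[ng/ul] * 1e-9 * N_A / (bp_w * bp)

with bp_w the average mass of one base pair (660 g/mol for dsDNA by
convention) and N_A the Avogadro constant.

``peptide_properties`` computes the mature/precursor peptide descriptors:
average molecular weight, isoelectric point (bisection on the
Henderson-Hasselbalch net-charge function) and hydrophobicity ratio
(percentage of residues in a hydrophobic set).  pKa tables (EMBOSS default,
Bjellqvist selectable) and the hydrophobic set are documented and
configurable rather than asserted to reproduce any published digits, whose
exact definitions are not stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

AVOGADRO = 6.02214076e23  # /mol
DSDNA_BP_WEIGHT = 660.0   # g/mol per base pair


@dataclass(frozen=True)
class PoolingSpec:
    concentration_ng_ul: float
    bp: int
    bp_weight: float = DSDNA_BP_WEIGHT
    avogadro: float = AVOGADRO
    target_molecules_ul: Optional[float] = 7e9

    def __post_init__(self):
        if self.concentration_ng_ul < 0:
            raise ValueError("concentration must be >= 0")
        if self.bp < 1:
            raise ValueError("amplicon length must be >= 1 bp")
        if self.bp_weight <= 0:
            raise ValueError("bp weight must be positive")


@dataclass(frozen=True)
class PoolingResult:
    molecules_per_ul: float
    dilution_factor: Optional[float]  # fold-dilution to reach the target


def molecules_per_ul(spec: PoolingSpec) -> PoolingResult:
    """Molecules per microliter of a dsDNA amplicon, plus the dilution
    factor to the pooling target."""
    n = spec.concentration_ng_ul * 1e-9 * spec.avogadro / (spec.bp_weight * spec.bp)
    dilution = None
    if spec.target_molecules_ul:
        dilution = n / spec.target_molecules_ul
    return PoolingResult(molecules_per_ul=n, dilution_factor=dilution)


# Average residue masses (Da); peptide MW = sum + one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# pKa tables: side chains plus termini.
PKA_TABLES = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")

HYDROPHOBIC_SET = frozenset("ACFILMVW")


def net_charge(peptide: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a (reduced) peptide at given pH."""
    pka = PKA_TABLES[pka_set]
    counts = {aa: peptide.count(aa) for aa in "CDEHKRY"}
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))           # N-terminus
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))          # C-terminus
    for aa in _POSITIVE[1:]:
        charge += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE[1:]:
        charge -= counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(peptide: str, pka_set: str = "emboss",
                      tol: float = 1e-6) -> float:
    """pI by bisection of the monotone net-charge function on pH [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(peptide, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class PeptideProperties:
    length: int
    molecular_weight_da: float
    molecular_weight_kda: float
    isoelectric_point: float
    hydrophobicity_ratio_pct: float


def peptide_properties(peptide: str, pka_set: str = "emboss",
                       hydrophobic_set: frozenset = HYDROPHOBIC_SET
                       ) -> PeptideProperties:
    """MW, pI and hydrophobicity ratio of a peptide (reduced chain)."""
    peptide = peptide.upper()
    bad = sorted(set(peptide) - set(RESIDUE_MASS))
    if bad:
        raise ValueError(f"non-standard residues: {bad}")
    if not peptide:
        raise ValueError("empty peptide")
    mw = sum(RESIDUE_MASS[aa] for aa in peptide) + WATER_MASS
    hydro = 100.0 * sum(1 for aa in peptide if aa in hydrophobic_set) / len(peptide)
    return PeptideProperties(
        length=len(peptide),
        molecular_weight_da=mw,
        molecular_weight_kda=mw / 1000.0,
        isoelectric_point=isoelectric_point(peptide, pka_set),
        hydrophobicity_ratio_pct=hydro,
    )
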