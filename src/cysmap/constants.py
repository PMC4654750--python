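"""Physical constants, isotope tables and residue compositions.

The isotope masses and natural abundances are pinned IUPAC/NIST values of the
early-2010s vintage (CHNOS only — the elements occurring in unmodified
peptides).  Standard atomic weights are derived from the table as
abundance-weighted mean isotope masses, which keeps monoisotopic, average and
isotope-distribution arithmetic mutually consistent; they agree with the CIAAW
conventional atomic weights to better than 1 mDa per atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Mass of the proton (Da); used for m/z <-> neutral-mass conversion under
#: electrospray protonation.
PROTON_MASS = 1.007276467

#: Monoisotopic mass of the hydrogen atom (Da).
H_ATOM_MONO = 1.0078250319

#: Scale factor mapping monoisotopic mass onto the integer (nominal) mass
#: scale for peptides.
NOMINAL_SCALE = 0.9995

#: Mass removed from a peptide species per disulfide bond (two hydrogens).
SS_DECREMENT = 2.0 * H_ATOM_MONO

#: 13C - 12C mass difference (Da); dominant isotopomer spacing of peptides.
C13_C12_SPACING = 1.0033548378

#: Per element: list of (exact isotope mass in Da, natural abundance),
#: sorted by mass ascending.  Abundances sum to 1 per element.
ISOTOPE_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017781, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088989, 0.00364)),
    "O": (
        (15.9949146221, 0.99757),
        (16.9991315000, 0.00038),
        (17.9991604000, 0.00205),
    ),
    "S": (
        (31.9720706900, 0.9499),
        (32.9714585000, 0.0075),
        (33.9678668300, 0.0425),
        (35.9670808800, 0.0001),
    ),
}

#: Standard atomic weights (Da): abundance-weighted mean isotope masses.
AVERAGE_WEIGHTS: dict[str, float] = {
    element: sum(m * a for m, a in isotopes)
    for element, isotopes in ISOTOPE_TABLE.items()
}

#: Monoisotopic mass per element: the lightest (for CHNOS also the most
#: abundant) isotope.
MONOISOTOPIC_WEIGHTS: dict[str, float] = {
    element: isotopes[0][0] for element, isotopes in ISOTOPE_TABLE.items()
}

#: Monoisotopic mass of water (one condensation water per peptide chain).
WATER_MONO = 2 * MONOISOTOPIC_WEIGHTS["H"] + MONOISOTOPIC_WEIGHTS["O"]

#: Elemental composition of the 20 standard amino acid residues
#: (as incorporated in a chain, i.e. minus one water).
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

STANDARD_RESIDUES = frozenset(RESIDUE_COMPOSITIONS)

#: Ambiguity / non-standard one-letter codes that are rejected by the core
#: chemistry layer (the FASTA layer decides whether to skip such entries).
NON_STANDARD_RESIDUES = frozenset("BJOUXZ")


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the physical constants the mass arithmetic relies on."""

    proton_mass: float = PROTON_MASS
    h_atom_mono: float = H_ATOM_MONO
    water_mono: float = WATER_MONO
    nominal_scale: float = NOMINAL_SCALE
    ss_decrement: float = SS_DECREMENT
    isotope_table: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(ISOTOPE_TABLE)
    )
    average_weights: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_WEIGHTS)
    )


CONSTANTS = PhysicalConstants()
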