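"""Elemental-composition arithmetic, masses and isotope distributions.

The core chemistry layer is fail-loud: unknown residues (including the
ambiguity codes B, J, O, U, X, Z) raise :class:`UnknownResidueError` naming the
offending symbol and its position.  Callers that need to tolerate dirty
database exports (the FASTA layer) catch the error and skip.

Isotope distributions are aggregated per *isotopomer*: all isotopologues
sharing one nominal mass are collapsed into a single centroid at their
abundance-weighted mean mass, matching what a 30,000-resolution zoom scan
actually resolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    AVERAGE_WEIGHTS,
    ISOTOPE_TABLE,
    MONOISOTOPIC_WEIGHTS,
    NON_STANDARD_RESIDUES,
    RESIDUE_COMPOSITIONS,
    SS_DECREMENT,
)

# abundance below which trailing isotopomer bins are dropped during
# convolution; small enough that abundances still sum to 1 within 1e-9
_PRUNE_ABUNDANCE = 1e-14


class ChemError(ValueError):
    """Invalid chemical input (composition, residue, species)."""


class UnknownResidueError(ChemError):
    """A sequence contains a symbol outside the 20 standard residues."""


class UnknownElementError(ChemError):
    """A composition references an element absent from the isotope tables."""


class ElementalComposition:
    """Atom counts per chemical element.

    Supports element-wise addition and subtraction; subtraction that would
    produce a negative count raises :class:`ChemError`.
    """

    __slots__ = ("counts",)

    def __init__(self, counts: dict[str, int] | None = None):
        cleaned: dict[str, int] = {}
        for element, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ChemError(f"negative count for element {element!r}: {n}")
            if n:
                cleaned[element] = n
        self.counts = cleaned

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self):
        return iter(sorted(self.counts.items()))

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalComposition) and self.counts == other.counts

    def __hash__(self):
        return hash(tuple(sorted(self.counts.items())))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) - n
            if merged[element] < 0:
                raise ChemError(
                    f"subtraction yields negative count for element {element!r}"
                )
        return ElementalComposition(merged)

    def formula(self) -> str:
        """Hill-order formula string, e.g. ``C2H5NO2``."""
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in order
        )

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula() or 'empty'})"


WATER = ElementalComposition({"H": 2, "O": 1})


@dataclass(frozen=True)
class PeptideSpecies:
    """A neutral peptide molecule: one or two chains plus modifications.

    Parameters
    ----------
    chains : tuple of str
        One or two amino-acid sequences (20 standard one-letter codes).
    c_term_amidated : tuple of bool
        Per-chain C-terminal amidation flag.
    n_disulfides : int
        Number of disulfide bonds (intra- plus inter-chain); each bond
        removes two hydrogens from the composition.
    """

    chains: tuple[str, ...]
    c_term_amidated: tuple[bool, ...] = ()
    n_disulfides: int = 0

    def __post_init__(self):
        chains = tuple(str(c).upper() for c in self.chains)
        object.__setattr__(self, "chains", chains)
        if not 1 <= len(chains) <= 2:
            raise ChemError(f"a species has 1 or 2 chains, got {len(chains)}")
        amid = tuple(self.c_term_amidated) or (False,) * len(chains)
        if len(amid) != len(chains):
            raise ChemError("one amidation flag per chain required")
        object.__setattr__(self, "c_term_amidated", tuple(bool(a) for a in amid))
        for ci, chain in enumerate(chains):
            if not chain:
                raise ChemError(f"chain {ci + 1} is empty")
            for pos, aa in enumerate(chain, start=1):
                if aa not in RESIDUE_COMPOSITIONS:
                    kind = (
                        "ambiguous/non-standard"
                        if aa in NON_STANDARD_RESIDUES
                        else "unknown"
                    )
                    raise UnknownResidueError(
                        f"{kind} residue {aa!r} at chain {ci + 1} position {pos}"
                    )
        if self.n_disulfides < 0:
            raise ChemError("n_disulfides must be non-negative")
        if self.n_cys < 2 * self.n_disulfides:
            raise ChemError(
                f"{self.n_disulfides} disulfide(s) require "
                f"{2 * self.n_disulfides} cysteines, found {self.n_cys}"
            )

    @property
    def n_cys(self) -> int:
        return sum(chain.count("C") for chain in self.chains)

    @property
    def n_met(self) -> int:
        return sum(chain.count("M") for chain in self.chains)

    @property
    def length(self) -> int:
        return sum(len(chain) for chain in self.chains)


@dataclass(frozen=True)
class IsotopeDistribution:
    """Isotopomer envelope: (neutral mass, relative abundance) pairs.

    Peaks are aggregated per nominal-mass bin and sorted by mass ascending;
    the first peak is the monoisotopic species.
    """

    masses: np.ndarray
    abundances: np.ndarray

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.abundances.tolist()))

    def mean_mass(self) -> float:
        """Abundance-weighted mean mass (equals the average mass when the
        distribution is untruncated)."""
        return float(np.average(self.masses, weights=self.abundances))


def composition_of(species: PeptideSpecies) -> ElementalComposition:
    """Elemental composition of a peptide species.

    Sum of residue compositions plus one water per chain; C-terminal
    amidation replaces the terminal -OH with -NH2 (net -O +N +H per flagged
    chain); each disulfide bond removes two hydrogens.
    """
    total = ElementalComposition()
    for chain, amidated in zip(species.chains, species.c_term_amidated):
        comp = ElementalComposition()
        for aa in chain:
            comp = comp + ElementalComposition(RESIDUE_COMPOSITIONS[aa])
        comp = comp + WATER
        if amidated:
            comp = comp - ElementalComposition({"O": 1, "H": 1})
            comp = comp + ElementalComposition({"N": 1, "H": 2})
        total = total + comp
    if species.n_disulfides:
        total = total - ElementalComposition({"H": 2 * species.n_disulfides})
    return total


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass: every atom at its lightest stable isotope."""
    try:
        return sum(n * MONOISOTOPIC_WEIGHTS[e] for e, n in comp.counts.items())
    except KeyError as err:
        raise UnknownElementError(f"no isotope data for element {err.args[0]!r}")


def average_mass(comp: ElementalComposition) -> float:
    """Average mass: sum of standard atomic weights."""
    try:
        return sum(n * AVERAGE_WEIGHTS[e] for e, n in comp.counts.items())
    except KeyError as err:
        raise UnknownElementError(f"no atomic weight for element {err.args[0]!r}")


def _element_base(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom distribution on nominal-shift bins: (abundance, mass)."""
    isotopes = ISOTOPE_TABLE[element]
    mono = isotopes[0][0]
    size = int(round(isotopes[-1][0] - mono)) + 1
    a = np.zeros(size)
    m = np.zeros(size)
    for mass, abundance in isotopes:
        k = int(round(mass - mono))
        a[k] += abundance
        m[k] += mass * abundance
    nz = a > 0
    m[nz] /= a[nz]
    return a, m


def _convolve(a1, m1, a2, m2) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two binned distributions, tracking per-bin mean mass."""
    a = np.convolve(a1, a2)
    w = np.convolve(a1 * m1, a2) + np.convolve(a1, a2 * m2)
    m = np.zeros_like(a)
    nz = a > 0
    m[nz] = w[nz] / a[nz]
    # prune the negligible heavy tail to bound array growth
    keep = np.nonzero(a > _PRUNE_ABUNDANCE)[0]
    if keep.size:
        end = keep[-1] + 1
        a, m = a[:end], m[:end]
    return a, m


def _element_power(element: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n atoms of one element via binary exponentiation."""
    acc_a, acc_m = np.array([1.0]), np.array([0.0])
    base_a, base_m = _element_base(element)
    while n:
        if n & 1:
            acc_a, acc_m = _convolve(acc_a, acc_m, base_a, base_m)
        n >>= 1
        if n:
            base_a, base_m = _convolve(base_a, base_m, base_a, base_m)
    return acc_a, acc_m


def isotope_distribution(
    comp: ElementalComposition, min_abundance: float = 0.0
) -> IsotopeDistribution:
    """Isotopomer distribution of a composition.

    Element-wise convolution of the natural isotopic distributions with fine
    structure collapsed into nominal-mass bins (one centroid per isotopomer at
    the abundance-weighted mean mass).  Peaks below ``min_abundance`` times
    the most abundant peak are removed only after the full distribution has
    been computed.
    """
    if not 0.0 <= min_abundance <= 0.1:
        raise ChemError("min_abundance must lie in [0, 0.1]")
    for element in comp.counts:
        if element not in ISOTOPE_TABLE:
            raise UnknownElementError(f"no isotope data for element {element!r}")
    a, m = np.array([1.0]), np.array([0.0])
    for element, n in comp.counts.items():
        ea, em = _element_power(element, n)
        a, m = _convolve(a, m, ea, em)
    nz = a > 0
    a, m = a[nz], m[nz]
    if min_abundance > 0 and a.size:
        keep = a >= min_abundance * a.max()
        a, m = a[keep], m[keep]
    return IsotopeDistribution(masses=m, abundances=a)


def dimer_mass(chain_a_mass: float, chain_b_mass: float, n_ss: int) -> float:
    """Mass of a disulfide-linked dimer built from two free-chain masses.

    Each bond removes two hydrogen atoms from the sum of the chain masses.
    """
    if n_ss < 1:
        raise ChemError("a linked dimer needs at least one disulfide bond")
    mass = chain_a_mass + chain_b_mass - n_ss * SS_DECREMENT
    if mass < 0:
        raise ChemError("dimer mass would be negative")
    return mass
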