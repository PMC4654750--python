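"""Normalized mass-defect metrics, candidate classification and disulfide
counting.

The two screening coordinates, both dimensionless and reported x1000:

* NMD (normalized nominal mass defect) = 1000 x (mono - nominal) / mono,
  where nominal = nearest integer of 0.9995 x mono.  Sulfur (and acidic
  residues) pull NMD down.
* NIS (normalized isotopic shift) = 1000 x (average - mono) / mono.
  Sulfur pushes NIS up.

Peptides with NMD below ~0.55 and NIS above ~0.65 are likely to contain
cysteines and are flagged for targeted follow-up.

Disulfide counting compares an unreduced species' mass with the mass(es) of
its reduced chain(s): reduction adds two hydrogens per former bond, so the
bond count is the integer n that best explains the observed shift.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .constants import NOMINAL_SCALE, SS_DECREMENT


class MetricError(ValueError):
    """Invalid input to a mass-metric computation."""


def nominal_mass(mono: float) -> int:
    """Nominal (integer) mass: nearest integer of 0.9995 x monoisotopic mass.

    Round-to-nearest (half away from zero), not truncation.
    """
    if mono < 0:
        raise MetricError("monoisotopic mass must be non-negative")
    return int(math.floor(NOMINAL_SCALE * mono + 0.5))


def nis(average: float, mono: float) -> float:
    """Normalized isotopic shift, x1000."""
    if mono <= 0:
        raise MetricError("monoisotopic mass must be positive")
    return 1000.0 * (average - mono) / mono


def nmd(mono: float) -> float:
    """Normalized nominal mass defect, x1000."""
    if mono <= 0:
        raise MetricError("monoisotopic mass must be positive")
    return 1000.0 * (mono - nominal_mass(mono)) / mono


@dataclass
class PeptideRecord:
    """One row of a mass map: masses, screening coordinates and counts.

    ``n_cys``/``n_met``/``n_disulfides`` are ``None`` when unknown
    (experimental records).  ``source`` is ``"theoretical"`` or
    ``"experimental"``.
    """

    label: str
    monoisotopic_mass: float
    average_mass: float
    nominal_mass: int
    nis: float
    nmd: float
    n_cys: int | None = None
    n_met: int | None = None
    n_disulfides: int | None = None
    source: str = "theoretical"
    length: int | None = None
    sequence: str | None = None
    charge_states: tuple[int, ...] = ()
    n_scans: int | None = None
    retention_time: float | None = None
    tic: float | None = None
    candidate: bool | None = None

    @classmethod
    def from_masses(
        cls, label: str, mono: float, average: float, **kwargs
    ) -> "PeptideRecord":
        """Build a record from neutral monoisotopic and average masses,
        deriving nominal mass, NMD and NIS."""
        return cls(
            label=label,
            monoisotopic_mass=mono,
            average_mass=average,
            nominal_mass=nominal_mass(mono),
            nis=nis(average, mono),
            nmd=nmd(mono),
            **kwargs,
        )


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the cysteine-candidate rule (strict inequalities)."""

    nmd_max: float = 0.55
    nis_min: float = 0.65
    combine: str = "and"

    def __post_init__(self):
        if self.nmd_max <= 0 or self.nis_min <= 0:
            raise MetricError("thresholds must be positive")
        if self.combine not in ("and", "or"):
            raise MetricError("combine must be 'and' or 'or'")


DEFAULT_CLASSIFIER = ClassifierConfig()


def classify_candidate(
    rec: PeptideRecord, cfg: ClassifierConfig = DEFAULT_CLASSIFIER
) -> bool:
    """Flag a record as a likely cysteine-containing peptide.

    Strict inequalities: NMD strictly below ``nmd_max`` and/or NIS strictly
    above ``nis_min`` depending on ``cfg.combine``.
    """
    low_nmd = rec.nmd < cfg.nmd_max
    high_nis = rec.nis > cfg.nis_min
    return (low_nmd and high_nis) if cfg.combine == "and" else (low_nmd or high_nis)


@dataclass(frozen=True)
class DisulfideAssignment:
    """A counted disulfide linkage between an unreduced species and its
    reduced chain(s)."""

    unreduced_mass: float
    chain_masses: tuple[float, ...]
    n_bonds: int
    residual: float
    unreduced_label: str | None = None
    chain_labels: tuple[str, ...] = ()


def infer_disulfide_count(
    unreduced: float,
    reduced_chains,
    max_bonds: int = 10,
    tol: float = 0.02,
) -> DisulfideAssignment | None:
    """Count disulfide bonds from an unreduced mass and 1-2 reduced chain
    masses.

    Reduction opens every bond, adding two hydrogens per bond per molecule;
    so sum(reduced chains) - unreduced = n x 2.0156501 Da.  Returns the n in
    1..max_bonds minimizing the residual (ties broken toward smaller n), or
    ``None`` when no n matches within ``tol``.
    """
    if max_bonds < 1:
        raise MetricError("max_bonds must be at least 1")
    if tol <= 0:
        raise MetricError("tol must be positive")
    chains = tuple(float(m) for m in reduced_chains)
    if not 1 <= len(chains) <= 2:
        raise MetricError("reduced_chains must hold 1 or 2 masses")
    shift = sum(chains) - unreduced
    best_n, best_res = None, None
    for n in range(1, max_bonds + 1):
        res = abs(shift - n * SS_DECREMENT)
        if best_res is None or res < best_res:
            best_n, best_res = n, res
    if best_res is None or best_res > tol:
        return None
    return DisulfideAssignment(
        unreduced_mass=unreduced,
        chain_masses=chains,
        n_bonds=best_n,
        residual=best_res,
    )


def _ppm_match(a: float, b: float, ppm: float) -> bool:
    return abs(a - b) <= ppm * 1e-6 * max(a, b)


def match_reduction_pairs(
    unreduced_records,
    reduced_records,
    max_bonds: int = 10,
    tol: float = 0.02,
    ppm_tol: float = 5.0,
) -> list[DisulfideAssignment]:
    """Find disulfide-linked species by comparing unreduced and reduced mass
    tables.

    For every unreduced mass absent from the reduced table (within
    ``ppm_tol``), every single reduced mass and every unordered pair of
    reduced masses (pairs with repetition, covering homodimers) is tested via
    :func:`infer_disulfide_count`.  All matching assignments are returned
    sorted by residual; one unreduced mass may yield several candidates.
    """
    unreduced_records = list(unreduced_records)
    reduced_records = list(reduced_records)
    if not unreduced_records or not reduced_records:
        raise MetricError("both tables must be non-empty")
    assignments: list[DisulfideAssignment] = []
    for urec in unreduced_records:
        umass = urec.monoisotopic_mass
        if any(
            _ppm_match(umass, r.monoisotopic_mass, ppm_tol) for r in reduced_records
        ):
            continue  # still present after reduction: no bond opened
        combos = [(r,) for r in reduced_records]
        combos += list(itertools.combinations_with_replacement(reduced_records, 2))
        for combo in combos:
            hit = infer_disulfide_count(
                umass,
                [r.monoisotopic_mass for r in combo],
                max_bonds=max_bonds,
                tol=tol,
            )
            if hit is not None:
                assignments.append(
                    DisulfideAssignment(
                        unreduced_mass=umass,
                        chain_masses=hit.chain_masses,
                        n_bonds=hit.n_bonds,
                        residual=hit.residual,
                        unreduced_label=urec.label,
                        chain_labels=tuple(r.label for r in combo),
                    )
                )
    assignments.sort(key=lambda a: a.residual)
    return assignments


def best_assignments(
    assignments: list[DisulfideAssignment],
) -> list[DisulfideAssignment]:
    """Keep only the minimum-residual assignment per unreduced mass."""
    best: dict[float, DisulfideAssignment] = {}
    for a in assignments:
        cur = best.get(a.unreduced_mass)
        if cur is None or a.residual < cur.residual:
            best[a.unreduced_mass] = a
    return sorted(best.values(), key=lambda a: a.residual)
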