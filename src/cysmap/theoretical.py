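"""Theoretical mass-map tables from FASTA sequences.

Reads a (possibly gzipped) FASTA export, filters by length, and computes per
entry the monoisotopic / average / nominal mass, NMD, NIS and Cys/Met counts.
Entries with ambiguity codes (B, J, O, U, X, Z) are skipped with a logged
reason — a database screen must keep going — never silently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import chem
from .chem import PeptideSpecies, UnknownResidueError
from .metrics import (
    ClassifierConfig,
    DEFAULT_CLASSIFIER,
    PeptideRecord,
    classify_candidate,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_LENGTH = 34  # "smaller than 35 residues"


@dataclass(frozen=True)
class FastaEntry:
    identifier: str
    sequence: str


def read_fasta(source) -> list[FastaEntry]:
    """Read FASTA entries from a path or open text handle.

    Input order is preserved; sequences are uppercased, whitespace and a
    trailing ``*`` are stripped.  Duplicate identifiers are suffixed
    (``_2``, ``_3``, ...) with a warning.  Gzipped files are detected by the
    ``.gz`` extension.
    """
    close = False
    if isinstance(source, (str, Path)):
        path = Path(source)
        handle = (
            gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")
        )
        close = True
    else:
        handle = source
    entries: list[FastaEntry] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            identifier = rec.description.strip() or rec.id
            seq = "".join(str(rec.seq).split()).upper().rstrip("*")
            n = seen.get(identifier, 0) + 1
            seen[identifier] = n
            if n > 1:
                logger.warning(
                    "duplicate FASTA identifier %r; suffixing _%d", identifier, n
                )
                identifier = f"{identifier}_{n}"
            entries.append(FastaEntry(identifier=identifier, sequence=seq))
    finally:
        if close:
            handle.close()
    return entries


def filter_by_length(
    entries: list[FastaEntry], max_len: int = DEFAULT_MAX_LENGTH
) -> list[FastaEntry]:
    """Keep entries with sequence length <= ``max_len``."""
    if max_len < 1:
        raise ValueError("max_len must be at least 1")
    kept = [e for e in entries if len(e.sequence) <= max_len]
    logger.info(
        "length filter (<= %d): kept %d of %d entries",
        max_len,
        len(kept),
        len(entries),
    )
    return kept


def record_from_species(label: str, species: PeptideSpecies) -> PeptideRecord:
    """Theoretical mass-map record for a fully specified species."""
    comp = chem.composition_of(species)
    return PeptideRecord.from_masses(
        label=label,
        mono=chem.monoisotopic_mass(comp),
        average=chem.average_mass(comp),
        n_cys=species.n_cys,
        n_met=species.n_met,
        n_disulfides=species.n_disulfides,
        source="theoretical",
        length=species.length,
        sequence="-".join(species.chains),
    )


def _species_for_entry(entry: FastaEntry, policy) -> PeptideSpecies:
    if policy == "reduced":
        n_ss = 0
    elif policy == "all-cys-paired":
        n_ss = entry.sequence.count("C") // 2
    elif isinstance(policy, dict):
        n_ss = int(policy.get(entry.identifier, 0))
    else:
        raise ValueError(f"unknown modifications policy {policy!r}")
    return PeptideSpecies(chains=(entry.sequence,), n_disulfides=n_ss)


def build_theoretical_table(
    entries: list[FastaEntry],
    modifications_policy="reduced",
    classifier: ClassifierConfig = DEFAULT_CLASSIFIER,
) -> tuple[list[PeptideRecord], list[tuple[str, str]]]:
    """One record per admissible entry, plus a list of (identifier, reason)
    for skipped entries.

    The default policy treats every entry as fully reduced with free termini
    (bare FASTA carries no disulfide or amidation annotation);
    ``"all-cys-paired"`` pairs all cysteines, or pass a dict mapping
    identifier -> bond count.
    """
    records: list[PeptideRecord] = []
    skipped: list[tuple[str, str]] = []
    for entry in entries:
        try:
            species = _species_for_entry(entry, modifications_policy)
        except UnknownResidueError as err:
            logger.warning("skipping %r: %s", entry.identifier, err)
            skipped.append((entry.identifier, str(err)))
            continue
        records.append(record_from_species(entry.identifier, species))
    for rec in records:
        rec.candidate = classify_candidate(rec, classifier)
    return records, skipped
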