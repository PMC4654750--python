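"""TSV serialization of mass-map tables.

Every output file starts with ``#``-prefixed header lines recording the
package version, the command line and all thresholds in effect, so any table
can be traced back to the parameters that produced it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .metrics import PeptideRecord

BASE_COLUMNS = [
    "identifier",
    "length",
    "n_cys",
    "n_met",
    "monoisotopic_mass",
    "average_mass",
    "nominal_mass",
    "NMD",
    "NIS",
    "candidate_flag",
]
EXPERIMENTAL_COLUMNS = ["charge_states", "n_scans", "retention_time", "tic"]


def records_to_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    rows = []
    experimental = any(r.source == "experimental" for r in records)
    for r in records:
        row = {
            "identifier": r.label,
            "length": r.length if r.length is not None else "NA",
            "n_cys": r.n_cys if r.n_cys is not None else "NA",
            "n_met": r.n_met if r.n_met is not None else "NA",
            "monoisotopic_mass": f"{r.monoisotopic_mass:.6f}",
            "average_mass": f"{r.average_mass:.4f}",
            "nominal_mass": r.nominal_mass,
            "NMD": f"{r.nmd:.4f}",
            "NIS": f"{r.nis:.4f}",
            "candidate_flag": int(bool(r.candidate)) if r.candidate is not None else "NA",
            "source": r.source,
        }
        if experimental:
            row["charge_states"] = (
                ",".join(str(z) for z in r.charge_states) if r.charge_states else "NA"
            )
            row["n_scans"] = r.n_scans if r.n_scans is not None else "NA"
            row["retention_time"] = (
                f"{r.retention_time:.2f}" if r.retention_time is not None else "NA"
            )
            row["tic"] = f"{r.tic:.1f}" if r.tic is not None else "NA"
        rows.append(row)
    columns = BASE_COLUMNS + ["source"] + (
        EXPERIMENTAL_COLUMNS if experimental else []
    )
    return pd.DataFrame(rows, columns=columns)


def write_records(
    path, records: list[PeptideRecord], header_meta: dict | None = None
) -> None:
    """Write records as TSV with a ``#`` provenance header."""
    frame = records_to_frame(records)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cysmap {__version__}\n")
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a mass-map TSV back into a DataFrame (header comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def frame_to_records(frame: pd.DataFrame) -> list[PeptideRecord]:
    """Rebuild records from a mass-map table (for compare/map commands)."""
    records = []
    for _, row in frame.iterrows():
        def _opt_int(key):
            v = row.get(key)
            return int(v) if v is not None and str(v) not in ("NA", "nan") else None

        records.append(
            PeptideRecord(
                label=str(row["identifier"]),
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                average_mass=float(row["average_mass"]),
                nominal_mass=int(row["nominal_mass"]),
                nmd=float(row["NMD"]),
                nis=float(row["NIS"]),
                n_cys=_opt_int("n_cys"),
                n_met=_opt_int("n_met"),
                source=str(row.get("source", "theoretical")),
                candidate=(
                    bool(int(row["candidate_flag"]))
                    if str(row.get("candidate_flag")) not in ("NA", "nan", "None")
                    else None
                ),
            )
        )
    return records
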