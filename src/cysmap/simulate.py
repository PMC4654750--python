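"""Synthetic zoom-scan and run generator with known ground truth.

Emulates the acquisition the pipeline was designed for: multiply charged
peptide precursors (roughly 0.8-8.2 kDa) selected for narrow-window centroid
zoom scans spanning -1.50/+2.25 m/z around the most abundant isotopomer, at a
resolution where isotopomers are resolved but fine structure is not.

The measurement model: isotopomer centroids at (mass + z x proton)/z for all
isotopomers above 1% of the envelope maximum that fall inside the window;
intensities proportional to abundance with multiplicative Gaussian noise
(default CV 5%, folding the instrument's four-microscan averaging into one
term); m/z perturbed by Gaussian jitter (default 2 ppm); a sparse uniform
noise floor (default 5 peaks per scan below 2% of the base peak).  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

import base64
import warnings
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from . import chem
from .chem import PeptideSpecies
from .constants import C13_C12_SPACING, PROTON_MASS
from .metrics import PeptideRecord
from .tables import write_records
from .theoretical import record_from_species
from .zoomscan import ZoomScan

BASE_PEAK_INTENSITY = 1.0e6
SURVEY_WINDOW = (400.0, 1500.0)

#: isotopomers below this fraction of the envelope maximum are not observed
OBSERVABLE_ABUNDANCE = 0.01


@dataclass(frozen=True)
class AcquisitionModel:
    """Noise and window model of the synthetic zoom-scan acquisition."""

    window_low: float = -1.50  # m/z relative to precursor
    window_high: float = 2.25
    mz_jitter_ppm: float = 2.0
    intensity_cv: float = 0.05
    noise_peaks_per_scan: int = 5
    noise_intensity_max: float = 0.02  # fraction of base peak
    seed: int = 0

    def __post_init__(self):
        if not self.window_low < 0 < self.window_high:
            raise ValueError("window must bracket the precursor")
        if min(
            self.mz_jitter_ppm,
            self.intensity_cv,
            self.noise_peaks_per_scan,
            self.noise_intensity_max,
        ) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SimulatedScan:
    """A synthetic zoom scan together with its ground truth."""

    scan: ZoomScan
    species: PeptideSpecies
    charge: int
    truth: PeptideRecord


@dataclass(frozen=True)
class RunEntry:
    """One peptide species scheduled in a synthetic run."""

    species: PeptideSpecies
    label: str
    charges: tuple[int, ...]
    retention_time: float  # seconds
    n_replicates: int = 1


def default_charge(mass: float) -> int:
    """A realistic electrospray charge state for a peptide of given mass
    (keeps m/z within the survey range and the envelope inside the zoom
    window)."""
    return max(2, int(round(mass / 900.0)))


def simulate_zoom_scan(
    species: PeptideSpecies,
    charge: int,
    model: AcquisitionModel = AcquisitionModel(),
    rng: np.random.Generator | None = None,
    scan_id: str = "1",
    retention_time: float = 0.0,
) -> SimulatedScan:
    """Simulate one centroid zoom scan of a species at a given charge."""
    if charge < 1:
        raise ValueError("charge must be at least 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    dist = chem.isotope_distribution(chem.composition_of(species))
    mz = (dist.masses + charge * PROTON_MASS) / charge
    abundance = dist.abundances
    precursor = float(mz[np.argmax(abundance)])
    if C13_C12_SPACING / charge < 8 * model.mz_jitter_ppm * 1e-6 * precursor:
        warnings.warn(
            f"charge {charge}: isotopomer spacing "
            f"{C13_C12_SPACING / charge:.4f} m/z is not resolvable at "
            f"{model.mz_jitter_ppm} ppm jitter",
            stacklevel=2,
        )
    lo, hi = precursor + model.window_low, precursor + model.window_high
    keep = (abundance >= OBSERVABLE_ABUNDANCE * abundance.max()) & (
        (mz >= lo) & (mz <= hi)
    )
    mz, abundance = mz[keep], abundance[keep]
    intensity = (
        abundance
        / abundance.max()
        * BASE_PEAK_INTENSITY
        * np.clip(1.0 + rng.normal(0.0, model.intensity_cv, mz.size), 0.05, None)
    )
    mz_obs = mz * (1.0 + rng.normal(0.0, model.mz_jitter_ppm * 1e-6, mz.size))
    if model.noise_peaks_per_scan:
        noise_mz = rng.uniform(lo, hi, model.noise_peaks_per_scan)
        noise_int = rng.uniform(
            0.0, model.noise_intensity_max * BASE_PEAK_INTENSITY,
            model.noise_peaks_per_scan,
        )
        mz_obs = np.concatenate([mz_obs, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    scan = ZoomScan(
        scan_id=scan_id,
        retention_time=retention_time,
        precursor_mz=precursor,
        mz=mz_obs,
        intensity=intensity,
        window_low=lo,
        window_high=hi,
        precursor_charge=charge,
    )
    truth = record_from_species(f"truth_{scan_id}", species)
    return SimulatedScan(scan=scan, species=species, charge=charge, truth=truth)


def _simulate_scans(entries, model, rng) -> list[SimulatedScan]:
    scans = []
    num = 0
    for entry in entries:
        for z in entry.charges:
            for rep in range(entry.n_replicates):
                num += 1
                sim = simulate_zoom_scan(
                    entry.species,
                    z,
                    model,
                    rng=rng,
                    scan_id=str(num),
                    retention_time=entry.retention_time + 2.0 * rep,
                )
                scans.append(sim)
    return scans


def simulate_run(
    entries: list[RunEntry],
    model: AcquisitionModel = AcquisitionModel(),
    path=None,
    truth_path=None,
    file_format: str = "mzxml",
) -> tuple[Path, list[SimulatedScan]]:
    """Write a synthetic run (surveys interleaved with zoom scans) and its
    ground-truth table.

    Returns the run path and the simulated scans with ground truth.
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    if path is None:
        raise ValueError("an output path is required")
    rng = np.random.default_rng(model.seed)
    sims = _simulate_scans(entries, model, rng)

    xml_scans = []
    num = 0
    for sim in sims:
        scan = sim.scan
        # a survey scan preceding each zoom scan, carrying the precursor
        num += 1
        xml_scans.append(
            {
                "num": num,
                "ms_level": 1,
                "rt": max(scan.retention_time - 1.0, 0.0),
                "low": SURVEY_WINDOW[0],
                "high": SURVEY_WINDOW[1],
                "precursor": None,
                "mz": np.array([scan.precursor_mz]),
                "intensity": np.array([BASE_PEAK_INTENSITY]),
            }
        )
        num += 1
        xml_scans.append(
            {
                "num": num,
                "ms_level": 2,
                "rt": scan.retention_time,
                "low": scan.window_low,
                "high": scan.window_high,
                "precursor": (scan.precursor_mz, sim.charge),
                "mz": scan.mz,
                "intensity": scan.intensity,
            }
        )

    path = Path(path)
    if file_format == "mzxml":
        _write_mzxml(path, xml_scans)
    elif file_format == "mzml":
        _write_mzml(path, xml_scans)
    else:
        raise ValueError(f"unknown file format {file_format!r}")

    if truth_path is not None:
        truth_records = [
            record_from_species(entry.label, entry.species) for entry in entries
        ]
        write_records(
            truth_path,
            truth_records,
            header_meta={"ground_truth_for": str(path), "seed": model.seed},
        )
    return path, sims


def simulate_reduction_experiment(
    species_list: list[tuple[str, PeptideSpecies]],
    model: AcquisitionModel = AcquisitionModel(),
    unreduced_path=None,
    reduced_path=None,
    file_format: str = "mzxml",
):
    """Paired synthetic runs before and after disulfide reduction.

    The unreduced run contains the oxidized species; in the reduced run every
    disulfide is opened (adding two hydrogens per bond) and two-chain species
    fall apart into their free chains.  As in data-dependent acquisition,
    each eluting peptide is zoom-scanned repeatedly and at two adjacent
    charge states; clustering averages the repeats.  Returns the two run
    paths plus the ground-truth bond count per label.
    """
    rt = 120.0
    unreduced_entries: list[RunEntry] = []
    reduced_entries: list[RunEntry] = []
    truth: dict[str, int] = {}
    for label, species in species_list:
        truth[label] = species.n_disulfides
        mono = chem.monoisotopic_mass(chem.composition_of(species))
        z = default_charge(mono)
        unreduced_entries.append(
            RunEntry(
                species=species,
                label=label,
                charges=(z, z + 1),
                retention_time=rt,
                n_replicates=2,
            )
        )
        for ci, (seq, amid) in enumerate(
            zip(species.chains, species.c_term_amidated), start=1
        ):
            chain = PeptideSpecies(
                chains=(seq,), c_term_amidated=(amid,), n_disulfides=0
            )
            cmono = chem.monoisotopic_mass(chem.composition_of(chain))
            cz = default_charge(cmono)
            reduced_entries.append(
                RunEntry(
                    species=chain,
                    label=f"{label}_chain{ci}",
                    charges=(cz, cz + 1),
                    retention_time=rt + 10.0 * ci,
                    n_replicates=2,
                )
            )
        rt += 90.0
    u_path, _ = simulate_run(
        unreduced_entries, model, path=unreduced_path, file_format=file_format
    )
    r_model = AcquisitionModel(
        window_low=model.window_low,
        window_high=model.window_high,
        mz_jitter_ppm=model.mz_jitter_ppm,
        intensity_cv=model.intensity_cv,
        noise_peaks_per_scan=model.noise_peaks_per_scan,
        noise_intensity_max=model.noise_intensity_max,
        seed=model.seed + 1,
    )
    r_path, _ = simulate_run(
        reduced_entries, r_model, path=reduced_path, file_format=file_format
    )
    return u_path, r_path, truth


# ---------------------------------------------------------------------------
# writers


def _encode_peaks_mzxml(mz: np.ndarray, intensity: np.ndarray) -> str:
    pairs = np.empty(2 * mz.size, dtype=">f8")
    pairs[0::2] = mz
    pairs[1::2] = intensity
    return base64.b64encode(pairs.tobytes()).decode("ascii")


def _write_mzxml(path: Path, scans: list[dict]) -> None:
    ns = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        f'<mzXML xmlns="{ns}">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for s in scans:
        tic = float(np.sum(s["intensity"]))
        base_i = int(np.argmax(s["intensity"])) if len(s["intensity"]) else 0
        lines.append(
            f'  <scan num="{s["num"]}" msLevel="{s["ms_level"]}" '
            f'peaksCount="{len(s["mz"])}" centroided="1" '
            f'retentionTime="PT{s["rt"]:.3f}S" '
            f'lowMz="{s["low"]:.4f}" highMz="{s["high"]:.4f}" '
            f'basePeakMz="{float(s["mz"][base_i]):.6f}" '
            f'basePeakIntensity="{float(s["intensity"][base_i]):.2f}" '
            f'totIonCurrent="{tic:.2f}">'
        )
        if s["precursor"] is not None:
            pmz, z = s["precursor"]
            lines.append(
                f'   <precursorMz precursorIntensity="{BASE_PEAK_INTENSITY:.1f}" '
                f'precursorCharge="{z}">{pmz:.6f}</precursorMz>'
            )
        payload = _encode_peaks_mzxml(s["mz"], s["intensity"])
        lines.append(
            '   <peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    path.write_text("\n".join(lines))


def _b64_array(values: np.ndarray, dtype: str) -> str:
    return base64.b64encode(np.asarray(values, dtype=dtype).tobytes()).decode(
        "ascii"
    )


def _cv(accession: str, name: str, value: str = "", unit: str | None = None) -> str:
    extra = ""
    if unit is not None:
        extra = (
            f' unitCvRef="UO" unitAccession="{unit[0]}" unitName="{unit[1]}"'
        )
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{escape(name)}" '
        f'value="{escape(str(value))}"{extra}/>'
    )


def _write_mzml(path: Path, scans: list[dict]) -> None:
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry '
        'Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        '<run id="synthetic_run">',
        f'<spectrumList count="{len(scans)}">',
    ]
    for index, s in enumerate(scans):
        n = len(s["mz"])
        mz_b64 = _b64_array(s["mz"], "<f8")
        int_b64 = _b64_array(s["intensity"], "<f8")
        lines.append(
            f'<spectrum index="{index}" id="scan={s["num"]}" defaultArrayLength="{n}">'
        )
        lines.append(_cv("MS:1000511", "ms level", s["ms_level"]))
        lines.append(_cv("MS:1000127", "centroid spectrum"))
        lines.append('<scanList count="1"><scan>')
        lines.append(
            _cv(
                "MS:1000016",
                "scan start time",
                f"{s['rt']:.3f}",
                unit=("UO:0000010", "second"),
            )
        )
        lines.append('<scanWindowList count="1"><scanWindow>')
        lines.append(
            _cv(
                "MS:1000501",
                "scan window lower limit",
                f"{s['low']:.4f}",
                unit=("MS:1000040", "m/z"),
            )
        )
        lines.append(
            _cv(
                "MS:1000500",
                "scan window upper limit",
                f"{s['high']:.4f}",
                unit=("MS:1000040", "m/z"),
            )
        )
        lines.append("</scanWindow></scanWindowList>")
        lines.append("</scan></scanList>")
        if s["precursor"] is not None:
            pmz, z = s["precursor"]
            lines.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
            )
            lines.append(
                _cv(
                    "MS:1000744",
                    "selected ion m/z",
                    f"{pmz:.6f}",
                    unit=("MS:1000040", "m/z"),
                )
            )
            lines.append(_cv("MS:1000041", "charge state", z))
            lines.append(
                "</selectedIon></selectedIonList></precursor></precursorList>"
            )
        lines.append('<binaryDataArrayList count="2">')
        lines.append(f'<binaryDataArray encodedLength="{len(mz_b64)}">')
        lines.append(_cv("MS:1000523", "64-bit float"))
        lines.append(_cv("MS:1000576", "no compression"))
        lines.append(_cv("MS:1000514", "m/z array", unit=("MS:1000040", "m/z")))
        lines.append(f"<binary>{mz_b64}</binary>")
        lines.append("</binaryDataArray>")
        lines.append(f'<binaryDataArray encodedLength="{len(int_b64)}">')
        lines.append(_cv("MS:1000523", "64-bit float"))
        lines.append(_cv("MS:1000576", "no compression"))
        lines.append(
            _cv(
                "MS:1000515",
                "intensity array",
                unit=("MS:1000131", "number of detector counts"),
            )
        )
        lines.append(f"<binary>{int_b64}</binary>")
        lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>", ""]
    path.write_text("\n".join(lines))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random peptide sequence over the 20 standard residues."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[i] for i in rng.integers(0, 20, size=length))


def random_species(
    rng: np.random.Generator,
    mass_low: float = 800.0,
    mass_high: float = 8200.0,
) -> PeptideSpecies:
    """Random single-chain species with monoisotopic mass in the given range
    (rejection sampling on random sequences)."""
    while True:
        # ~110 Da per residue on average
        target = rng.uniform(mass_low, mass_high)
        length = max(5, int(round(target / 110.0)))
        seq = random_sequence(rng, length)
        species = PeptideSpecies(chains=(seq,))
        mono = chem.monoisotopic_mass(chem.composition_of(species))
        if mass_low <= mono <= mass_high:
            return species
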