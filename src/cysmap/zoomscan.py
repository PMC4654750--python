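"""Experimental mass determination from narrow-window zoom scans.

A zoom scan is a high-resolution centroid scan acquired in a small m/z window
around a selected multiply charged precursor (here -1.50/+2.25 m/z), wide
enough to contain the precursor's whole isotopomer envelope.  The pipeline:

1. extract zoom scans from an mzXML/mzML run (narrow window + precursor),
2. discard poor-quality scans (low total ion current),
3. remove noise peaks below 3% of the most abundant peak,
4. find the isotopomer series and its charge from peak spacings,
5. neutral monoisotopic mass from the lowest-m/z series member, neutral
   average mass as the intensity-weighted mean m/z of the series,
6. NMD/NIS per record, then single-linkage clustering of repeat observations
   of the same peptide across scans and charge states.

Per-scan failures are logged and skipped; only an unreadable file is fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .constants import C13_C12_SPACING, PROTON_MASS
from .metrics import PeptideRecord, nis as _nis, nmd as _nmd

logger = logging.getLogger(__name__)


class ScanError(ValueError):
    """A scan cannot be processed (empty, chimeric, no consistent series)."""


class RunError(ValueError):
    """A run file cannot be read."""


@dataclass
class ZoomScan:
    """Centroid peak list of one zoom scan with acquisition metadata."""

    scan_id: str
    retention_time: float  # seconds
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    window_low: float  # acquired m/z bounds
    window_high: float
    precursor_charge: int | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ScanError(f"scan {self.scan_id}: negative intensity")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class IsotopomerSeries:
    """Consecutive isotopomer peaks of one charge state."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int
    base_peak_index: int  # index of the most intense member
    spacing_rmsd: float

    def __post_init__(self):
        if self.mz.size < 2:
            raise ScanError("an isotopomer series needs at least 2 members")
        if self.charge < 1:
            raise ScanError("charge must be at least 1")


@dataclass(frozen=True)
class PeptideObservation:
    """Per-scan experimental result: neutral masses and map coordinates."""

    neutral_monoisotopic: float
    neutral_average: float
    charge: int
    nis: float
    nmd: float
    scan_id: str
    retention_time: float
    tic: float
    n_isotopomers: int
    spacing_rmsd: float


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the zoom-scan pipeline."""

    max_window_width: float = 5.0  # m/z; wider scans are surveys
    min_tic: float = 1e4  # arbitrary units
    rel_noise: float = 0.03  # fraction of base peak
    max_charge: int = 12
    spacing_tol: float = 0.01  # m/z
    ppm_tol: float = 5.0  # clustering, mass dimension
    rt_tol: float = 60.0  # clustering, seconds


def _read_mzxml(path) -> list[dict]:
    from pyteomics import mzxml

    spectra = []
    with mzxml.read(str(path)) as reader:
        for scan in reader:
            rt = scan.get("retentionTime")
            rt_s = float(rt) * 60.0 if rt is not None else 0.0  # minutes -> s
            prec_list = scan.get("precursorMz") or []
            precursor = None
            charge = None
            if prec_list:
                precursor = float(prec_list[0]["precursorMz"])
                charge = prec_list[0].get("precursorCharge")
            mz = np.asarray(scan.get("m/z array", []), dtype=float)
            spectra.append(
                {
                    "id": str(scan.get("num", scan.get("id", ""))),
                    "rt": rt_s,
                    "low": float(scan.get("lowMz", mz.min() if mz.size else 0.0)),
                    "high": float(scan.get("highMz", mz.max() if mz.size else 0.0)),
                    "precursor": precursor,
                    "charge": int(charge) if charge is not None else None,
                    "mz": mz,
                    "intensity": np.asarray(
                        scan.get("intensity array", []), dtype=float
                    ),
                    "centroided": scan.get("centroided"),
                }
            )
    return spectra


def _decode_mzml_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray> (float32/64, zlib or none)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession"): cv.get("value", "")
        for cv in bda.iter("{*}cvParam")
    }
    binary = bda.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path) -> list[dict]:
    """Minimal mzML reader for centroid MS runs (plain or indexed).

    pyteomics' mzML parser needs the optional ``psims`` package, so the small
    subset this pipeline requires — ms level, centroid/profile flag, scan
    start time, scan window, selected ion m/z + charge and the two binary
    arrays — is read directly with lxml.  Namespace handling uses ``{*}``
    wildcards, so indexedmzML wrappers are transparent.
    """
    from lxml import etree

    spectra = []
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spectrum.iter("{*}cvParam")
        }

        def _value(accession, default=None):
            cv = params.get(accession)
            return cv.get("value") if cv is not None else default

        rt = 0.0
        scan = spectrum.find("{*}scanList/{*}scan")
        if scan is not None:
            for cv in scan.iter("{*}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt *= 60.0
        mz = np.array([])
        intensity = np.array([])
        for bda in spectrum.iter("{*}binaryDataArray"):
            acc = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
            if "MS:1000514" in acc:
                mz = _decode_mzml_array(bda)
            elif "MS:1000515" in acc:
                intensity = _decode_mzml_array(bda)
        low = _value("MS:1000501")
        high = _value("MS:1000500")
        centroided = None
        if "MS:1000127" in params:
            centroided = True
        elif "MS:1000128" in params:
            centroided = False
        charge = _value("MS:1000041")
        spectra.append(
            {
                "id": str(spectrum.get("id", spectrum.get("index", ""))),
                "rt": rt,
                "low": float(low) if low is not None else (mz.min() if mz.size else 0.0),
                "high": float(high) if high is not None else (mz.max() if mz.size else 0.0),
                "precursor": (
                    float(_value("MS:1000744"))
                    if "MS:1000744" in params
                    else None
                ),
                "charge": int(charge) if charge is not None else None,
                "mz": mz,
                "intensity": intensity,
                "centroided": centroided,
            }
        )
        spectrum.clear()
    return spectra


def _read_run(path) -> list[dict]:
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".mzxml":
            return _read_mzxml(path)
        if suffix == ".mzml":
            return _read_mzml(path)
        raise RunError(f"unsupported run format {suffix!r} (need mzXML or mzML)")
    except RunError:
        raise
    except Exception as err:  # unreadable / malformed file is fatal
        raise RunError(f"cannot read run {path}: {err}") from err


def extract_zoom_scans(path, max_window_width: float = 5.0) -> list[ZoomScan]:
    """Select the zoom scans of a run, in acquisition order.

    A scan qualifies when its acquired m/z window spans at most
    ``max_window_width`` and it carries a precursor/target m/z.  Profile-mode
    zoom scans are rejected with a message (centroiding is out of scope);
    narrow scans missing a precursor annotation are skipped and logged.
    """
    scans: list[ZoomScan] = []
    for spec in _read_run(path):
        width = spec["high"] - spec["low"]
        if width > max_window_width:
            continue  # survey scan
        if spec["precursor"] is None:
            logger.warning(
                "scan %s: narrow window but no precursor annotation; skipped",
                spec["id"],
            )
            continue
        if spec["centroided"] is False:
            logger.error(
                "scan %s: profile-mode zoom scan rejected (centroid data required)",
                spec["id"],
            )
            continue
        scans.append(
            ZoomScan(
                scan_id=spec["id"],
                retention_time=spec["rt"],
                precursor_mz=spec["precursor"],
                mz=spec["mz"],
                intensity=spec["intensity"],
                window_low=spec["low"],
                window_high=spec["high"],
                precursor_charge=spec["charge"],
            )
        )
    return scans


def quality_filter(scans: list[ZoomScan], min_tic: float = 1e4) -> list[ZoomScan]:
    """Discard poor-quality scans indicated by a low total ion current."""
    if min_tic < 0:
        raise ValueError("min_tic must be non-negative")
    kept = [s for s in scans if s.tic >= min_tic]
    if scans and not kept:
        logger.warning("all %d zoom scans below min_tic %.3g", len(scans), min_tic)
    return kept


def denoise(scan: ZoomScan, rel_threshold: float = 0.03) -> ZoomScan:
    """Remove noise peaks below ``rel_threshold`` of the most abundant peak."""
    if scan.n_peaks == 0:
        raise ScanError(f"scan {scan.scan_id}: empty scan")
    cutoff = rel_threshold * scan.intensity.max()
    keep = scan.intensity >= cutoff
    return replace(scan, mz=scan.mz[keep], intensity=scan.intensity[keep])


def _longest_chains_for_spacing(
    mz: np.ndarray, d: float, tol: float
) -> list[list[int]]:
    """All maximal-length chains of peaks with consecutive spacing ~ d."""
    n = mz.size
    length = np.ones(n, dtype=int)
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            if abs(mz[i] - mz[j] - d) <= tol and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                prev[i] = j
    best = int(length.max())
    chains = []
    for i in np.nonzero(length == best)[0]:
        chain = []
        k = int(i)
        while k != -1:
            chain.append(k)
            k = int(prev[k])
        chains.append(chain[::-1])
    return chains


def find_series_and_charge(
    scan: ZoomScan, max_charge: int = 12, spacing_tol: float = 0.01
) -> IsotopomerSeries:
    """Locate the isotopomer series of a denoised scan and determine its
    charge from the peak spacings.

    The longest run of peaks with mutually consistent adjacent spacings is
    selected (ties broken toward the run containing the most intense peak);
    the charge is the z in 1..max_charge minimizing the summed absolute
    deviation of the run's spacings from 1.0033548/z.  The run must contain
    the scan's base peak, otherwise the scan is rejected as chimeric.
    """
    if scan.n_peaks < 2:
        raise ScanError(f"scan {scan.scan_id}: need at least 2 peaks")
    mz, intensity = scan.mz, scan.intensity
    base_idx = int(np.argmax(intensity))

    candidates: list[list[int]] = []
    for z in range(1, max_charge + 1):
        d = C13_C12_SPACING / z
        candidates.extend(_longest_chains_for_spacing(mz, d, spacing_tol))
    candidates = [c for c in candidates if len(c) >= 2]
    if not candidates:
        raise ScanError(
            f"scan {scan.scan_id}: no consistent isotopomer series found"
        )
    best_len = max(len(c) for c in candidates)
    finalists = [c for c in candidates if len(c) == best_len]
    # tie-break toward the run containing the most intense peak, then by
    # summed intensity for determinism
    finalists.sort(
        key=lambda c: (base_idx in c, float(intensity[c].sum())), reverse=True
    )
    run = finalists[0]
    if base_idx not in run:
        raise ScanError(
            f"scan {scan.scan_id}: most intense peak outside the series "
            "(chimeric scan)"
        )
    spacings = np.diff(mz[run])
    residuals = [
        float(np.abs(spacings - C13_C12_SPACING / z).sum())
        for z in range(1, max_charge + 1)
    ]
    charge = int(np.argmin(residuals)) + 1
    dev = np.abs(spacings - C13_C12_SPACING / charge)
    if dev.max() > spacing_tol:
        raise ScanError(
            f"scan {scan.scan_id}: best charge {charge} leaves spacing residual "
            f"{dev.max():.4f} above tolerance {spacing_tol}"
        )
    member_int = intensity[run]
    return IsotopomerSeries(
        mz=mz[run],
        intensity=member_int,
        charge=charge,
        base_peak_index=int(np.argmax(member_int)),
        spacing_rmsd=float(np.sqrt(np.mean(dev**2))),
    )


def monoisotopic_from_series(series: IsotopomerSeries) -> float:
    """Neutral monoisotopic mass: lowest-m/z series member, deprotonated."""
    return series.charge * (float(series.mz[0]) - PROTON_MASS)


def average_from_series(series: IsotopomerSeries) -> float:
    """Neutral average mass: intensity-weighted mean m/z of the series,
    deprotonated.  The weights are the centroid peak intensities of all
    isotopomers that survived the noise cutoff."""
    total = float(series.intensity.sum())
    if total <= 0:
        raise ScanError("series has zero total intensity")
    weighted_mz = float(np.dot(series.mz, series.intensity)) / total
    return series.charge * (weighted_mz - PROTON_MASS)


def observation_from_scan(
    scan: ZoomScan, config: PipelineConfig = PipelineConfig()
) -> PeptideObservation:
    """Denoise one zoom scan and measure its peptide."""
    clean = denoise(scan, config.rel_noise)
    series = find_series_and_charge(clean, config.max_charge, config.spacing_tol)
    mono = monoisotopic_from_series(series)
    avg = average_from_series(series)
    return PeptideObservation(
        neutral_monoisotopic=mono,
        neutral_average=avg,
        charge=series.charge,
        nis=_nis(avg, mono),
        nmd=_nmd(mono),
        scan_id=scan.scan_id,
        retention_time=scan.retention_time,
        tic=scan.tic,
        n_isotopomers=int(series.mz.size),
        spacing_rmsd=series.spacing_rmsd,
    )


def process_run(
    path, config: PipelineConfig = PipelineConfig()
) -> tuple[list[PeptideObservation], list[tuple[str, str]]]:
    """Run the full zoom-scan pipeline on an mzXML/mzML file.

    Returns (observations, failures); per-scan failures are logged and
    collected, never fatal.
    """
    scans = extract_zoom_scans(path, config.max_window_width)
    scans = quality_filter(scans, config.min_tic)
    observations: list[PeptideObservation] = []
    failures: list[tuple[str, str]] = []
    for scan in scans:
        try:
            observations.append(observation_from_scan(scan, config))
        except ScanError as err:
            logger.warning("scan %s failed: %s", scan.scan_id, err)
            failures.append((scan.scan_id, str(err)))
    if not observations:
        logger.warning("run %s produced no usable observations", path)
    return observations, failures


def cluster_observations(
    observations: list[PeptideObservation],
    ppm_tol: float = 5.0,
    rt_tol: float = 60.0,
) -> list[PeptideRecord]:
    """Group repeat observations of one peptide into consensus records.

    Single-linkage on neutral monoisotopic mass (within ``ppm_tol``) and
    retention time (within ``rt_tol`` seconds); consensus masses are
    TIC-weighted means over members.
    """
    n = len(observations)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    order = sorted(range(n), key=lambda i: observations[i].neutral_monoisotopic)
    for a in range(n):
        i = order[a]
        oi = observations[i]
        for b in range(a + 1, n):
            j = order[b]
            oj = observations[j]
            if not _within_ppm(
                oi.neutral_monoisotopic, oj.neutral_monoisotopic, ppm_tol
            ):
                break  # sorted by mass: no later member can match either
            if abs(oi.retention_time - oj.retention_time) <= rt_tol:
                union(i, j)
    groups: dict[int, list[PeptideObservation]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(observations[i])
    records = []
    for members in groups.values():
        weights = np.array([m.tic for m in members])
        if weights.sum() <= 0:
            weights = np.ones(len(members))
        mono = float(
            np.average([m.neutral_monoisotopic for m in members], weights=weights)
        )
        avg = float(
            np.average([m.neutral_average for m in members], weights=weights)
        )
        first = min(members, key=lambda m: m.retention_time)
        rec = PeptideRecord.from_masses(
            label=f"cluster_{first.scan_id}",
            mono=mono,
            average=avg,
            source="experimental",
            charge_states=tuple(sorted({m.charge for m in members})),
            n_scans=len(members),
            retention_time=first.retention_time,
            tic=float(weights.sum()),
        )
        records.append(rec)
    records.sort(key=lambda r: r.monoisotopic_mass)
    return records


def _within_ppm(a: float, b: float, ppm: float) -> bool:
    return abs(a - b) <= ppm * 1e-6 * max(a, b)
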