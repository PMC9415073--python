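"""MS/MS spectrum input and neutral precursor mass.

MGF and mzXML are parsed through pyteomics. The tool processes a single
compound–spectrum pair per run, so multi-scan files need an explicit scan
selector. Negative-mode spectra are rejected: the adduct model is cationic
(H+, Na+, K+).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import mzxml as _mzxml

from .errors import SpectrumParseError, ParameterError
from .masses import cation_mass


@dataclass
class Spectrum:
    """Centroided peak list with precursor information.

    Peaks are sorted by ascending m/z on construction; zero-intensity peaks
    and duplicate m/z values are retained.
    """

    peaks: list[tuple[float, float]]  # (mz Da, intensity)
    precursor_mz: float
    charge: int = 1
    scan_id: str = ""
    source_file: str = ""
    ground_truth: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        for mz, inten in self.peaks:
            if not (math.isfinite(mz) and math.isfinite(inten)):
                raise SpectrumParseError("spectrum contains NaN/inf peak values")
            if mz <= 0 or inten < 0:
                raise SpectrumParseError(
                    f"invalid peak (mz={mz}, intensity={inten}): "
                    "m/z must be > 0 and intensity >= 0"
                )
        if not math.isfinite(self.precursor_mz) or self.precursor_mz <= 0:
            raise SpectrumParseError(f"invalid precursor m/z: {self.precursor_mz}")
        if self.charge < 1:
            raise SpectrumParseError(
                f"invalid charge {self.charge}: only positive-mode spectra with "
                "charge >= 1 are supported"
            )
        self.peaks = sorted(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)


def _to_spectrum(mz, intensity, precursor_mz, charge, scan_id, source) -> Spectrum:
    if precursor_mz is None:
        raise SpectrumParseError(f"{source}: no precursor m/z found for scan {scan_id!r}")
    if charge is None:
        warnings.warn(
            f"{source}: scan {scan_id!r} has no charge; assuming 1+", stacklevel=3
        )
        charge = 1
    peaks = [(float(m), float(i)) for m, i in zip(mz, intensity)]
    return Spectrum(
        peaks=peaks,
        precursor_mz=float(precursor_mz),
        charge=int(charge),
        scan_id=str(scan_id),
        source_file=source,
    )


def parse_mgf(text: str, scan_selector=None, source: str = "mgf") -> Spectrum:
    """Parse one spectrum out of MGF content.

    *scan_selector* is a 0-based block index or a TITLE string; it is
    required when the file holds more than one BEGIN IONS block. CHARGE
    "2+" parses to 2; a missing CHARGE defaults to 1 with a warning; peak
    lines without an intensity column default to intensity 1.0.
    """
    if "BEGIN IONS" not in text:
        raise SpectrumParseError(f"{source}: no BEGIN IONS block found")
    text = _default_missing_intensities(text)
    try:
        with _mgf.MGF(io.StringIO(text)) as reader:
            entries = list(reader)
    except Exception as exc:
        raise SpectrumParseError(f"{source}: MGF parsing failed: {exc}") from exc
    if not entries:
        raise SpectrumParseError(f"{source}: no spectra parsed from MGF")

    titles = [e["params"].get("title", f"scan {i}") for i, e in enumerate(entries)]
    if scan_selector is None:
        if len(entries) > 1:
            raise SpectrumParseError(
                f"{source}: file holds {len(entries)} spectra but this tool "
                "processes one compound-spectrum pair per run; select one with "
                f"a scan index or title (available: {titles})"
            )
        entry = entries[0]
        idx = 0
    elif isinstance(scan_selector, int) or str(scan_selector).isdigit():
        idx = int(scan_selector)
        if not 0 <= idx < len(entries):
            raise SpectrumParseError(
                f"{source}: scan index {idx} out of range; available: {titles}"
            )
        entry = entries[idx]
    else:
        matches = [i for i, t in enumerate(titles) if t == scan_selector]
        if not matches:
            raise SpectrumParseError(
                f"{source}: no scan titled {scan_selector!r}; available: {titles}"
            )
        idx = matches[0]
        entry = entries[idx]

    params = entry["params"]
    pepmass = params.get("pepmass")
    precursor_mz = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
    charge_field = params.get("charge")
    charge = None
    if charge_field:
        c = int(charge_field[0])
        if c < 0:
            raise SpectrumParseError(
                f"{source}: negative charge {c}; only positive mode is supported"
            )
        charge = c
    mz = np.asarray(entry["m/z array"], dtype=float)
    inten = np.asarray(entry["intensity array"], dtype=float)
    inten = np.where(np.isnan(inten), 1.0, inten)
    return _to_spectrum(mz, inten, precursor_mz, charge, titles[idx], source)


def _default_missing_intensities(text: str) -> str:
    """Give m/z-only peak lines an explicit intensity of 1.0."""
    out = []
    for line in text.splitlines():
        s = line.strip()
        if s and s[0].isdigit() and "=" not in s and len(s.split()) == 1:
            line = f"{s} 1.0"
        out.append(line)
    return "\n".join(out)


def parse_mzxml(data, scan_selector=None, source: str = "mzxml") -> Spectrum:
    """Parse one MS2 scan out of mzXML content (text or bytes).

    Peak arrays are decoded per the mzXML spec (base64, network byte order,
    32/64-bit, optional zlib) by pyteomics. *scan_selector* is the scan
    number; required when the file has several MS2 scans.
    """
    if isinstance(data, str):
        data = data.encode()
    try:
        with _mzxml.MzXML(io.BytesIO(data)) as reader:
            scans = list(reader)
    except Exception as exc:
        raise SpectrumParseError(f"{source}: mzXML parsing failed: {exc}") from exc

    by_num = {str(s.get("num")): s for s in scans}
    if scan_selector is not None:
        scan = by_num.get(str(scan_selector))
        if scan is None:
            raise SpectrumParseError(
                f"{source}: no scan number {scan_selector}; "
                f"available: {sorted(by_num)}"
            )
        if scan.get("msLevel") != 2:
            raise SpectrumParseError(
                f"{source}: scan {scan_selector} is MS{scan.get('msLevel')}, "
                "not an MS2 scan"
            )
    else:
        ms2 = [s for s in scans if s.get("msLevel") == 2]
        if not ms2:
            raise SpectrumParseError(f"{source}: file contains no MS2 scans")
        if len(ms2) > 1:
            raise SpectrumParseError(
                f"{source}: file holds {len(ms2)} MS2 scans; select one by "
                f"scan number (available: {[s['num'] for s in ms2]})"
            )
        scan = ms2[0]

    prec = scan.get("precursorMz")
    precursor_mz = charge = None
    if prec:
        precursor_mz = prec[0].get("precursorMz")
        charge = prec[0].get("precursorCharge")
    return _to_spectrum(
        scan["m/z array"], scan["intensity array"], precursor_mz, charge,
        scan.get("num", ""), source,
    )


def neutral_precursor_mass(s: Spectrum, adduct: str = "H") -> float:
    """Neutral monoisotopic mass implied by the precursor ion.

    Assumes an [M + z·adduct]^z+ ion: ``z * precursor_mz - z * cation_mass``.
    """
    if s.charge < 1:
        raise ParameterError(f"charge must be >= 1, got {s.charge}")
    return s.charge * s.precursor_mz - s.charge * cation_mass(adduct)
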