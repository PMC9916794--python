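"""Spectrum data model and readers/writers.

Acquisitions are read from mzML or MGF (centroided data only); libraries
are exchanged as NIST-style MSP text and persisted losslessly in a
single-file versioned JSON archive; SRM assays are exported as delimited
transition tables.

Retention times are stored in minutes throughout (LC convention);
collision energies are normalized collision energy (NCE) in eV-equivalent
units; m/z values are serialized with at least 4 decimal places (5 ppm at
m/z 300 is ~0.0015 Da).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .chem_mass import (
    AdductSpec,
    BUILTIN_ADDUCTS,
    ElementCounts,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "Peak",
    "Spectrum",
    "CompoundRecord",
    "LibraryEntry",
    "Library",
    "SpectrumFormatError",
    "LibraryFormatError",
    "read_acquisition",
    "write_mgf",
    "write_msp",
    "read_msp",
    "save_library",
    "load_library",
    "export_transition_table",
    "read_transition_table",
]

POSITIVE = "positive"
NEGATIVE = "negative"

ARCHIVE_VERSION = "1"


class SpectrumFormatError(ValueError):
    """Malformed or unsupported spectral input."""


class LibraryFormatError(ValueError):
    """Malformed library file or version mismatch."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(eq=False)
class Spectrum:
    """One centroided MS1 or MS/MS scan.

    Peaks are kept as parallel ``mz``/``intensity`` arrays, sorted by
    ascending m/z on construction.  MS2 scans carry the precursor m/z and
    (when known) the NCE at which they were acquired.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int
    polarity: str
    nce: float | None = None
    precursor_mz: float | None = None
    retention_time: float | None = None
    scan_range: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError("all m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires precursor_mz")
        if self.ms_level == 1 and self.nce is not None:
            raise ValueError("NCE applies only to MS2 spectra")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self, **overrides) -> "Spectrum":
        kw = dict(
            mz=self.mz.copy(),
            intensity=self.intensity.copy(),
            ms_level=self.ms_level,
            polarity=self.polarity,
            nce=self.nce,
            precursor_mz=self.precursor_mz,
            retention_time=self.retention_time,
            scan_range=self.scan_range,
            source_id=self.source_id,
        )
        kw.update(overrides)
        return Spectrum(**kw)


@dataclass
class CompoundRecord:
    """A catalogued compound: identity, formula, expected adducts per
    polarity, and optional retention time (minutes)."""

    compound_id: str
    name: str
    formula: ElementCounts
    adducts: dict[str, list[AdductSpec]] = field(default_factory=dict)
    retention_time: float | None = None
    monoisotopic_weight: float | None = None

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.formula)
        if self.monoisotopic_weight is None:
            self.monoisotopic_weight = expected
        elif abs(self.monoisotopic_weight - expected) > 1e-6:
            raise ValueError(
                f"{self.compound_id}: cached weight {self.monoisotopic_weight} "
                f"inconsistent with formula ({expected:.6f})"
            )


@dataclass
class LibraryEntry:
    """A compound plus its retained multi-NCE spectra and designated
    quantitation / confirming ions."""

    compound: CompoundRecord
    spectra: list[Spectrum]
    assignments: dict = field(default_factory=dict)  # polarity -> PrecursorAssignment
    quant_ion: float | None = None
    confirming_ions: list[float] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"{self.compound.compound_id}: entry has no spectra")
        if len(self.confirming_ions) > 3:
            raise ValueError("at most 3 confirming ions")

    def spectra_for(self, polarity: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.polarity == polarity]

    def polarities(self) -> list[str]:
        seen: list[str] = []
        for s in self.spectra:
            if s.polarity not in seen:
                seen.append(s.polarity)
        return seen


@dataclass
class Library:
    """A spectral library: entries keyed by compound_id."""

    entries: dict[str, LibraryEntry] = field(default_factory=dict)
    format_version: str = ARCHIVE_VERSION
    metadata: dict = field(default_factory=dict)

    def add(self, entry: LibraryEntry) -> None:
        cid = entry.compound.compound_id
        if cid in self.entries:
            raise ValueError(f"duplicate compound_id: {cid}")
        self.entries[cid] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.entries


# ---------------------------------------------------------------------------
# acquisition reading

def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".mgf":
        return "mgf"
    raise SpectrumFormatError(f"cannot infer acquisition format from {path}")


def read_acquisition(path, format: str | None = None) -> list[Spectrum]:
    """Read centroided spectra from mzML or MGF, order preserved.

    Profile-mode mzML scans and scans without polarity are rejected rather
    than silently coerced.  An empty file is an error, never an empty list.
    """
    fmt = _infer_format(path, format)
    if os.path.getsize(path) == 0:
        raise SpectrumFormatError(f"empty acquisition file: {path}")
    if fmt == "mzml":
        spectra = _read_mzml(path)
    elif fmt == "mgf":
        spectra = _read_mgf(path)
    else:
        raise SpectrumFormatError(f"unsupported acquisition format: {fmt}")
    if not spectra:
        raise SpectrumFormatError(f"no spectra found in {path}")
    return spectra


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(element) -> dict[str, tuple[str, str]]:
    """cvParam name -> (value, unitName) for direct children."""
    out: dict[str, tuple[str, str]] = {}
    for cv in element.findall(f"{_MZML_NS}cvParam"):
        out[cv.get("name")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def _decode_binary_array(element) -> np.ndarray:
    params = _cv_params(element)
    node = element.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path) -> list[Spectrum]:
    """Minimal mzML reader (64/32-bit float arrays, optional zlib).

    Direct XML parsing: the general-purpose mzML machinery in pyteomics
    needs the full PSI controlled vocabulary; this reader extracts just
    the scan metadata the pipeline uses.
    """
    spectra: list[Spectrum] = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumFormatError(f"unreadable mzML file {path}: {exc}") from exc
    for scan in tree.iter(f"{_MZML_NS}spectrum"):
        scan_id = scan.get("id", "?")
        params = _cv_params(scan)
        if "profile spectrum" in params:
            raise SpectrumFormatError(
                f"{path}: profile-mode data; centroid before import (scan {scan_id})"
            )
        if "positive scan" in params:
            polarity = POSITIVE
        elif "negative scan" in params:
            polarity = NEGATIVE
        else:
            raise SpectrumFormatError(f"{path}: scan {scan_id} has no polarity")
        if "ms level" not in params:
            raise SpectrumFormatError(f"{path}: scan {scan_id} has no ms level")
        ms_level = int(params["ms level"][0])
        precursor_mz = None
        nce = None
        if ms_level >= 2:
            ion = scan.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
                f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
            )
            if ion is not None:
                ion_params = _cv_params(ion)
                if "selected ion m/z" in ion_params:
                    precursor_mz = float(ion_params["selected ion m/z"][0])
            activation = scan.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor/{_MZML_NS}activation"
            )
            if activation is not None:
                act_params = _cv_params(activation)
                for key in ("normalized collision energy", "collision energy"):
                    if key in act_params:
                        nce = float(act_params[key][0])
                        break
        rt = None
        scan_range = None
        scan_node = scan.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan_node is not None:
            scan_params = _cv_params(scan_node)
            if "scan start time" in scan_params:
                value, unit = scan_params["scan start time"]
                rt = float(value) / 60.0 if unit in ("second", "seconds") else float(value)
            window = scan_node.find(
                f"{_MZML_NS}scanWindowList/{_MZML_NS}scanWindow"
            )
            if window is not None:
                wp = _cv_params(window)
                lo = wp.get("scan window lower limit")
                hi = wp.get("scan window upper limit")
                if lo and hi:
                    scan_range = (float(lo[0]), float(hi[0]))
        arrays: dict[str, np.ndarray] = {}
        for bda in scan.iter(f"{_MZML_NS}binaryDataArray"):
            bparams = _cv_params(bda)
            if "m/z array" in bparams:
                arrays["mz"] = _decode_binary_array(bda)
            elif "intensity array" in bparams:
                arrays["intensity"] = _decode_binary_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(f"{path}: scan {scan_id} lacks peak arrays")
        spectra.append(
            Spectrum(
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                ms_level=ms_level,
                polarity=polarity,
                nce=nce,
                precursor_mz=precursor_mz,
                retention_time=rt,
                scan_range=scan_range,
                source_id=scan_id,
            )
        )
    return spectra


def _read_mgf(path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block["params"]
            ion_mode = str(params.get("ion_mode", "")).lower()
            if ion_mode in (POSITIVE, NEGATIVE):
                polarity = ion_mode
            elif "charge" in params:
                polarity = POSITIVE if int(params["charge"][0]) > 0 else NEGATIVE
            else:
                raise SpectrumFormatError(
                    f"{path}: MGF block {params.get('title', '?')} has no polarity"
                )
            ms_level = int(params.get("mslevel", 2))
            precursor_mz = None
            if "pepmass" in params and params["pepmass"][0]:
                precursor_mz = float(params["pepmass"][0])
            if ms_level == 1:
                precursor_mz = None
            nce = None
            if ms_level == 2 and "collision_energy" in params:
                nce = float(params["collision_energy"])
            rt = None
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            spectra.append(
                Spectrum(
                    mz=block["m/z array"],
                    intensity=block["intensity array"],
                    ms_level=ms_level,
                    polarity=polarity,
                    nce=nce,
                    precursor_mz=precursor_mz,
                    retention_time=rt,
                    source_id=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF with deterministic key order.

    MS1 scans are written as blocks with ``MSLEVEL=1`` and no PEPMASS;
    polarity travels in ``ION_MODE``.
    """
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.source_id}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
                charge = "1+" if s.polarity == POSITIVE else "1-"
                fh.write(f"CHARGE={charge}\n")
            fh.write(f"MSLEVEL={s.ms_level}\n")
            fh.write(f"ION_MODE={s.polarity}\n")
            if s.nce is not None:
                fh.write(f"COLLISION_ENERGY={s.nce:g}\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time * 60.0:.3f}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.6g}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# MSP

_ION_MODE_CODE = {POSITIVE: "P", NEGATIVE: "N"}
_ION_MODE_NAME = {"P": POSITIVE, "N": NEGATIVE}


def _comment_fields(entry: LibraryEntry, spectrum: Spectrum) -> str:
    assignment = entry.assignments.get(spectrum.polarity)
    parts = [f"compound_id={entry.compound.compound_id}"]
    if assignment is not None:
        parts.append(f"adduct={assignment.adduct.label}")
        parts.append(f"theoretical_mz={assignment.theoretical_mz:.6f}")
        parts.append(f"observed_mz={assignment.observed_mz:.6f}")
        parts.append(f"isotope_score={assignment.isotope_score:.4f}")
    if entry.quant_ion is not None:
        parts.append(f"quant_ion={entry.quant_ion:.4f}")
    if entry.confirming_ions:
        parts.append(
            "confirming_ions=" + ",".join(f"{m:.4f}" for m in entry.confirming_ions)
        )
    if spectrum.source_id:
        parts.append(f"source_id={spectrum.source_id}")
    return " ".join(parts)


def write_msp(library: Library, path) -> None:
    """Write one NIST-style MSP record per retained spectrum.

    Collision_energy is a bare number (NCE in eV-equivalent units);
    intensities are serialized to 6 significant figures, m/z to 4 decimal
    places.
    """
    with open(path, "w") as fh:
        for cid in sorted(library.entries):
            entry = library.entries[cid]
            if not entry.spectra:
                raise LibraryFormatError(f"{cid}: entry has no spectra")
            for s in entry.spectra:
                fh.write(f"Name: {entry.compound.name}\n")
                fh.write(f"Formula: {entry.compound.formula.hill_formula()}\n")
                if s.precursor_mz is not None:
                    fh.write(f"PrecursorMZ: {s.precursor_mz:.4f}\n")
                fh.write(f"Ion_mode: {_ION_MODE_CODE[s.polarity]}\n")
                if s.nce is not None:
                    fh.write(f"Collision_energy: {s.nce:g}\n")
                if s.retention_time is not None:
                    fh.write(f"RetentionTime: {s.retention_time:.3f}\n")
                fh.write(f"Comment: {_comment_fields(entry, s)}\n")
                if entry.provenance:
                    fh.write(f"Provenance: {' | '.join(entry.provenance)}\n")
                fh.write(f"Num Peaks: {s.n_peaks}\n")
                for m, i in zip(s.mz, s.intensity):
                    fh.write(f"{m:.4f}\t{i:.6g}\n")
                fh.write("\n")


def _parse_comment(comment: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in comment.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_msp(path, adducts: dict[str, AdductSpec] | None = None) -> Library:
    """Parse an MSP library written by :func:`write_msp` (or compatible
    NIST-style text) back into a :class:`Library`."""
    from .library_builder import PrecursorAssignment  # local: avoids cycle
    from .chem_mass import ppm_error

    adducts = adducts or BUILTIN_ADDUCTS
    records: list[tuple[dict[str, str], list[tuple[float, float]]]] = []
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expected: int | None = None

    def flush() -> None:
        nonlocal header, peaks, expected
        if not header:
            return
        if expected is None:
            raise LibraryFormatError(
                f"record {header.get('Name', '?')!r}: missing 'Num Peaks'"
            )
        if len(peaks) != expected:
            raise LibraryFormatError(
                f"record {header.get('Name', '?')!r}: 'Num Peaks: {expected}' "
                f"but {len(peaks)} peak lines"
            )
        records.append((header, peaks))
        header, peaks, expected = {}, [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip()
                header[key] = value.strip()
                if key.lower() == "num peaks":
                    expected = int(value)
            else:
                fields = line.replace("\t", " ").split()
                if len(fields) < 2:
                    raise LibraryFormatError(f"bad peak line: {line!r}")
                peaks.append((float(fields[0]), float(fields[1])))
        flush()

    library = Library()
    for header, pk in records:
        comment = _parse_comment(header.get("Comment", ""))
        cid = comment.get("compound_id", header.get("Name", ""))
        polarity = _ION_MODE_NAME.get(header.get("Ion_mode", "P"), POSITIVE)
        nce = float(header["Collision_energy"]) if "Collision_energy" in header else None
        rt = float(header["RetentionTime"]) if "RetentionTime" in header else None
        precursor = float(header["PrecursorMZ"]) if "PrecursorMZ" in header else None
        mzs = [m for m, _ in pk]
        ints = [i for _, i in pk]
        spectrum = Spectrum(
            mz=np.array(mzs),
            intensity=np.array(ints),
            ms_level=2 if precursor is not None else 1,
            polarity=polarity,
            nce=nce,
            precursor_mz=precursor,
            retention_time=rt,
            source_id=comment.get("source_id", ""),
        )
        if cid in library.entries:
            library.entries[cid].spectra.append(spectrum)
        else:
            formula = parse_formula(header["Formula"])
            compound = CompoundRecord(
                compound_id=cid,
                name=header.get("Name", cid),
                formula=formula,
                retention_time=rt,
            )
            entry = LibraryEntry(
                compound=compound,
                spectra=[spectrum],
                quant_ion=float(comment["quant_ion"]) if "quant_ion" in comment else None,
                confirming_ions=[
                    float(x) for x in comment.get("confirming_ions", "").split(",") if x
                ],
                provenance=header["Provenance"].split(" | ")
                if "Provenance" in header
                else [],
            )
            library.add(entry)
        entry = library.entries[cid]
        if "adduct" in comment and polarity not in entry.assignments:
            label = comment["adduct"]
            if label in adducts:
                theo = float(comment.get("theoretical_mz", precursor or 0.0))
                obs = float(comment.get("observed_mz", precursor or theo))
                entry.assignments[polarity] = PrecursorAssignment(
                    compound_id=cid,
                    adduct=adducts[label],
                    theoretical_mz=theo,
                    observed_mz=obs,
                    ppm=ppm_error(obs, theo),
                    isotope_score=float(comment.get("isotope_score", 1.0)),
                )
        if polarity not in entry.compound.adducts and "adduct" in comment:
            label = comment["adduct"]
            if label in adducts:
                entry.compound.adducts[polarity] = [adducts[label]]
    return library


# ---------------------------------------------------------------------------
# native archive (single-file versioned JSON)

def _spectrum_to_dict(s: Spectrum) -> dict:
    return {
        "mz": [float(x) for x in s.mz],
        "intensity": [float(x) for x in s.intensity],
        "ms_level": s.ms_level,
        "polarity": s.polarity,
        "nce": s.nce,
        "precursor_mz": s.precursor_mz,
        "retention_time": s.retention_time,
        "scan_range": list(s.scan_range) if s.scan_range else None,
        "source_id": s.source_id,
    }


def _spectrum_from_dict(d: dict) -> Spectrum:
    return Spectrum(
        mz=np.array(d["mz"], dtype=float),
        intensity=np.array(d["intensity"], dtype=float),
        ms_level=d["ms_level"],
        polarity=d["polarity"],
        nce=d["nce"],
        precursor_mz=d["precursor_mz"],
        retention_time=d["retention_time"],
        scan_range=tuple(d["scan_range"]) if d.get("scan_range") else None,
        source_id=d.get("source_id", ""),
    )


def save_library(library: Library, path) -> None:
    """Persist a library to a single-file JSON archive (lossless,
    deterministic for fixed content)."""
    doc = {
        "format": "phytospeclib-archive",
        "format_version": ARCHIVE_VERSION,
        "metadata": library.metadata,
        "entries": [],
    }
    for cid in sorted(library.entries):
        entry = library.entries[cid]
        c = entry.compound
        doc["entries"].append(
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "formula": c.formula.hill_formula(),
                "retention_time": c.retention_time,
                "adducts": {
                    pol: [a.label for a in specs] for pol, specs in c.adducts.items()
                },
                "assignments": {
                    pol: {
                        "adduct": a.adduct.label,
                        "theoretical_mz": a.theoretical_mz,
                        "observed_mz": a.observed_mz,
                        "ppm": a.ppm,
                        "isotope_score": a.isotope_score,
                    }
                    for pol, a in entry.assignments.items()
                },
                "quant_ion": entry.quant_ion,
                "confirming_ions": entry.confirming_ions,
                "provenance": entry.provenance,
                "spectra": [_spectrum_to_dict(s) for s in entry.spectra],
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def load_library(path, adducts: dict[str, AdductSpec] | None = None) -> Library:
    from .library_builder import PrecursorAssignment  # local: avoids cycle

    adducts = adducts or BUILTIN_ADDUCTS
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise LibraryFormatError(f"corrupt library file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "phytospeclib-archive":
        raise LibraryFormatError(f"{path} is not a phytospeclib library archive")
    if doc.get("format_version") != ARCHIVE_VERSION:
        raise LibraryFormatError(
            f"{path}: archive version {doc.get('format_version')!r} not supported "
            f"(expected {ARCHIVE_VERSION!r})"
        )
    library = Library(metadata=doc.get("metadata", {}))
    for e in doc["entries"]:
        compound = CompoundRecord(
            compound_id=e["compound_id"],
            name=e["name"],
            formula=parse_formula(e["formula"]),
            adducts={
                pol: [adducts[label] for label in labels if label in adducts]
                for pol, labels in e.get("adducts", {}).items()
            },
            retention_time=e.get("retention_time"),
        )
        assignments = {
            pol: PrecursorAssignment(
                compound_id=e["compound_id"],
                adduct=adducts[a["adduct"]],
                theoretical_mz=a["theoretical_mz"],
                observed_mz=a["observed_mz"],
                ppm=a["ppm"],
                isotope_score=a["isotope_score"],
            )
            for pol, a in e.get("assignments", {}).items()
            if a["adduct"] in adducts
        }
        library.add(
            LibraryEntry(
                compound=compound,
                spectra=[_spectrum_from_dict(d) for d in e["spectra"]],
                assignments=assignments,
                quant_ion=e.get("quant_ion"),
                confirming_ions=list(e.get("confirming_ions", [])),
                provenance=list(e.get("provenance", [])),
            )
        )
    return library


# ---------------------------------------------------------------------------
# transition tables

_TRANSITION_COLUMNS = [
    "compound_id",
    "name",
    "polarity",
    "precursor_mz",
    "product_mz",
    "collision_energy_eV",
    "role",
    "retention_time",
]

_ROLE_PRIORITY = {"quant": 0, "confirm": 1}


def export_transition_table(assay, path) -> None:
    """Write an SRM assay as CSV, rows ordered by compound, role priority
    (quant before confirm), then product m/z."""
    import pandas as pd

    if not assay.transitions:
        raise ValueError("assay has no transitions")
    rows = []
    for t in assay.transitions:
        rows.append(
            {
                "compound_id": t.compound_id,
                "name": t.name,
                "polarity": t.polarity,
                "precursor_mz": f"{t.precursor_mz:.4f}",
                "product_mz": f"{t.product_mz:.4f}",
                "collision_energy_eV": f"{t.collision_energy:g}",
                "role": t.role,
                "retention_time": ""
                if t.retention_time is None
                else f"{t.retention_time:.3f}",
            }
        )
    df = pd.DataFrame(rows, columns=_TRANSITION_COLUMNS)
    df = df.sort_values(
        by=["compound_id", "role", "product_mz"],
        key=lambda col: col.map(_ROLE_PRIORITY) if col.name == "role" else col,
        kind="stable",
    )
    df.to_csv(path, index=False)


def read_transition_table(path):
    """Read a transition CSV back into an Assay."""
    import pandas as pd

    from .srm_designer import Assay, Transition

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transition table missing columns: {missing}")
    transitions = []
    for _, row in df.iterrows():
        transitions.append(
            Transition(
                compound_id=row["compound_id"],
                name=row["name"],
                polarity=row["polarity"],
                precursor_mz=float(row["precursor_mz"]),
                product_mz=float(row["product_mz"]),
                collision_energy=float(row["collision_energy_eV"]),
                role=row["role"],
                retention_time=float(row["retention_time"])
                if row["retention_time"]
                else None,
            )
        )
    return Assay(transitions=transitions)
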