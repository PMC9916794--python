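"""Spectral-library construction: the acquisition-to-library decision tree.

For each catalogued compound and each candidate MS/MS scan the builder
(1) assigns a precursor adduct by minimal ppm error against theoretical
accurate mass, optionally checking the MS1 isotope envelope against
theory, (2) applies QC filters (fragment signal-to-noise > 10, at least
three fragment ions, precursor mass accuracy within 5 ppm, molecular
weight below 1500 Da), (3) recalibrates passing spectra multiplicatively
so the precursor lands exactly on its theoretical m/z, (4) scores each
spectrum for library suitability — little residual precursor, product
ions balanced across the mass range — and retains the best spectrum per
polarity, or a few spectra when the best is not clear, and (5) assembles
the library plus an exclusion report for compounds that never produced a
satisfactory spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_mass import (
    AdductSpec,
    IsotopePattern,
    adduct_mz,
    isotope_pattern,
    isotope_similarity,
    ppm_error,
)
from .spectra_io import CompoundRecord, Library, LibraryEntry, Spectrum

__all__ = [
    "PrecursorAssignment",
    "QCThresholds",
    "QCResult",
    "QualityScore",
    "PRECURSOR_WINDOW",
    "DEFAULT_NCE_LADDER",
    "check_inclusion",
    "assign_precursor",
    "estimate_snr",
    "qc_spectrum",
    "recalibrate",
    "spectrum_quality",
    "build_entry",
    "build_library",
]

logger = logging.getLogger(__name__)

#: Half-width (m/z) of the precursor-exclusion window: residual precursor
#: signal inside an isolation window of ~1.3 m/z must not count as a
#: fragment ion.
PRECURSOR_WINDOW = 1.0

#: Default normalized collision energy ladder (eV) used for acquisition.
DEFAULT_NCE_LADDER = (10, 15, 20, 30, 35, 40, 50, 60, 70, 80, 90, 120)

# QC failure codes
LOW_SNR = "LOW_SNR"
FEW_FRAGMENTS = "FEW_FRAGMENTS"
PPM_FAIL = "PPM_FAIL"
ISOTOPE_FAIL = "ISOTOPE_FAIL"
OVERWEIGHT = "OVERWEIGHT"
NO_PRECURSOR = "NO_PRECURSOR"


@dataclass
class PrecursorAssignment:
    """The adduct chosen for a spectrum's precursor and its mass accuracy."""

    compound_id: str
    adduct: AdductSpec
    theoretical_mz: float
    observed_mz: float
    ppm: float
    isotope_score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.isotope_score <= 1.0:
            raise ValueError("isotope_score must be in [0, 1]")


@dataclass
class QCThresholds:
    """Acceptance thresholds for library inclusion.

    ``min_snr`` is a strict bound (S/N must exceed it); ``min_fragments``
    is inclusive (at least three fragment ions).
    """

    min_snr: float = 10.0
    min_fragments: int = 3
    max_precursor_ppm: float = 5.0
    min_isotope_score: float = 0.8
    max_weight: float = 1500.0
    retention_fraction: float = 0.9  # keep spectra with q >= fraction * max q

    def __post_init__(self) -> None:
        for name in ("min_snr", "min_fragments", "max_precursor_ppm",
                     "min_isotope_score", "max_weight", "retention_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCResult:
    passed: bool
    failure_reasons: list[str]
    retained_fragments: list[tuple[float, float]]
    snr_per_peak: np.ndarray

    def __post_init__(self) -> None:
        assert self.passed == (not self.failure_reasons)


@dataclass
class QualityScore:
    """Library-suitability score q = (1 − precursor_fraction) × balance."""

    q: float
    precursor_fraction: float
    balance: float


def check_inclusion(compound: CompoundRecord, thresholds: QCThresholds | None = None) -> bool:
    """Molecular-weight inclusion filter: monoisotopic weight strictly
    below the cap (default 1500 Da)."""
    thresholds = thresholds or QCThresholds()
    return compound.monoisotopic_weight < thresholds.max_weight


def assign_precursor(
    spectrum: Spectrum,
    compound: CompoundRecord,
    ms1: Spectrum | None = None,
    thresholds: QCThresholds | None = None,
) -> PrecursorAssignment | None:
    """Choose, among the compound's expected adducts for the spectrum's
    polarity, the one minimizing |ppm| against the observed precursor.

    Returns None (a NO_PRECURSOR failure) when no adduct falls within the
    precursor ppm tolerance.  When an MS1 scan is supplied the observed
    isotope envelope near the theoretical pattern is scored against
    theory; without MS1 the isotope check is skipped (score 1.0).
    """
    thresholds = thresholds or QCThresholds()
    if spectrum.ms_level != 2:
        raise ValueError("precursor assignment needs an MS2 spectrum")
    candidates = compound.adducts.get(spectrum.polarity, [])
    if not candidates:
        return None
    best: tuple[float, AdductSpec, float] | None = None
    for adduct in candidates:
        theo = adduct_mz(compound.formula, adduct)
        err = ppm_error(spectrum.precursor_mz, theo)
        if best is None or abs(err) < abs(best[0]):
            best = (err, adduct, theo)
    err, adduct, theo = best
    if abs(err) > thresholds.max_precursor_ppm:
        return None
    score = 1.0
    if ms1 is not None:
        score = _ms1_isotope_score(ms1, compound, adduct)
    return PrecursorAssignment(
        compound_id=compound.compound_id,
        adduct=adduct,
        theoretical_mz=theo,
        observed_mz=float(spectrum.precursor_mz),
        ppm=err,
        isotope_score=score,
    )


def _ms1_isotope_score(
    ms1: Spectrum, compound: CompoundRecord, adduct: AdductSpec, mz_tol: float = 0.01
) -> float:
    theo = isotope_pattern(adduct.apply(compound.formula), prune=1e-3)
    observed_ab = np.zeros(theo.mz.size)
    for i, mz_t in enumerate(theo.mz):
        diffs = np.abs(ms1.mz - mz_t)
        j = int(np.argmin(diffs)) if diffs.size else 0
        if diffs.size and diffs[j] <= mz_tol:
            observed_ab[i] = ms1.intensity[j]
    if observed_ab.sum() == 0:
        return 0.0
    obs = IsotopePattern(theo.mz.copy(), np.maximum(observed_ab, 1e-300), theo.charge)
    return isotope_similarity(obs, theo, mz_tol=mz_tol)


def estimate_snr(spectrum: Spectrum) -> np.ndarray:
    """Per-peak signal-to-noise against a robust noise floor.

    The floor is 1.4826 × the median absolute deviation of the
    lowest-intensity half of the peaks (a floor of 1 count when that
    estimate degenerates to zero, e.g. single-peak or uniform spectra).
    """
    if spectrum.n_peaks == 0:
        raise ValueError("cannot estimate S/N of an empty spectrum")
    intensities = np.sort(spectrum.intensity)
    half = intensities[: max(1, intensities.size // 2)]
    mad = np.median(np.abs(half - np.median(half)))
    noise = 1.4826 * mad
    if noise <= 0:
        noise = 1.0
    return spectrum.intensity / noise


def _fragment_mask(spectrum: Spectrum, precursor_mz: float | None) -> np.ndarray:
    """Peaks outside the precursor-exclusion window."""
    if precursor_mz is None:
        return np.ones(spectrum.n_peaks, dtype=bool)
    return np.abs(spectrum.mz - precursor_mz) > PRECURSOR_WINDOW


def qc_spectrum(
    spectrum: Spectrum,
    assignment: PrecursorAssignment | None,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Apply all QC filters, accumulating every failure reason.

    Retained fragments are the peaks with S/N strictly above ``min_snr``
    lying outside the precursor-exclusion window.  Failures are data, not
    exceptions: the decision tree logs them per compound.
    """
    thresholds = thresholds or QCThresholds()
    snr = estimate_snr(spectrum)
    precursor = (
        assignment.observed_mz if assignment is not None else spectrum.precursor_mz
    )
    mask = _fragment_mask(spectrum, precursor) & (snr > thresholds.min_snr)
    retained = [
        (float(m), float(i))
        for m, i in zip(spectrum.mz[mask], spectrum.intensity[mask])
    ]
    reasons: list[str] = []
    if assignment is None:
        reasons.append(NO_PRECURSOR)
    else:
        if abs(assignment.ppm) > thresholds.max_precursor_ppm:
            reasons.append(PPM_FAIL)
        if assignment.isotope_score < thresholds.min_isotope_score:
            reasons.append(ISOTOPE_FAIL)
    fragment_snr = snr[_fragment_mask(spectrum, precursor)]
    if fragment_snr.size == 0 or fragment_snr.max() <= thresholds.min_snr:
        reasons.append(LOW_SNR)
    if len(retained) < thresholds.min_fragments:
        reasons.append(FEW_FRAGMENTS)
    return QCResult(
        passed=not reasons,
        failure_reasons=reasons,
        retained_fragments=retained,
        snr_per_peak=snr,
    )


def recalibrate(spectrum: Spectrum, assignment: PrecursorAssignment) -> Spectrum:
    """Single-point multiplicative recalibration to theoretical accurate
    mass: every m/z is scaled by theoretical/observed so the recalibrated
    precursor ppm error is exactly zero.  The input is not modified."""
    if assignment.observed_mz <= 0:
        raise ValueError("observed precursor m/z must be positive")
    factor = assignment.theoretical_mz / assignment.observed_mz
    out = spectrum.copy(mz=spectrum.mz * factor)
    if out.precursor_mz is not None:
        out.precursor_mz = assignment.theoretical_mz
    return out


def spectrum_quality(
    spectrum: Spectrum,
    assignment: PrecursorAssignment,
    thresholds: QCThresholds | None = None,
) -> QualityScore:
    """Score a QC-passed spectrum for library suitability.

    The ideal spectrum shows little precursor and products balanced
    across the mass range: ``precursor_fraction`` is the intensity share
    inside the precursor-exclusion window, ``balance`` the Shannon
    entropy (base-4-normalized) of retained-fragment intensity over 4
    equal-width m/z bins spanning [lowest fragment m/z, precursor m/z].
    """
    thresholds = thresholds or QCThresholds()
    total = spectrum.intensity.sum()
    if total <= 0:
        raise ValueError("spectrum has no intensity")
    in_window = ~_fragment_mask(spectrum, assignment.observed_mz)
    precursor_fraction = float(spectrum.intensity[in_window].sum() / total)
    snr = estimate_snr(spectrum)
    frag = ~in_window & (snr > thresholds.min_snr)
    if not frag.any():
        raise ValueError("no retained fragments to score")
    fmz = spectrum.mz[frag]
    fint = spectrum.intensity[frag]
    lo = float(fmz.min())
    hi = float(assignment.observed_mz)
    if hi <= lo:
        balance = 0.0
    else:
        idx = np.clip(((fmz - lo) / (hi - lo) * 4).astype(int), 0, 3)
        binned = np.bincount(idx, weights=fint, minlength=4)
        p = binned / binned.sum()
        p = p[p > 0]
        balance = float(-(p * np.log(p)).sum() / np.log(4))
    q = (1.0 - precursor_fraction) * balance
    return QualityScore(q=q, precursor_fraction=precursor_fraction, balance=balance)


@dataclass
class ExclusionRecord:
    compound_id: str
    name: str
    reasons: list[str]


def build_entry(
    compound: CompoundRecord,
    spectra: Sequence[Spectrum],
    thresholds: QCThresholds | None = None,
    ms1_lookup=None,
) -> LibraryEntry | ExclusionRecord:
    """Run the decision tree for one compound over its candidate MS2
    spectra (across NCEs and polarities).

    Per polarity, QC-passing recalibrated spectra are ranked by quality
    q; all spectra with q within ``retention_fraction`` of the best are
    retained ("a few spectra when the best was not clear").  Ties break
    toward more retained fragments, then lower NCE.  If no polarity
    yields a passing spectrum an :class:`ExclusionRecord` aggregating all
    failure reasons is returned.
    """
    thresholds = thresholds or QCThresholds()
    if not spectra:
        raise ValueError(f"{compound.compound_id}: no candidate spectra")
    if not check_inclusion(compound, thresholds):
        return ExclusionRecord(compound.compound_id, compound.name, [OVERWEIGHT])

    reasons: set[str] = set()
    per_polarity: dict[str, list[tuple[QualityScore, int, Spectrum, PrecursorAssignment]]] = {}
    for s in spectra:
        if s.ms_level != 2:
            continue
        ms1 = ms1_lookup(s) if ms1_lookup is not None else None
        assignment = assign_precursor(s, compound, ms1=ms1, thresholds=thresholds)
        qc = qc_spectrum(s, assignment, thresholds)
        if not qc.passed:
            reasons.update(qc.failure_reasons)
            continue
        recal = recalibrate(s, assignment)
        # quality on the recalibrated spectrum; assignment of the
        # recalibrated precursor is exact by construction
        recal_assignment = PrecursorAssignment(
            compound_id=assignment.compound_id,
            adduct=assignment.adduct,
            theoretical_mz=assignment.theoretical_mz,
            observed_mz=assignment.theoretical_mz,
            ppm=0.0,
            isotope_score=assignment.isotope_score,
        )
        quality = spectrum_quality(recal, recal_assignment, thresholds)
        per_polarity.setdefault(s.polarity, []).append(
            (quality, len(qc.retained_fragments), recal, assignment)
        )
    if not per_polarity:
        if not reasons:
            reasons.add(NO_PRECURSOR)
        return ExclusionRecord(compound.compound_id, compound.name, sorted(reasons))

    retained_spectra: list[Spectrum] = []
    assignments: dict[str, PrecursorAssignment] = {}
    provenance: list[str] = []
    for polarity, scored in per_polarity.items():
        best_q = max(qs.q for qs, _, _, _ in scored)
        cutoff = thresholds.retention_fraction * best_q
        keep = [t for t in scored if t[0].q >= cutoff]
        keep.sort(key=lambda t: (-t[0].q, -t[1], t[2].nce if t[2].nce is not None else 0.0))
        retained_spectra.extend(s for _, _, s, _ in keep)
        assignments[polarity] = keep[0][3]
        provenance.append(
            f"{polarity}: retained {len(keep)}/{len(scored)} passing spectra, "
            f"best q={best_q:.3f}"
        )
    return LibraryEntry(
        compound=compound,
        spectra=retained_spectra,
        assignments=assignments,
        provenance=provenance,
    )


def _default_attribution(source_id: str) -> str:
    return source_id.split("|")[0]


def build_library(
    catalogue: Sequence[CompoundRecord],
    acquisitions: Sequence[Spectrum],
    thresholds: QCThresholds | None = None,
    attribution=None,
) -> tuple[Library, pd.DataFrame]:
    """Build the library over a catalogue and its acquisitions.

    Acquisitions are attributed to compounds via ``attribution`` (a
    callable mapping source_id to compound_id; by default the source_id
    prefix before the first ``|``).  MS1 scans from the same source
    prefix, polarity and NCE tag as an MS2 scan serve as its isotope
    check.  Returns the library plus an exclusion report with one row
    per excluded compound; every inclusion-passing catalogued compound
    appears exactly once across the two.
    """
    thresholds = thresholds or QCThresholds()
    attribution = attribution or _default_attribution
    by_id = {c.compound_id: c for c in catalogue}

    ms2_by_compound: dict[str, list[Spectrum]] = {c.compound_id: [] for c in catalogue}
    ms1_index: dict[str, Spectrum] = {}
    ms1_by_compound_pol: dict[tuple[str, str], Spectrum] = {}
    for s in acquisitions:
        cid = attribution(s.source_id)
        if cid not in by_id:
            logger.warning("acquisition %r matches no catalogued compound; skipped",
                           s.source_id)
            continue
        if s.ms_level == 1:
            ms1_index[s.source_id] = s
            ms1_by_compound_pol.setdefault((cid, s.polarity), s)
        else:
            ms2_by_compound[cid].append(s)

    def ms1_lookup(ms2: Spectrum) -> Spectrum | None:
        sibling = ms2.source_id.replace("|ms2", "|ms1")
        if sibling in ms1_index:
            return ms1_index[sibling]
        return ms1_by_compound_pol.get((attribution(ms2.source_id), ms2.polarity))

    library = Library(metadata={"n_catalogue": len(catalogue)})
    excluded: list[ExclusionRecord] = []
    for compound in catalogue:
        if not check_inclusion(compound, thresholds):
            excluded.append(
                ExclusionRecord(compound.compound_id, compound.name, [OVERWEIGHT])
            )
            continue
        candidates = ms2_by_compound[compound.compound_id]
        if not candidates:
            excluded.append(
                ExclusionRecord(compound.compound_id, compound.name, [NO_PRECURSOR])
            )
            continue
        result = build_entry(compound, candidates, thresholds, ms1_lookup=ms1_lookup)
        if isinstance(result, LibraryEntry):
            library.add(result)
        else:
            excluded.append(result)
    report = pd.DataFrame(
        [
            {"compound_id": e.compound_id, "name": e.name, "reasons": ";".join(e.reasons)}
            for e in excluded
        ],
        columns=["compound_id", "name", "reasons"],
    )
    return library, report
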