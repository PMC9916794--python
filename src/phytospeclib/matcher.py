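"""Library-based untargeted metabolite identification.

Candidate library spectra are found by precursor m/z within a ppm
tolerance (polarity-gated), scored with a square-root-intensity weighted
cosine over greedily paired fragments, and filtered to "full matches"
(score, matched-fragment and ppm thresholds).  Identifications from
positive and negative mode are merged with redundancy removal, mirroring
the untargeted annotation funnel: spectral matching against a curated
library yields level-two metabolite annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_mass import ppm_error
from .spectra_io import Library, LibraryEntry, Spectrum

__all__ = [
    "MatchConfig",
    "MatchResult",
    "CompoundAnnotation",
    "candidate_search",
    "match_score",
    "identify",
    "merge_polarities",
]


@dataclass
class MatchConfig:
    """Matching tolerances and thresholds.

    Precursor tolerance is in ppm (high-resolution MS1); fragment
    tolerance in Da, reflecting lower-resolution MS2.  ``full_match_score``
    and the >=3-matched-fragments rule operationalize the "fully matched"
    filter; they are package defaults, not instrument-vendor values.
    """

    precursor_tol_ppm: float = 5.0
    fragment_tol: float = 0.01
    full_match_score: float = 0.8
    intensity_power: float = 0.5
    min_matched_fragments: int = 3

    def __post_init__(self) -> None:
        if min(self.precursor_tol_ppm, self.fragment_tol,
               self.full_match_score, self.intensity_power) <= 0:
            raise ValueError("all MatchConfig values must be positive")
        if self.full_match_score > 1:
            raise ValueError("full_match_score must be <= 1")


@dataclass
class MatchResult:
    query_id: str
    compound_id: str
    best_nce: float | None
    score: float
    matched_fragment_count: int
    precursor_ppm: float
    full_match: bool
    polarity: str


def _entry_precursor_mz(entry: LibraryEntry, spectrum: Spectrum) -> float | None:
    assignment = entry.assignments.get(spectrum.polarity)
    if assignment is not None:
        return assignment.theoretical_mz
    return spectrum.precursor_mz


def candidate_search(
    query: Spectrum, library: Library, config: MatchConfig | None = None
) -> list[tuple[LibraryEntry, Spectrum]]:
    """All library spectra of matching polarity whose precursor m/z lies
    within the precursor ppm tolerance of the query's."""
    config = config or MatchConfig()
    if query.ms_level != 2:
        raise ValueError("candidate search needs an MS2 query")
    out: list[tuple[LibraryEntry, Spectrum]] = []
    for entry in library:
        for s in entry.spectra:
            if s.ms_level != 2 or s.polarity != query.polarity:
                continue
            ref_mz = _entry_precursor_mz(entry, s)
            if ref_mz is None:
                continue
            if abs(ppm_error(query.precursor_mz, ref_mz)) <= config.precursor_tol_ppm:
                out.append((entry, s))
    return out


def _greedy_pairs(
    mz_a: np.ndarray, mz_b: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Pair peaks across two spectra by smallest m/z difference within
    tol, each peak used at most once.  Deterministic and symmetric."""
    cand: list[tuple[float, int, int]] = []
    j0 = 0
    for i, ma in enumerate(mz_a):
        for j, mb in enumerate(mz_b):
            d = abs(ma - mb)
            if d <= tol:
                cand.append((d, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def match_score(
    query: Spectrum, ref: Spectrum, config: MatchConfig | None = None
) -> tuple[float, int]:
    """Weighted cosine similarity between two MS2 spectra.

    Intensities are base-peak normalized and raised to
    ``intensity_power`` (0.5: square-root weighting, damping dominant
    peaks); unmatched peaks contribute zero overlap but still count in
    the vector norms, so extra peaks on either side lower the score.
    Returns (score in [0, 1], number of matched fragment pairs).
    """
    config = config or MatchConfig()
    if query.ms_level != 2 or ref.ms_level != 2:
        raise ValueError("match_score needs MS2 spectra")
    if query.polarity != ref.polarity:
        raise ValueError("cannot match spectra of opposite polarity")
    if query.n_peaks == 0 or ref.n_peaks == 0:
        raise ValueError("cannot score an empty spectrum")
    wq = (query.intensity / query.intensity.max()) ** config.intensity_power
    wr = (ref.intensity / ref.intensity.max()) ** config.intensity_power
    pairs = _greedy_pairs(query.mz, ref.mz, config.fragment_tol)
    overlap = sum(wq[i] * wr[j] for i, j in pairs)
    denom = float(np.linalg.norm(wq) * np.linalg.norm(wr))
    score = float(np.clip(overlap / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return score, len(pairs)


def identify(
    queries: list[Spectrum], library: Library, config: MatchConfig | None = None
) -> list[MatchResult]:
    """Annotate each query with its best-scoring library entry.

    For every query the best (entry, NCE-spectrum) pair over all
    candidates is kept; queries with no candidate yield no result.
    Results are sorted by descending score.
    """
    config = config or MatchConfig()
    if not queries:
        raise ValueError("no query spectra")
    results: list[MatchResult] = []
    for query in queries:
        best: MatchResult | None = None
        for entry, ref in candidate_search(query, library, config):
            score, n_matched = match_score(query, ref, config)
            ppm = ppm_error(query.precursor_mz, _entry_precursor_mz(entry, ref))
            full = (
                score >= config.full_match_score
                and n_matched >= config.min_matched_fragments
                and abs(ppm) <= config.precursor_tol_ppm
            )
            result = MatchResult(
                query_id=query.source_id,
                compound_id=entry.compound.compound_id,
                best_nce=ref.nce,
                score=score,
                matched_fragment_count=n_matched,
                precursor_ppm=ppm,
                full_match=full,
                polarity=query.polarity,
            )
            if best is None or result.score > best.score:
                best = result
        if best is not None:
            results.append(best)
    results.sort(key=lambda r: -r.score)
    return results


@dataclass
class CompoundAnnotation:
    """One identified compound, possibly seen in both polarities."""

    compound_id: str
    results: dict[str, MatchResult] = field(default_factory=dict)

    @property
    def best_score(self) -> float:
        return max(r.score for r in self.results.values())

    @property
    def polarities(self) -> list[str]:
        return sorted(self.results)


def merge_polarities(
    results_pos: list[MatchResult], results_neg: list[MatchResult]
) -> list[CompoundAnnotation]:
    """Union of positive- and negative-mode identifications keyed by
    compound, removing redundancy: a compound found in both modes appears
    once, carrying each polarity's best-scoring result."""
    merged: dict[str, CompoundAnnotation] = {}
    for res in list(results_pos) + list(results_neg):
        ann = merged.setdefault(res.compound_id, CompoundAnnotation(res.compound_id))
        prev = ann.results.get(res.polarity)
        if prev is None or res.score > prev.score:
            ann.results[res.polarity] = res
    return sorted(merged.values(), key=lambda a: -a.best_score)
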