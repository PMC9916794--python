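"""Pseudo-targeted SRM method design from a multi-NCE spectral library.

Breakdown curves trace each product ion's response across the collision
energy ladder; the optimal collision energy is the energy maximizing the
response (ties to the lowest energy — gentler fragmentation preferred).
The most intense product ion across energies becomes the quantitation
ion and, ideally, three further ions confirm identity.  A two-transition
targeted assay (quant + best confirming, default collision energy 30 eV
when no breakdown data exist) can be exported for a triple-quadrupole
method, and SRM chromatographic traces are quantified by baseline-
corrected trapezoidal peak areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library_builder import PRECURSOR_WINDOW
from .spectra_io import Library, LibraryEntry, Spectrum

__all__ = [
    "BreakdownCurve",
    "Transition",
    "Assay",
    "DEFAULT_CE",
    "breakdown_curves",
    "optimal_ce",
    "select_transitions",
    "build_targeted_assay",
    "integrate_trace",
]

#: Default collision energy (eV) for targeted SRM when no breakdown data
#: are available.
DEFAULT_CE = 30.0


@dataclass
class BreakdownCurve:
    """A product ion's response as a function of collision energy."""

    product_mz: float
    points: dict[float, float]  # NCE (eV) -> response

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("breakdown curve needs at least 2 energies")
        if any(v < 0 for v in self.points.values()):
            raise ValueError("responses must be non-negative")


@dataclass
class Transition:
    """One SRM transition: precursor -> product at a collision energy."""

    compound_id: str
    polarity: str
    precursor_mz: float
    product_mz: float
    collision_energy: float
    role: str  # "quant" | "confirm"
    name: str = ""
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("quant", "confirm"):
            raise ValueError(f"bad transition role: {self.role!r}")
        if self.product_mz >= self.precursor_mz + 1.0:
            raise ValueError("product m/z must lie below precursor m/z (+1)")
        if self.collision_energy <= 0:
            raise ValueError("collision energy must be positive")


@dataclass
class Assay:
    """A targeted SRM method: exactly one quant transition per compound."""

    transitions: list[Transition]
    per_compound_cap: int | None = None
    default_ce: float = DEFAULT_CE

    def __post_init__(self) -> None:
        by_compound: dict[str, list[Transition]] = {}
        for t in self.transitions:
            by_compound.setdefault(t.compound_id, []).append(t)
        for cid, ts in by_compound.items():
            n_quant = sum(1 for t in ts if t.role == "quant")
            if n_quant != 1:
                raise ValueError(f"{cid}: {n_quant} quant transitions (need exactly 1)")
            if self.per_compound_cap is not None and len(ts) > self.per_compound_cap:
                raise ValueError(f"{cid}: exceeds per-compound transition cap")

    def compounds(self) -> list[str]:
        seen: list[str] = []
        for t in self.transitions:
            if t.compound_id not in seen:
                seen.append(t.compound_id)
        return seen


def _pick_polarity(entry: LibraryEntry, polarity: str | None) -> str:
    if polarity is not None:
        return polarity
    # prefer the polarity with the most distinct NCEs
    best, best_n = None, -1
    for pol in entry.polarities():
        n = len({s.nce for s in entry.spectra_for(pol) if s.ms_level == 2})
        if n > best_n:
            best, best_n = pol, n
    if best is None:
        raise ValueError("entry has no MS2 spectra")
    return best


def breakdown_curves(
    entry: LibraryEntry,
    ions: Sequence[float],
    tol: float = 0.01,
    polarity: str | None = None,
) -> list[BreakdownCurve]:
    """Per requested ion, the response at each available collision
    energy: the intensity of the nearest peak within ``tol``, 0 when the
    ion is absent at that energy."""
    polarity = _pick_polarity(entry, polarity)
    spectra = [s for s in entry.spectra_for(polarity)
               if s.ms_level == 2 and s.nce is not None]
    nces = sorted({s.nce for s in spectra})
    if len(nces) < 2:
        raise ValueError(
            f"{entry.compound.compound_id}: need spectra at >=2 collision "
            f"energies in {polarity} mode, have {len(nces)}"
        )
    by_nce = {}
    for s in spectra:
        by_nce.setdefault(s.nce, s)
    curves: list[BreakdownCurve] = []
    for ion in ions:
        points: dict[float, float] = {}
        for nce in nces:
            s = by_nce[nce]
            if s.n_peaks == 0:
                points[nce] = 0.0
                continue
            j = int(np.argmin(np.abs(s.mz - ion)))
            points[nce] = (
                float(s.intensity[j]) if abs(s.mz[j] - ion) <= tol else 0.0
            )
        curves.append(BreakdownCurve(product_mz=float(ion), points=points))
    return curves


def optimal_ce(curve: BreakdownCurve) -> float:
    """The collision energy with the maximal response, ties broken toward
    the lowest energy.  An ion never observed (all-zero curve) is an
    error."""
    if all(v == 0 for v in curve.points.values()):
        raise ValueError(
            f"ion {curve.product_mz:.4f}: never observed at any collision energy"
        )
    best_ce = min(
        curve.points, key=lambda ce: (-curve.points[ce], ce)
    )
    return float(best_ce)


def _cluster_products(
    spectra: list[Spectrum], precursor_mz: float, tol: float
) -> list[tuple[float, float]]:
    """Union of fragment peaks across NCEs, clustered within tol and
    excluding the precursor window.  Returns (representative m/z, max
    response) per cluster, ranked by response descending."""
    pts: list[tuple[float, float]] = []
    for s in spectra:
        for m, i in zip(s.mz, s.intensity):
            if abs(m - precursor_mz) > PRECURSOR_WINDOW:
                pts.append((float(m), float(i)))
    pts.sort()
    clusters: list[list[tuple[float, float]]] = []
    for m, i in pts:
        if clusters and m - clusters[-1][-1][0] <= tol:
            clusters[-1].append((m, i))
        else:
            clusters.append([(m, i)])
    reps = []
    for cl in clusters:
        best = max(cl, key=lambda p: p[1])
        reps.append((best[0], best[1]))
    reps.sort(key=lambda p: (-p[1], p[0]))
    return reps


def select_transitions(
    entry: LibraryEntry,
    max_confirming: int = 3,
    tol: float = 0.01,
    polarity: str | None = None,
) -> list[Transition]:
    """Choose the quantitation ion and, ideally, ``max_confirming``
    confirming ions for a compound.

    Candidate products are the union of fragments across the retained
    NCE spectra (precursor window excluded), ranked by maximum response
    across energies.  Each transition carries the optimal collision
    energy of its own breakdown curve; with a single-NCE entry all
    transitions fall back to the default 30 eV.
    """
    polarity = _pick_polarity(entry, polarity)
    spectra = [s for s in entry.spectra_for(polarity) if s.ms_level == 2]
    if not spectra:
        raise ValueError(f"{entry.compound.compound_id}: no MS2 spectra")
    assignment = entry.assignments.get(polarity)
    precursor_mz = (
        assignment.theoretical_mz if assignment is not None
        else spectra[0].precursor_mz
    )
    reps = _cluster_products(spectra, precursor_mz, tol)
    if not reps:
        raise ValueError(f"{entry.compound.compound_id}: no candidate product ions")
    chosen = reps[: 1 + max_confirming]
    nces = {s.nce for s in spectra if s.nce is not None}
    multi_nce = len(nces) >= 2
    curves = (
        {c.product_mz: c for c in breakdown_curves(
            entry, [m for m, _ in chosen], tol=tol, polarity=polarity)}
        if multi_nce
        else {}
    )
    transitions: list[Transition] = []
    for rank, (mz, _resp) in enumerate(chosen):
        if multi_nce and mz in curves:
            ce = optimal_ce(curves[mz])
        else:
            ce = DEFAULT_CE
        transitions.append(
            Transition(
                compound_id=entry.compound.compound_id,
                polarity=polarity,
                precursor_mz=float(precursor_mz),
                product_mz=float(mz),
                collision_energy=ce,
                role="quant" if rank == 0 else "confirm",
                name=entry.compound.name,
                retention_time=entry.compound.retention_time,
            )
        )
    return transitions


def build_targeted_assay(
    library: Library,
    targets: Sequence[str],
    per_compound: int = 2,
    default_ce: float = DEFAULT_CE,
    tol: float = 0.01,
) -> Assay:
    """Two-transition targeted assay (quant + best confirming by
    default) for the requested library compounds."""
    if per_compound < 1:
        raise ValueError("per_compound must be >= 1")
    transitions: list[Transition] = []
    for cid in targets:
        if cid not in library:
            raise KeyError(f"target {cid!r} not in library")
        entry = library.entries[cid]
        selected = select_transitions(entry, max_confirming=per_compound - 1, tol=tol)
        transitions.extend(selected[:per_compound])
    return Assay(transitions=transitions, per_compound_cap=per_compound,
                 default_ce=default_ce)


def integrate_trace(
    times: np.ndarray, intensities: np.ndarray
) -> float:
    """Baseline-corrected trapezoidal peak area of an SRM chromatographic
    trace (times in minutes).

    The baseline is the trace median; the apex must exceed 3x the
    baseline noise to qualify (else area 0).  Integration bounds are the
    nearest points on each side of the apex where the trace falls back
    to the baseline, and the baseline rectangle is subtracted.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    if times.size < 5:
        raise ValueError("trace too short to integrate (need >=5 points)")
    baseline = float(np.median(intensities))
    apex = int(np.argmax(intensities))
    if intensities[apex] <= 3 * baseline or intensities[apex] <= 0:
        return 0.0
    left = apex
    while left > 0 and intensities[left - 1] > baseline:
        left -= 1
    right = apex
    while right < intensities.size - 1 and intensities[right + 1] > baseline:
        right += 1
    if right == left:
        return 0.0
    t = times[left : right + 1]
    y = intensities[left : right + 1]
    area = float(np.trapezoid(y, t)) - baseline * float(t[-1] - t[0])
    return max(area, 0.0)
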