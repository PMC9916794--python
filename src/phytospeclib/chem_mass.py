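"""Molecular formula arithmetic for small-molecule mass spectrometry.

Monoisotopic masses, adduct m/z calculation, ppm mass errors, and
theoretical isotope patterns by iterated convolution of per-element
isotope distributions.  These primitives underpin precursor assignment,
spectral recalibration to theoretical accurate mass, and the comparison
of experimental MS1 envelopes with theory.

All charged-species masses are electron-corrected; at m/z < 400 the
electron mass (~0.55 mDa) is comparable to a 5 ppm tolerance and cannot
be neglected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "ElementCounts",
    "AdductSpec",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_pattern",
    "isotope_similarity",
    "BUILTIN_ADDUCTS",
    "load_adducts",
]

#: CODATA electron rest mass in Da.
ELECTRON_MASS = 0.000548579909

# Static IUPAC-derived isotope table: element -> [(mass Da, abundance), ...],
# abundances summing to 1 per element.  Embedded so that all mass arithmetic
# is reproducible offline.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [(15.99491461956, 0.99757), (16.99913170, 0.00038), (17.99916100, 0.00205)],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "Na": [(22.9897692809, 1.0)],
    "K": [(38.96370668, 0.932581), (39.96399848, 0.000117), (40.96182576, 0.067302)],
    "Cl": [(34.96885268, 0.7576), (36.96590259, 0.2424)],
    "F": [(18.99840322, 1.0)],
    "Br": [(78.9183371, 0.5069), (80.9162906, 0.4931)],
    "I": [(126.904473, 1.0)],
    "Si": [(27.97692653, 0.92223), (28.97649470, 0.04685), (29.97377017, 0.03092)],
    "Se": [
        (73.92247644, 0.0089),
        (75.91921367, 0.0937),
        (76.91991400, 0.0763),
        (77.91730909, 0.2377),
        (79.91652176, 0.4961),
        (81.91669940, 0.0873),
    ],
    "B": [(10.0129370, 0.199), (11.0093054, 0.801)],
    "Mg": [(23.98504170, 0.7899), (24.98583692, 0.1000), (25.98259293, 0.1101)],
    "Ca": [
        (39.96259098, 0.96941),
        (41.95861801, 0.00647),
        (42.95876660, 0.00135),
        (43.95548180, 0.02086),
        (45.95369260, 0.00004),
        (47.95253400, 0.00187),
    ],
    "Fe": [
        (53.93961050, 0.05845),
        (55.93493750, 0.91754),
        (56.93539400, 0.02119),
        (57.93327560, 0.00282),
    ],
    "Zn": [
        (63.92914220, 0.48268),
        (65.92603340, 0.27975),
        (66.92712730, 0.04102),
        (67.92484420, 0.19024),
        (69.92531930, 0.00631),
    ],
}

#: element -> mass of its most abundant isotope.
MONOISOTOPIC: dict[str, float] = {
    el: max(iso, key=lambda p: p[1])[0] for el, iso in ISOTOPES.items()
}


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula input."""


@dataclass
class ElementCounts:
    """A molecular formula: element symbol -> count, plus a net charge.

    ``net_charge`` is 0 for neutral molecules and nonzero for intrinsic
    ions (e.g. permanently charged quaternary alkaloids such as
    jatrorrhizine, C20H20NO4+).
    """

    counts: dict[str, int]
    net_charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula has no atoms")
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}")
        if all(n == 0 for n in self.counts.values()):
            raise FormulaError("formula has no atoms")
        self.counts = {el: n for el, n in self.counts.items() if n > 0}

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementCounts(merged, self.net_charge + other.net_charge)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill_formula(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical), with
        trailing charge marks."""
        parts: list[str] = []
        keys = sorted(self.counts)
        if "C" in self.counts:
            ordered = ["C"] + (["H"] if "H" in self.counts else [])
            ordered += [k for k in keys if k not in ("C", "H")]
        else:
            ordered = keys
        for el in ordered:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        sign = "+" if self.net_charge > 0 else "-"
        return "".join(parts) + sign * abs(self.net_charge)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementCounts):
            return NotImplemented
        return self.counts == other.counts and self.net_charge == other.net_charge


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style formula, optionally suffixed with ``+``/``-``
    charge marks (one mark per unit charge).

    >>> parse_formula("C20H20NO4+").net_charge
    1
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    m = re.fullmatch(r"([A-Za-z0-9]+)([+-]*)", text)
    if m is None:
        raise FormulaError(f"malformed formula: {text!r}")
    body, marks = m.groups()
    charge = marks.count("+") - marks.count("-")
    counts: dict[str, int] = {}
    pos = 0
    for tok in _TOKEN.finditer(body):
        if tok.start() != pos:
            raise FormulaError(f"malformed token near {body[pos:]!r} in {text!r}")
        el, digits = tok.groups()
        if not el:
            break
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = tok.end()
    if pos != len(body):
        raise FormulaError(f"malformed token near {body[pos:]!r} in {text!r}")
    return ElementCounts(counts, charge)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses,
    electron-corrected for the net charge."""
    m = sum(MONOISOTOPIC[el] * n for el, n in counts.counts.items())
    return m - counts.net_charge * ELECTRON_MASS


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: element deltas applied to the neutral formula
    and the resulting ion charge.

    ``[M]+`` (identity deltas, charge +1) covers intrinsic cations that
    ionize without gaining or losing atoms.
    """

    label: str
    deltas: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"adduct {self.label!r} has zero charge")
        object.__setattr__(self, "deltas", dict(self.deltas))

    def apply(self, counts: ElementCounts) -> ElementCounts:
        """Element counts of the ion species (charge set to self.charge)."""
        merged = dict(counts.counts)
        for el, d in self.deltas.items():
            merged[el] = merged.get(el, 0) + d
            if merged[el] < 0:
                raise ValueError(
                    f"adduct {self.label} removes more {el} than formula "
                    f"{counts.hill_formula()} contains"
                )
        return ElementCounts(merged, self.charge)


#: Adducts covering an ammonium-formate / formic-acid mobile phase in
#: positive and negative ESI, plus the intrinsic-cation identity adduct.
BUILTIN_ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, 1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, 1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, 1),
    "[M]+": AdductSpec("[M]+", {}, 1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", {"H": 1, "C": 1, "O": 2}, -1),
}


def load_adducts(path) -> dict[str, AdductSpec]:
    """Load user adduct definitions from a plain-text config.

    Each non-comment line: ``label<TAB>deltas<TAB>charge`` where deltas is
    a comma list of ``El:+n`` / ``El:-n`` terms (empty string for none),
    e.g. ``[M+K]+\tK:+1\t+1``.
    """
    adducts = dict(BUILTIN_ADDUCTS)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"bad adduct line: {raw!r}")
            label, delta_s, charge_s = fields
            deltas: dict[str, int] = {}
            if delta_s:
                for term in delta_s.split(","):
                    el, n = term.split(":")
                    deltas[el.strip()] = int(n)
            adducts[label] = AdductSpec(label, deltas, int(charge_s))
    return adducts


def adduct_mz(counts: ElementCounts, adduct: AdductSpec) -> float:
    """m/z of the adduct ion: electron-corrected mass of the modified
    formula divided by absolute charge."""
    ion = adduct.apply(counts)
    atoms_mass = sum(MONOISOTOPIC[el] * n for el, n in ion.counts.items())
    return (atoms_mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class IsotopePattern:
    """A theoretical (or observed) isotope envelope.

    ``mz`` strictly increasing; ``abundance`` as fractions summing to 1
    for freshly computed patterns.  ``charge`` 0 means neutral masses.
    """

    mz: np.ndarray
    abundance: np.ndarray
    charge: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.size == 0:
            raise ValueError("empty isotope pattern")
        if self.mz.size != self.abundance.size:
            raise ValueError("mz / abundance length mismatch")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("pattern m/z must be strictly increasing")

    def base_peak_normalized(self) -> "IsotopePattern":
        return IsotopePattern(self.mz.copy(), self.abundance / self.abundance.max(), self.charge)

    def fractions(self) -> np.ndarray:
        return self.abundance / self.abundance.sum()


_MERGE_WINDOW = 1e-4  # Da; below Orbitrap relevance at R=70,000


def _merge(dist: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge peaks closer than the merge window (abundance-weighted mass)."""
    dist = sorted(dist)
    out: list[tuple[float, float]] = []
    for m, a in dist:
        if out and m - out[-1][0] < _MERGE_WINDOW:
            pm, pa = out[-1]
            tot = pa + a
            out[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            out.append((m, a))
    return out


def _convolve(
    a: list[tuple[float, float]], b: list[tuple[float, float]], prune: float
) -> list[tuple[float, float]]:
    dist = [(ma + mb, aa * ab) for ma, aa in a for mb, ab in b]
    dist = _merge(dist)
    if prune > 0:
        top = max(x for _, x in dist)
        dist = [(m, x) for m, x in dist if x > prune * top]
    return dist


def isotope_pattern(
    counts: ElementCounts, prune: float = 1e-5, charge: int | None = None
) -> IsotopePattern:
    """Theoretical isotope pattern of a formula by iterated convolution.

    Parameters
    ----------
    counts : formula whose envelope to compute.
    prune : relative abundance threshold (fraction of the base peak)
        below which isotopologue peaks are dropped, in (0, 0.1].
    charge : ion charge for the m/z axis; defaults to the formula's net
        charge.  0 yields neutral masses.

    Abundances are renormalized to sum to 1 after pruning.
    """
    if not (0 < prune <= 0.1):
        raise ValueError("prune must be in (0, 0.1]")
    if charge is None:
        charge = counts.net_charge
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for el, n in counts.counts.items():
        if el not in ISOTOPES:
            raise FormulaError(f"no isotope data for element {el}")
        # exponentiation by squaring of the one-atom distribution
        base = list(ISOTOPES[el])
        power = n
        acc: list[tuple[float, float]] | None = None
        while power:
            if power & 1:
                acc = base if acc is None else _convolve(acc, base, prune)
            power >>= 1
            if power:
                base = _convolve(base, base, prune)
        dist = _convolve(dist, acc, prune)
    masses = np.array([m for m, _ in dist])
    ab = np.array([a for _, a in dist])
    ab = ab / ab.sum()
    keep = ab > 0
    masses, ab = masses[keep], ab[keep]
    if charge != 0:
        masses = (masses - charge * ELECTRON_MASS) / abs(charge)
    order = np.argsort(masses)
    return IsotopePattern(masses[order], ab[order], charge)


def isotope_similarity(
    observed: IsotopePattern, theoretical: IsotopePattern, mz_tol: float = 0.01
) -> float:
    """Agreement between two isotope envelopes in [0, 1].

    Both patterns are renormalized to fractional abundances (sum 1); peaks
    are matched across patterns within ``mz_tol`` and the score is one
    minus the total-variation distance: 1 − ½·Σ|obs − theo|, where
    abundance without a partner on either side counts fully as
    discrepancy.  1 iff identical, 0 iff the m/z sets are disjoint.
    """
    obs_f = observed.fractions()
    theo_f = theoretical.fractions()
    used = np.zeros(obs_f.size, dtype=bool)
    d = 0.0
    for mz_t, a_t in zip(theoretical.mz, theo_f):
        diffs = np.abs(observed.mz - mz_t)
        diffs[used] = np.inf
        j = int(np.argmin(diffs))
        if diffs[j] <= mz_tol:
            used[j] = True
            d += abs(obs_f[j] - a_t)
        else:
            d += a_t
    d += obs_f[~used].sum()
    return float(np.clip(1.0 - 0.5 * d, 0.0, 1.0))
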