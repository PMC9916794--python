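"""Synthetic acquisition generator with known ground truth.

Emulates one-compound-at-a-time infusion/LC runs on a high-resolution
instrument: per compound a random small-molecule formula, a set of
product ions whose collision-energy dependence follows a Gaussian
breakdown profile (each ion has a known optimal energy), and an
exponentially decaying residual precursor.  MS1 scans carry the
theoretical isotope envelope of the adduct ion; MS2 scans are produced
across a collision-energy ladder in both polarities with controllable
multiplicative intensity noise, bounded m/z jitter, and low-level
baseline peaks.  Designed QC violations (too few fragments, bad mass
accuracy, low signal-to-noise) can be injected per compound so the
library-building decision tree can be validated against ground truth.

All generators are pure functions of their explicit seeds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_mass import (
    BUILTIN_ADDUCTS,
    ElementCounts,
    adduct_mz,
    isotope_pattern,
    monoisotopic_mass,
)
from .library_builder import DEFAULT_NCE_LADDER
from .spectra_io import NEGATIVE, POSITIVE, CompoundRecord, Spectrum

__all__ = [
    "FragmentModel",
    "SimCompound",
    "NoiseModel",
    "FAIL_MODES",
    "simulate_compound",
    "simulate_batch",
    "simulate_spectrum",
    "simulate_ms1",
    "simulate_acquisition",
    "simulate_query",
    "decoy_spectrum",
    "simulate_srm_trace",
]

FAIL_MODES = ("two_fragments", "bad_ppm", "low_snr")

_POS_ADDUCT = BUILTIN_ADDUCTS["[M+H]+"]
_NEG_ADDUCT = BUILTIN_ADDUCTS["[M-H]-"]


@dataclass
class FragmentModel:
    """A product ion with a Gaussian collision-energy response."""

    product_mz: float
    amplitude: float
    ce_optimum: float
    ce_width: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.ce_width <= 0:
            raise ValueError("amplitude and ce_width must be positive")

    def response(self, nce: float) -> float:
        return self.amplitude * np.exp(
            -((nce - self.ce_optimum) ** 2) / (2 * self.ce_width**2)
        )


@dataclass
class SimCompound:
    """A simulated compound: catalogue record plus fragmentation model."""

    record: CompoundRecord
    fragments: list[FragmentModel]
    precursor_decay: float  # eV scale of residual precursor survival
    fail_mode: str | None = None
    ppm_offset: float = 0.0  # systematic calibration error, ppm

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("simulated compound needs fragments")
        pmz = adduct_mz(self.record.formula, _POS_ADDUCT)
        for f in self.fragments:
            if f.product_mz >= pmz:
                raise ValueError("fragment m/z must lie below the precursor")


@dataclass
class NoiseModel:
    """Acquisition noise: lognormal multiplicative intensity noise with
    coefficient of variation ``multiplicative_cv``, uniform m/z jitter
    bounded by ``mz_jitter_ppm``, and ``baseline_peaks`` random
    low-intensity peaks per scan."""

    multiplicative_cv: float = 0.05
    mz_jitter_ppm: float = 2.0
    baseline_peaks: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.multiplicative_cv, self.mz_jitter_ppm) < 0 or self.baseline_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


def _cid_key(compound_id: str) -> int:
    return zlib.crc32(compound_id.encode())


def _rng(noise: NoiseModel, compound_id: str, nce: float, polarity: str, tag: int):
    return np.random.default_rng(
        [noise.seed, _cid_key(compound_id), int(round(nce * 10)),
         0 if polarity == POSITIVE else 1, tag]
    )


def _random_formula(rng: np.random.Generator) -> ElementCounts:
    """A plausible CHNO(PS) formula with monoisotopic mass in [100, 900] Da."""
    while True:
        n_c = int(rng.integers(5, 41))
        n_h = int(rng.integers(n_c, 2 * n_c + 3))
        n_n = int(rng.integers(0, 4))
        n_o = int(rng.integers(1, 9))
        counts = {"C": n_c, "H": n_h, "O": n_o}
        if n_n:
            counts["N"] = n_n
        if rng.random() < 0.1:
            counts["S"] = 1
        f = ElementCounts(counts)
        if 100.0 <= monoisotopic_mass(f) <= 900.0:
            return f


def simulate_compound(seed: int, fail_mode: str | None = None) -> SimCompound:
    """Generate one compound, deterministically per seed.

    4-12 product ions; the first three share collision-energy optima in
    the mid range (30-50 eV) so every compound has a usable spectrum at
    moderate energies, the rest are drawn from the full ladder.
    ``fail_mode`` injects a designed QC violation:

    - ``two_fragments``: only 2 product ions (below the >=3 rule);
    - ``bad_ppm``: a +50 ppm systematic calibration error;
    - ``low_snr``: product-ion amplitudes at baseline level.
    """
    if fail_mode is not None and fail_mode not in FAIL_MODES:
        raise ValueError(f"unknown fail_mode: {fail_mode!r}")
    rng = np.random.default_rng([int(seed), 0xC0FFEE])
    formula = _random_formula(rng)
    cid = f"SIM{seed:05d}"
    record = CompoundRecord(
        compound_id=cid,
        name=f"simulated-{seed}",
        formula=formula,
        adducts={POSITIVE: [_POS_ADDUCT], NEGATIVE: [_NEG_ADDUCT]},
        retention_time=float(rng.uniform(0.5, 14.5)),
    )
    precursor = adduct_mz(formula, _POS_ADDUCT)
    n_frag = 2 if fail_mode == "two_fragments" else int(rng.integers(4, 13))
    mid_optima = [30.0, 35.0, 40.0, 50.0]
    fragments: list[FragmentModel] = []
    mzs = np.sort(rng.uniform(55.0, precursor - 20.0, size=n_frag))[::-1]
    for i, mz in enumerate(mzs):
        if i < 3:
            opt = float(rng.choice(mid_optima))
        else:
            opt = float(rng.choice(DEFAULT_NCE_LADDER))
        amp = float(rng.uniform(1e4, 1e6))
        if fail_mode == "low_snr":
            amp = float(rng.uniform(60.0, 140.0))
        fragments.append(
            FragmentModel(
                product_mz=float(mz),
                amplitude=amp,
                ce_optimum=opt,
                # widths narrow relative to the ladder spacing (5-10 eV), so
                # each ion's optimum is resolvable from neighbouring
                # energies, yet wide enough that mid-range ions coexist in
                # one scan
                ce_width=float(rng.uniform(5.0, 8.0)),
            )
        )
    ppm_offset = 50.0 if fail_mode == "bad_ppm" else float(rng.uniform(-2.0, 2.0))
    return SimCompound(
        record=record,
        fragments=fragments,
        precursor_decay=float(rng.uniform(25.0, 60.0)),
        fail_mode=fail_mode,
        ppm_offset=ppm_offset,
    )


def simulate_batch(
    n_compounds: int, seed: int, fail_modes: dict[int, str] | None = None
) -> list[SimCompound]:
    """A batch of compounds with designed failures injected at the given
    0-based indices (e.g. ``{0: "two_fragments", 1: "bad_ppm"}``)."""
    fail_modes = fail_modes or {}
    return [
        simulate_compound(seed * 1000 + i, fail_modes.get(i))
        for i in range(n_compounds)
    ]


def _theoretical_precursor(c: SimCompound, polarity: str) -> float:
    adduct = _POS_ADDUCT if polarity == POSITIVE else _NEG_ADDUCT
    return adduct_mz(c.record.formula, adduct)


def _observed(mz: float, c: SimCompound, rng, noise: NoiseModel) -> float:
    jitter = rng.uniform(-noise.mz_jitter_ppm, noise.mz_jitter_ppm)
    return mz * (1.0 + (c.ppm_offset + jitter) * 1e-6)


def _baseline_intensities(rng, n: int) -> np.ndarray:
    """Chemical/electronic baseline: intensities spread evenly over
    30-170 counts with 2% jitter.  The even spread keeps the robust
    (MAD-based) noise-floor estimate stable from scan to scan, so
    baseline peaks sit reliably below a S/N of 10."""
    if n == 0:
        return np.empty(0)
    return np.linspace(30.0, 170.0, n) * rng.uniform(0.98, 1.02, size=n)


def _lognormal_factor(rng, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def simulate_spectrum(
    c: SimCompound, nce: float, polarity: str, noise: NoiseModel | None = None
) -> Spectrum:
    """One MS2 scan of a compound at a collision energy.

    Fragment intensities follow each ion's Gaussian breakdown profile
    with lognormal noise; the residual precursor decays exponentially
    with energy (scale tau = ``precursor_decay``); baseline peaks and
    bounded m/z jitter complete the scan.  Deterministic per
    (noise seed, compound, nce, polarity).
    """
    if nce <= 0:
        raise ValueError("nce must be positive")
    noise = noise or NoiseModel()
    rng = _rng(noise, c.record.compound_id, nce, polarity, tag=2)
    theo_prec = _theoretical_precursor(c, polarity)
    obs_prec = _observed(theo_prec, c, rng, noise)
    mzs: list[float] = []
    ints: list[float] = []
    for f in c.fragments:
        inten = f.response(nce) * float(_lognormal_factor(rng, noise.multiplicative_cv))
        if inten < 1.0:
            continue
        mzs.append(_observed(f.product_mz, c, rng, noise))
        ints.append(inten)
    total_amp = sum(f.amplitude for f in c.fragments)
    prec_int = total_amp * np.exp(-nce / c.precursor_decay)
    prec_int *= float(_lognormal_factor(rng, noise.multiplicative_cv))
    if prec_int >= 1.0:
        mzs.append(obs_prec)
        ints.append(prec_int)
    mzs.extend(rng.uniform(50.0, theo_prec + 20.0, size=noise.baseline_peaks))
    ints.extend(_baseline_intensities(rng, noise.baseline_peaks))
    return Spectrum(
        mz=np.array(mzs),
        intensity=np.array(ints),
        ms_level=2,
        polarity=polarity,
        nce=float(nce),
        precursor_mz=obs_prec,
        retention_time=c.record.retention_time,
        source_id=f"{c.record.compound_id}|{polarity}|nce{nce:g}|ms2",
    )


def simulate_ms1(
    c: SimCompound, nce: float, polarity: str, noise: NoiseModel | None = None
) -> Spectrum:
    """The MS1 scan paired with an MS2 acquisition: theoretical isotope
    envelope of the adduct ion (with the compound's calibration error)
    over baseline peaks."""
    noise = noise or NoiseModel()
    rng = _rng(noise, c.record.compound_id, nce, polarity, tag=1)
    adduct = _POS_ADDUCT if polarity == POSITIVE else _NEG_ADDUCT
    pattern = isotope_pattern(adduct.apply(c.record.formula), prune=1e-3)
    scale = 1e6
    mzs = [m * (1.0 + c.ppm_offset * 1e-6) for m in pattern.mz]
    ints = [scale * a * float(_lognormal_factor(rng, noise.multiplicative_cv / 5))
            for a in pattern.fractions()]
    mzs.extend(rng.uniform(50.0, float(pattern.mz.max()) + 50.0, size=noise.baseline_peaks))
    ints.extend(_baseline_intensities(rng, noise.baseline_peaks))
    return Spectrum(
        mz=np.array(mzs),
        intensity=np.array(ints),
        ms_level=1,
        polarity=polarity,
        retention_time=c.record.retention_time,
        source_id=f"{c.record.compound_id}|{polarity}|nce{nce:g}|ms1",
    )


def simulate_acquisition(
    compounds: Sequence[SimCompound],
    nce_ladder: Sequence[float] = DEFAULT_NCE_LADDER,
    polarities: Sequence[str] = (POSITIVE, NEGATIVE),
    noise: NoiseModel | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """One MS1 + one MS2 scan per (compound, energy, polarity), plus a
    ground-truth table recording true precursors, fragment optima, and
    injected QC violations."""
    if not nce_ladder:
        raise ValueError("empty collision-energy ladder")
    noise = noise or NoiseModel()
    spectra: list[Spectrum] = []
    rows = []
    for c in compounds:
        for polarity in polarities:
            for nce in nce_ladder:
                spectra.append(simulate_ms1(c, nce, polarity, noise))
                spectra.append(simulate_spectrum(c, nce, polarity, noise))
        rows.append(
            {
                "compound_id": c.record.compound_id,
                "name": c.record.name,
                "formula": c.record.formula.hill_formula(),
                "precursor_mz_positive": _theoretical_precursor(c, POSITIVE),
                "precursor_mz_negative": _theoretical_precursor(c, NEGATIVE),
                "n_fragments": len(c.fragments),
                "fragment_optima": json.dumps(
                    {f"{f.product_mz:.4f}": f.ce_optimum for f in c.fragments}
                ),
                "ppm_offset": c.ppm_offset,
                "fail_mode": c.fail_mode or "",
            }
        )
    truth = pd.DataFrame(rows)
    return spectra, truth


def simulate_query(
    c: SimCompound,
    nce: float,
    polarity: str = POSITIVE,
    noise: NoiseModel | None = None,
    replicate: int = 0,
) -> Spectrum:
    """A query spectrum drawn from the same fragmentation model but an
    independent noise realization (for identification tests)."""
    noise = noise or NoiseModel()
    shifted = NoiseModel(
        multiplicative_cv=noise.multiplicative_cv,
        mz_jitter_ppm=noise.mz_jitter_ppm,
        baseline_peaks=noise.baseline_peaks,
        seed=noise.seed + 7919 * (replicate + 1),
    )
    s = simulate_spectrum(c, nce, polarity, shifted)
    return s.copy(source_id=f"query|{c.record.compound_id}|rep{replicate}")


def decoy_spectrum(spectrum: Spectrum, seed: int) -> Spectrum:
    """A decoy with the same intensities but shuffled, re-drawn fragment
    m/z values (precursor retained), for false-positive checks."""
    rng = np.random.default_rng([int(seed), 0xDEC0])
    lo = 50.0
    hi = float(spectrum.precursor_mz) - 2.0
    mzs = rng.uniform(lo, hi, size=spectrum.n_peaks)
    return spectrum.copy(
        mz=np.sort(mzs),
        intensity=spectrum.intensity[rng.permutation(spectrum.n_peaks)],
        source_id=spectrum.source_id + "|decoy",
    )


def simulate_srm_trace(
    area: float,
    rt: float,
    width: float,
    noise: NoiseModel | None = None,
    baseline: float = 0.0,
    n_points: int = 601,
    window_sigmas: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A Gaussian chromatographic peak with exact analytic area ``area``
    (intensity x minutes) centred at ``rt`` with sigma ``width``, on an
    optionally noisy baseline.  Returns (times, intensities)."""
    if area <= 0:
        raise ValueError("area must be positive")
    if width <= 0:
        raise ValueError("width must be positive")
    noise = noise or NoiseModel()
    rng = np.random.default_rng([noise.seed, int(rt * 1000) % 2**30, 0x5A])
    times = np.linspace(rt - window_sigmas * width, rt + window_sigmas * width, n_points)
    amp = area / (width * np.sqrt(2 * np.pi))
    y = amp * np.exp(-((times - rt) ** 2) / (2 * width**2))
    y[y < amp * 1e-9] = 0.0
    if noise.multiplicative_cv > 0:
        y = y * _lognormal_factor(rng, noise.multiplicative_cv, size=y.size)
    y = y + baseline
    if baseline > 0 and noise.multiplicative_cv > 0:
        y = y + rng.normal(0, noise.multiplicative_cv * baseline, size=y.size)
    return times, np.maximum(y, 0.0)
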