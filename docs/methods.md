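# Methods

This note documents the models, parameter choices, and numerical
conventions behind `phytospeclib`, and what the simulator does and does
not emulate.

## Mass arithmetic

Atomic masses and isotope abundances are a static IUPAC-derived table
embedded in `chem_mass` (no network access, bit-reproducible). All
charged-species masses subtract `z` electron masses (m_e ≈ 0.000549 Da);
at m/z < 400 the electron mass is comparable to a 5 ppm window, so
omitting it would make the precursor-tolerance checks physically wrong.
Built-in adducts cover an ammonium-formate/formic-acid mobile phase
([M+H]⁺, [M+NH₄]⁺, [M+Na]⁺, [M−H]⁻, [M+HCOO]⁻) plus the identity adduct
[M]⁺ for intrinsic cations such as quaternary alkaloids; catalogues can
override adducts per compound, and extra adducts load from a plain-text
config.

Theoretical isotope patterns are computed by iterated convolution of
per-element distributions (exponentiation by squaring), merging peaks
closer than 1e-4 Da (below what 70,000 resolving power separates) and
pruning below 1e-5 of the base peak by default; abundances are
renormalized to sum to 1 afterwards. A brute-force isotopologue
enumeration serves as the oracle in tests for small formulas.

Isotope-envelope agreement is scored as `1 − ½·Σ|p − q|` over
fraction-normalized abundances with peaks matched within an m/z
tolerance — one minus the total-variation distance, so 1 means
identical and 0 means disjoint. The base-peak convention common in
plotting is deliberately *not* used for scoring: with fractional
abundances the score has the clean 0/1 endpoints above and unmatched
abundance on either side counts symmetrically.

## QC thresholds and their semantics

| parameter | default | semantics |
|---|---|---|
| min_snr | 10 | strict: a fragment must *exceed* 10 × noise floor |
| min_fragments | 3 | inclusive: "at least three fragment ions" |
| max_precursor_ppm | 5 | absolute signed ppm bound |
| min_isotope_score | 0.8 | skipped (score 1.0) when no MS1 is supplied |
| max_weight | 1500 Da | strict: 1500.0 itself is excluded |
| retention_fraction | 0.9 | keep spectra with q ≥ 0.9 · max q per polarity |

The per-peak noise floor is 1.4826 × the median absolute deviation of
the lowest-intensity half of the peaks, with a floor of 1 count when
that estimate degenerates (single-peak or uniform spectra). This
measures baseline *spread*, not level — a deliberate choice: electronic
baseline with small spread yields a low floor, and genuine fragments
tower over it regardless of the baseline's mean.

Failure codes accumulate rather than short-circuit, so an exclusion
report row carries every reason a compound failed. `LOW_SNR` fires when
no fragment outside the precursor window exceeds the S/N bound;
`FEW_FRAGMENTS` when fewer than three do. The precursor-exclusion
window is ±1.0 m/z around the observed precursor: with an isolation
window of ~1.3 m/z, residual precursor always survives fragmentation
and must not be counted as a product ion.

Recalibration is single-point multiplicative from the precursor
(every m/z scaled by theoretical/observed). Orbitrap mass error at the
ppm scale is approximately multiplicative in m/z, and the theoretical
accurate mass of the assigned adduct is the only reference the workflow
guarantees to have; after recalibration the precursor error is exactly
zero by construction.

The library-suitability score q = (1 − precursor_fraction) × balance
operationalizes "little precursor, products balanced across the mass
range": balance is the Shannon entropy of retained-fragment intensity
over 4 equal-width m/z bins spanning [lowest fragment, precursor],
normalized by log 4. Four bins are a coarse but stable choice for
spectra with as few as three fragments. How vendor software ranks
"best" spectra is not public; q is this package's declared
operationalization and is exposed via `QCThresholds.retention_fraction`.

## Matching

Fragment tolerance is 0.01 Da (not ppm): product spectra come from
lower-resolution MS2 scans where an absolute window is the common
practice. Peaks are paired greedily by smallest Δm/z with each peak
used once — deterministic and symmetric. The score is a cosine over
base-peak-normalized intensities raised to the 0.5 power (square-root
weighting damps dominant peaks so mid-intensity fragments carry
identity information); unmatched peaks contribute zero overlap but
stay in the norms. The "full match" filter (score ≥ 0.8, ≥ 3 matched
fragments, ≤ 5 ppm) is a package default, documented as such — it is
not a reproduction of any vendor's proprietary criterion, and results
should not be read as reproducing vendor-software identification
counts.

## SRM design

Optimal collision energy is the discrete argmax of the breakdown curve
on the measured NCE grid — no interpolation, ties to the lowest energy
(gentler fragmentation preferred). Quantitation-ion ranking uses the
maximum response across energies. The default targeted assay takes the
quant plus the best confirming transition (two per compound) and falls
back to 30 eV when an entry lacks multi-energy data. The breakdown
"response" is spectral intensity here; chromatographic areas would work
identically through the same interface.

Peak integration: baseline = trace median, apex must exceed 3 × the
baseline to qualify, bounds are the nearest points where the trace
falls back to the baseline, and the baseline rectangle is subtracted
from the trapezoidal integral. This is a simple deterministic stand-in
for interactive vendor integration; it assumes one dominant peak per
trace and a trace window several peak-widths wide (so the median
reflects baseline, not peak).

## Simulator

The generator emulates one-compound-at-a-time acquisitions on a
high-resolution instrument:

- **Formulas**: random CHNO(S) compositions with monoisotopic mass in
  [100, 900] Da — the mass range typical of plant secondary
  metabolites.
- **Fragmentation**: 4–12 product ions per compound; ion intensity
  follows a Gaussian in NCE centred on a per-ion optimum drawn from the
  acquisition ladder {10, 15, 20, 30, 35, 40, 50, 60, 70, 80, 90,
  120} eV. Widths are U(5, 8) eV: 8 eV is the upper bound at which an
  optimum remains statistically resolvable from a neighbouring grid
  point 5 eV away under 5% intensity noise (≈2.8 σ), and 5 eV keeps
  ions with 30 and 50 eV optima jointly visible in a 40 eV scan so
  clean compounds always offer ≥ 3 fragments somewhere on the ladder.
  Three of each compound's ions have mid-range optima (30–50 eV) for
  the same reason.
- **Precursor survival**: residual precursor = (total fragment
  amplitude) · exp(−NCE/τ), τ ∈ U(25, 60) eV — the qualitative
  behaviour of HCD: precursor-dominated at 20 eV, fully fragmented by
  50 eV.
- **Noise**: lognormal multiplicative intensity noise (CV 5%), uniform
  m/z jitter bounded at 2 ppm, a per-compound systematic calibration
  error U(−2, 2) ppm, and 60 baseline peaks per scan with intensities
  spread evenly over 30–170 counts (±2%). The even spread keeps the
  MAD noise floor stable at ≈26 counts so the S/N > 10 boundary
  separates designed-pass from designed-fail compounds by construction
  rather than by luck.
- **Designed violations**: `two_fragments` (2 product ions),
  `bad_ppm` (+50 ppm systematic error), `low_snr` (fragment amplitudes
  at baseline level, 60–140 counts).
- **SRM traces**: Gaussian peaks with exact analytic area on an
  optionally noisy baseline, sampled over ±20 σ so the trace median is
  a true baseline estimate.

All generators are pure functions of explicit seeds (numpy
`default_rng` over structured seed sequences); no global random state.

What the simulator does **not** emulate: chemically realistic
fragmentation (bond-breaking rules, neutral losses), isotope peaks in
MS2, chimeric spectra from co-isolation, retention-time drift, detector
saturation, and centroiding artifacts. Passing tests therefore
demonstrate that the decision tree, matcher, and designer implement
their contracts correctly on data matching their stated assumptions —
not that the defaults are optimal for any particular instrument.

## Persistence formats

MSP is the interchange surface: NIST-style key/value headers (Name,
Formula, PrecursorMZ, Ion_mode, Collision_energy, RetentionTime,
Comment, Provenance, Num Peaks) with tab-separated peak lines, m/z to
4 decimals (5 ppm at m/z 300 ≈ 0.0015) and intensities to 6 significant
figures. The native archive is a single-file versioned JSON document:
saves are byte-deterministic for fixed content, floats round-trip
exactly, and version/corruption errors are explicit. mzML is read
directly (64/32-bit float arrays, optional zlib) and never written;
MGF serves as the writable acquisition format. Readers reject rather
than coerce: profile-mode scans, missing polarity, peak-count
mismatches, and truncated archives are all hard errors.

## Problem sizes

Test and acceptance runs use 20-compound batches (12 NCEs × 2
polarities → 960 scans), 50 identification queries, and ~150 breakdown
ions — sizes at which every stage completes in seconds while still
exercising multi-compound bookkeeping, both polarities, and the full
energy ladder.
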