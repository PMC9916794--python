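# phytospeclib

Multi-collision-energy MS/MS spectral libraries for plant metabolites:
construction from raw acquisitions, library-based untargeted
identification, and automatic design of pseudo-targeted SRM assays.

## The problem

Untargeted plant metabolomics lives or dies by the spectral library it
searches against. Building one from authentic standards is a pipeline of
small, well-defined decisions: which precursor adduct a scan belongs to,
whether its fragments clear the noise floor, whether its mass accuracy
and isotope envelope are consistent with the molecular formula, which of
the spectra acquired across a ladder of normalized collision energies
(NCEs) deserve to enter the library, and — once the library exists —
which product ions and collision energies make the best transitions for
a triple-quadrupole SRM method. `phytospeclib` implements that pipeline
as testable, scriptable software, together with a synthetic-data
generator that produces acquisitions with known ground truth so every
stage can be validated end to end.

## The core procedures

**Library construction (decision tree).** For each catalogued compound
(molecular formula, expected adducts, optional retention time) and each
candidate MS/MS scan:

1. *Inclusion*: monoisotopic weight must be < 1500 Da (strict).
2. *Precursor assignment*: among the compound's expected adducts, choose
   the one minimizing |δ| where δ = (m/z_obs − m/z_theo)/m/z_theo · 10⁶;
   reject if |δ| > 5 ppm. All ion masses are electron-corrected.
3. *Isotope check* (when an MS1 scan is available): the observed MS1
   envelope is compared with the theoretical isotope pattern (iterated
   convolution of IUPAC per-element distributions) by
   s = 1 − ½·Σᵢ|pᵢ − qᵢ| on fractional abundances; require s ≥ 0.8.
4. *Fragment QC*: per-peak S/N uses a robust noise floor
   (1.4826 × MAD of the lowest-intensity half of the peaks); fragments
   must satisfy S/N > 10 (strict), lie outside the ±1.0 m/z
   precursor-exclusion window, and number at least 3.
5. *Recalibration*: every m/z is scaled by m/z_theo/m/z_obs of the
   precursor, so the recalibrated precursor error is exactly 0 ppm.
6. *Best-spectrum retention*: each passing spectrum gets a quality score
   q = (1 − f_prec) · H₄, where f_prec is the intensity fraction inside
   the precursor window and H₄ the base-4-normalized Shannon entropy of
   fragment intensity over four m/z bins; per polarity, all spectra with
   q ≥ 0.9·q_max are retained ("a few spectra when the best is not
   clear"). Compounds with no passing spectrum go to the exclusion
   report with accumulated reason codes.

**Identification.** Queries are gated by polarity and 5 ppm precursor
tolerance, then scored against every retained library spectrum with a
weighted cosine: peaks paired greedily by smallest Δm/z within 0.01 Da,
intensities base-peak-normalized and raised to the 0.5 power, unmatched
peaks contributing zero overlap. A "full match" requires score ≥ 0.8,
≥ 3 matched fragments, and ≤ 5 ppm. Positive- and negative-mode results
merge by compound with redundancy removal.

**SRM design.** Product-ion breakdown curves (response vs. NCE) are read
off the retained multi-energy spectra; each ion's optimal collision
energy is the argmax on the measured grid (ties to the lowest energy).
The most intense product becomes the quantitation ion, the next up to
three the confirming ions; the default targeted assay exports two
transitions per compound, falling back to 30 eV when an entry lacks
multi-energy data. SRM traces are quantified by baseline-corrected
trapezoidal peak areas.

## Worked example

```bash
phytospeclib simulate --compounds 8 --out demo --seed 7 --fail 2
phytospeclib build-library --catalogue demo/catalogue.csv \
    --acquisitions demo/acquisition.mgf \
    --out demo/lib.splib --msp demo/lib.msp --report demo/exclusions.csv
phytospeclib match --library demo/lib.splib --queries demo/acquisition.mgf \
    --out demo/annotations.csv --full-match-only
phytospeclib design-srm --library demo/lib.splib --out demo/assay.csv
```

prints

```
wrote 384 spectra for 8 compounds to demo
library: 6 entries; excluded: 2
62 annotations written to demo/annotations.csv
12 transitions for 6 compounds
```

The simulator produced 8 compounds × 12 NCEs × 2 polarities × (MS1 +
MS2) = 384 scans, with 2 compounds carrying designed QC violations; the
builder admitted exactly the 6 clean compounds and reported the 2
designed failures with their reason codes
(`FEW_FRAGMENTS;LOW_SNR`, `...;NO_PRECURSOR` in `demo/exclusions.csv`).
The assay holds 2 transitions per library compound, e.g.

```
compound_id,name,polarity,precursor_mz,product_mz,collision_energy_eV,role,retention_time
SIM07002,simulated-7002,positive,281.1959,207.5116,30,quant,4.426
SIM07002,simulated-7002,positive,281.1959,254.2814,35,confirm,4.426
```

where each transition carries the collision energy that maximized its
own breakdown curve.

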