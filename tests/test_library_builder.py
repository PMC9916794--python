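"""The acquisition-to-library decision tree: QC, recalibration, retention."""

import numpy as np
import pytest

from phytospeclib.chem_mass import BUILTIN_ADDUCTS, ppm_error
from phytospeclib.library_builder import (
    FEW_FRAGMENTS,
    ISOTOPE_FAIL,
    LOW_SNR,
    NO_PRECURSOR,
    OVERWEIGHT,
    PPM_FAIL,
    PrecursorAssignment,
    QCThresholds,
    assign_precursor,
    build_entry,
    build_library,
    check_inclusion,
    estimate_snr,
    qc_spectrum,
    recalibrate,
    spectrum_quality,
)
from phytospeclib.spectra_io import CompoundRecord, LibraryEntry, Spectrum
from phytospeclib.chem_mass import ElementCounts
from phytospeclib import simulate as sim


def make_spectrum(mz, intensity, precursor_mz, polarity="positive", nce=40.0):
    return Spectrum(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float),
                    ms_level=2, polarity=polarity, nce=nce, precursor_mz=precursor_mz)


def with_baseline(mz, intensity, precursor_mz, n_noise=40, polarity="positive"):
    """Fragments over a deterministic low-level baseline (30-170 counts),
    mimicking the chemical noise every real scan carries; the robust
    noise floor then sits near 26 counts."""
    noise_mz = np.linspace(61.3, precursor_mz - 5.0, n_noise)
    noise_int = np.linspace(30.0, 170.0, n_noise)
    return make_spectrum(
        np.concatenate([np.asarray(mz, float), noise_mz]),
        np.concatenate([np.asarray(intensity, float), noise_int]),
        precursor_mz,
        polarity=polarity,
    )


def make_assignment(theoretical, observed, compound_id="X", isotope_score=1.0):
    return PrecursorAssignment(
        compound_id=compound_id,
        adduct=BUILTIN_ADDUCTS["[M+H]+"],
        theoretical_mz=theoretical,
        observed_mz=observed,
        ppm=ppm_error(observed, theoretical),
        isotope_score=isotope_score,
    )


def heavy_compound(weight_target):
    # CnH2n chains: 14.01565 Da per unit, neutral
    n = round(weight_target / 14.0156500642)
    return CompoundRecord(
        compound_id=f"heavy{n}", name="chain", formula=ElementCounts({"C": n, "H": 2 * n})
    )


class TestInclusion:
    def test_typical_metabolite_included(self):
        c = CompoundRecord("jat", "jatrorrhizine",
                           ElementCounts({"C": 20, "H": 20, "N": 1, "O": 4}, 1))
        assert c.monoisotopic_weight == pytest.approx(338.1387, abs=5e-4)
        assert check_inclusion(c)

    def test_weight_bound_is_strict(self):
        just_under = heavy_compound(1499.7)   # C107H214, 1499.67 Da
        just_over = heavy_compound(1513.7)    # C108H216, 1513.69 Da
        assert just_under.monoisotopic_weight < 1500.0 < just_over.monoisotopic_weight
        assert check_inclusion(just_under)
        assert not check_inclusion(just_over)
        # exactly at the bound: excluded (strict "<")
        t = QCThresholds(max_weight=just_under.monoisotopic_weight)
        assert not check_inclusion(just_under, t)


class TestAssignPrecursor:
    @pytest.fixture()
    def compound(self):
        return CompoundRecord(
            "glc", "glucose", ElementCounts({"C": 6, "H": 12, "O": 6}),
            adducts={"positive": [BUILTIN_ADDUCTS["[M+H]+"], BUILTIN_ADDUCTS["[M+Na]+"]],
                     "negative": [BUILTIN_ADDUCTS["[M-H]-"]]},
        )

    def test_small_offset_within_tolerance(self, compound):
        from phytospeclib.chem_mass import adduct_mz
        theo = adduct_mz(compound.formula, BUILTIN_ADDUCTS["[M+H]+"])
        s = make_spectrum([85.0, 97.0, 127.0], [10, 20, 30], theo * (1 + 2e-6))
        a = assign_precursor(s, compound)
        assert a is not None
        assert a.adduct.label == "[M+H]+"
        assert a.ppm == pytest.approx(2.0, abs=0.01)

    def test_far_off_every_adduct_fails(self, compound):
        from phytospeclib.chem_mass import adduct_mz
        theo = adduct_mz(compound.formula, BUILTIN_ADDUCTS["[M+H]+"])
        s = make_spectrum([85.0], [10], theo * (1 + 50e-6))
        assert assign_precursor(s, compound) is None

    def test_argmin_ppm_selects_closest_adduct(self, compound):
        # precursor placed at -1 ppm of [M+Na]+
        from phytospeclib.chem_mass import adduct_mz
        theo_na = adduct_mz(compound.formula, BUILTIN_ADDUCTS["[M+Na]+"])
        s = make_spectrum([85.0], [10], theo_na * (1 - 1e-6))
        a = assign_precursor(s, compound)
        assert a.adduct.label == "[M+Na]+"
        assert a.ppm == pytest.approx(-1.0, abs=0.01)


class TestEstimateSnr:
    def test_spike_over_noise_floor(self):
        rng = np.random.default_rng(11)
        noise_mz = np.sort(rng.uniform(100, 400, 50))
        noise_int = rng.normal(100, 10, 50)
        mz = np.append(noise_mz, 450.0)
        inten = np.append(noise_int, 5000.0)
        s = make_spectrum(mz, inten, 500.0)
        snr = estimate_snr(s)
        assert snr[np.argmax(s.intensity)] > 100

    def test_single_peak_degenerate_floor(self):
        s = make_spectrum([100.0], [42.0], 200.0)
        assert estimate_snr(s)[0] == pytest.approx(42.0)

    def test_uniform_spectrum_symmetric(self):
        s = make_spectrum([100.0, 110.0, 120.0, 130.0], [7.0] * 4, 200.0)
        snr = estimate_snr(s)
        assert np.all(snr == snr[0])


class TestQcSpectrum:
    def test_two_fragments_fails_fragment_count(self):
        s = with_baseline([100.0, 150.0, 299.9], [5000.0, 4000.0, 3000.0], 300.0)
        a = make_assignment(300.0, 300.0)
        res = qc_spectrum(s, a)
        assert not res.passed
        assert res.failure_reasons == [FEW_FRAGMENTS]
        # the peak at 299.9 sits inside the precursor window
        assert len(res.retained_fragments) == 2

    def test_three_good_fragments_pass(self):
        s = with_baseline([100.0, 150.0, 200.0], [5000.0, 4000.0, 3000.0], 300.0)
        a = make_assignment(300.0, 300.0 * (1 + 1.5e-6))
        assert qc_spectrum(s, a).passed

    def test_failures_accumulate(self):
        # baseline-level fragments AND a 12 ppm precursor error: both reported
        s = with_baseline([100.0], [150.0], 300.0)
        a = make_assignment(300.0, 300.0 * (1 + 12e-6))
        res = qc_spectrum(s, a)
        assert PPM_FAIL in res.failure_reasons
        assert LOW_SNR in res.failure_reasons
        assert FEW_FRAGMENTS in res.failure_reasons

    def test_no_precursor_reason(self):
        s = make_spectrum([100.0, 150.0, 200.0], [5000.0] * 3, 300.0)
        res = qc_spectrum(s, None)
        assert NO_PRECURSOR in res.failure_reasons

    def test_isotope_fail(self):
        s = make_spectrum([100.0, 150.0, 200.0, 250.0], [5000.0] * 4, 300.0)
        a = make_assignment(300.0, 300.0, isotope_score=0.5)
        assert ISOTOPE_FAIL in qc_spectrum(s, a).failure_reasons

    @pytest.mark.parametrize("relax", [
        dict(min_snr=5.0), dict(min_fragments=2), dict(max_precursor_ppm=20.0),
        dict(min_isotope_score=0.2),
    ])
    def test_relaxing_thresholds_is_monotone(self, relax):
        # a spectrum passing at defaults still passes at any relaxed threshold
        s = with_baseline([100.0, 150.0, 200.0], [5000.0, 4000.0, 3000.0], 300.0)
        a = make_assignment(300.0, 300.0 * (1 + 1.5e-6))
        assert qc_spectrum(s, a, QCThresholds()).passed
        assert qc_spectrum(s, a, QCThresholds(**relax)).passed


class TestRecalibrate:
    def test_uniform_offset_removed(self):
        scale = 1 + 4e-6
        true_mz = np.array([100.0, 150.0, 200.0])
        s = make_spectrum(true_mz * scale, [1.0, 2.0, 3.0], 300.0 * scale)
        a = make_assignment(300.0, 300.0 * scale)
        r = recalibrate(s, a)
        np.testing.assert_allclose(r.mz, true_mz, rtol=1e-12)
        assert ppm_error(r.precursor_mz, 300.0) == 0.0
        # original untouched
        assert s.precursor_mz == pytest.approx(300.0 * scale)

    def test_identity_on_perfect_spectrum(self):
        s = make_spectrum([100.0, 200.0], [1.0, 2.0], 300.0)
        a = make_assignment(300.0, 300.0)
        r = recalibrate(s, a)
        np.testing.assert_array_equal(r.mz, s.mz)

    def test_idempotent_with_reassignment(self, batch, noise):
        c = next(c for c in batch if c.fail_mode is None)
        s = sim.simulate_spectrum(c, 40.0, "positive", noise)
        a = assign_precursor(s, c.record)
        r = recalibrate(s, a)
        a2 = assign_precursor(r, c.record)
        assert a2.ppm == 0.0


class TestSpectrumQuality:
    def test_all_precursor_scores_zero(self):
        s = make_spectrum([100.0, 300.0], [1e-6, 1e6], 300.0)
        a = make_assignment(300.0, 300.0)
        with pytest.raises(ValueError):
            # no retained fragments at all
            spectrum_quality(make_spectrum([300.0], [1e6], 300.0), a)
        q = spectrum_quality(s, a, QCThresholds(min_snr=1e-9))
        assert q.precursor_fraction == pytest.approx(1.0, abs=1e-6)
        assert q.q == pytest.approx(0.0, abs=1e-6)

    def test_balanced_fragments_score_one(self):
        # 4 equal fragments, one per bin over [100, 500], no precursor signal
        s = make_spectrum([100.0, 210.0, 310.0, 410.0], [1000.0] * 4, 500.0)
        a = make_assignment(500.0, 500.0)
        q = spectrum_quality(s, a, QCThresholds(min_snr=1e-9))
        assert q.balance == pytest.approx(1.0)
        assert q.q == pytest.approx(1.0)

    def test_single_bin_zero_entropy(self):
        s = make_spectrum([100.0, 101.0, 102.0], [1000.0] * 3, 500.0)
        a = make_assignment(500.0, 500.0)
        q = spectrum_quality(s, a, QCThresholds(min_snr=1e-9))
        assert q.balance == pytest.approx(0.0, abs=1e-9)
        assert q.q == pytest.approx(0.0, abs=1e-9)


class TestBuildEntry:
    def test_retention_rule_keeps_near_best(self, batch, noise):
        c = next(c for c in batch if c.fail_mode is None)
        spectra = [sim.simulate_spectrum(c, nce, "positive", noise)
                   for nce in (10, 20, 30, 35, 40, 50, 60)]
        entry = build_entry(c.record, spectra)
        assert isinstance(entry, LibraryEntry)
        qs = []
        for s in entry.spectra:
            a = assign_precursor(s, c.record)
            qs.append(spectrum_quality(s, a).q)
        assert min(qs) >= 0.9 * max(qs) - 1e-12

    def test_all_failing_gives_exclusion(self, batch, noise):
        c = next(c for c in batch if c.fail_mode == "low_snr")
        spectra = [sim.simulate_spectrum(c, nce, "positive", noise)
                   for nce in (30, 40, 50)]
        result = build_entry(c.record, spectra)
        assert not isinstance(result, LibraryEntry)
        assert FEW_FRAGMENTS in result.reasons or LOW_SNR in result.reasons

    def test_empty_candidates_error(self, batch):
        with pytest.raises(ValueError):
            build_entry(batch[0].record, [])


class TestBuildLibrary:
    def test_designed_partition_recovered(self, batch, built):
        library, report = built
        assert len(library) == 17
        assert len(report) == 3
        by_id = dict(zip(report.compound_id, report.reasons))
        modes = {c.record.compound_id: c.fail_mode for c in batch if c.fail_mode}
        for cid, mode in modes.items():
            assert cid in by_id
            if mode == "two_fragments":
                assert FEW_FRAGMENTS in by_id[cid]
            elif mode == "bad_ppm":
                assert NO_PRECURSOR in by_id[cid]
            elif mode == "low_snr":
                assert LOW_SNR in by_id[cid] or FEW_FRAGMENTS in by_id[cid]

    def test_conservation_across_library_and_report(self, batch, built):
        library, report = built
        seen = set(library.entries) | set(report.compound_id)
        assert seen == {c.record.compound_id for c in batch}
        assert len(library) + len(report) == len(batch)

    def test_empty_acquisitions_exclude_everything(self, batch):
        records = [c.record for c in batch[:4]]
        library, report = build_library(records, [])
        assert len(library) == 0
        assert list(report.compound_id) == [r.compound_id for r in records]
        assert all(NO_PRECURSOR in r for r in report.reasons)

    def test_unattributable_spectra_skipped_with_warning(self, batch, noise, caplog):
        import logging

        c = batch[3]
        s = sim.simulate_spectrum(c, 40.0, "positive", noise)
        stray = s.copy(source_id="UNKNOWN|positive|nce40|ms2")
        with caplog.at_level(logging.WARNING, logger="phytospeclib.library_builder"):
            build_library([c.record], [s, stray])
        assert any("no catalogued compound" in r.message for r in caplog.records)

    def test_overweight_compound_reported(self, batch, noise):
        c = batch[3]
        big = CompoundRecord("big", "polymer",
                             ElementCounts({"C": 120, "H": 240}))
        lib, report = build_library(
            [big], [sim.simulate_spectrum(c, 40.0, "positive", noise)]
        )
        assert OVERWEIGHT in report.iloc[0]["reasons"]
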