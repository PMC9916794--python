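"""Breakdown curves, optimal collision energies, transition selection,
and chromatographic peak integration."""

import math

import numpy as np
import pytest

from phytospeclib import simulate as sim
from phytospeclib.library_builder import PRECURSOR_WINDOW
from phytospeclib.spectra_io import CompoundRecord, LibraryEntry, Spectrum
from phytospeclib.chem_mass import ElementCounts
from phytospeclib.srm_designer import (
    Assay,
    BreakdownCurve,
    Transition,
    breakdown_curves,
    build_targeted_assay,
    integrate_trace,
    optimal_ce,
    select_transitions,
)


def entry_from_sim(c, nces, polarity="positive", noise=None):
    """LibraryEntry carrying raw multi-NCE simulated spectra (no QC)."""
    noise = noise or sim.NoiseModel(multiplicative_cv=0.0, mz_jitter_ppm=0.0,
                                    baseline_peaks=0, seed=0)
    spectra = [sim.simulate_spectrum(c, nce, polarity, noise) for nce in nces]
    return LibraryEntry(compound=c.record, spectra=spectra)


@pytest.fixture(scope="module")
def clean_compound():
    return sim.simulate_compound(123)


class TestBreakdownCurves:
    def test_curve_covers_available_energies(self, clean_compound):
        entry = entry_from_sim(clean_compound, [20, 30, 40, 50])
        ion = clean_compound.fragments[0].product_mz
        curves = breakdown_curves(entry, [ion])
        assert len(curves) == 1
        assert sorted(curves[0].points) == [20, 30, 40, 50]
        assert all(v >= 0 for v in curves[0].points.values())

    def test_absent_ion_gets_zero_response(self, clean_compound):
        entry = entry_from_sim(clean_compound, [20, 30, 40, 50])
        curves = breakdown_curves(entry, [42.4242])  # no such product
        assert all(v == 0.0 for v in curves[0].points.values())

    def test_empty_ion_list(self, clean_compound):
        entry = entry_from_sim(clean_compound, [20, 30])
        assert breakdown_curves(entry, []) == []

    def test_single_energy_is_error(self, clean_compound):
        entry = entry_from_sim(clean_compound, [30])
        with pytest.raises(ValueError):
            breakdown_curves(entry, [clean_compound.fragments[0].product_mz])


class TestOptimalCe:
    def test_argmax(self):
        c = BreakdownCurve(100.0, {20: 1.0, 30: 5.0, 40: 9.0, 50: 4.0})
        assert optimal_ce(c) == 40

    def test_tie_breaks_to_lowest_energy(self):
        c = BreakdownCurve(100.0, {40: 7.0, 30: 7.0})
        assert optimal_ce(c) == 30

    def test_never_observed_ion_is_error(self):
        with pytest.raises(ValueError):
            optimal_ce(BreakdownCurve(100.0, {20: 0.0, 30: 0.0}))

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_argmax(self, seed):
        rng = np.random.default_rng(seed)
        nces = [10.0, 20.0, 30.0, 40.0, 50.0]
        responses = rng.uniform(0.1, 100.0, len(nces))
        c = BreakdownCurve(100.0, dict(zip(nces, responses)))
        brute = min(
            (ce for ce in c.points
             if c.points[ce] == max(c.points.values()))
        )
        assert optimal_ce(c) == brute

    def test_recovers_designed_optimum_noise_free(self):
        # Gaussian breakdown peaking at the top of the measured grid
        grid = [20.0, 30.0, 40.0, 50.0]
        for true_opt in grid:
            pts = {ce: 100.0 * math.exp(-((ce - true_opt) ** 2) / (2 * 15.0**2))
                   for ce in grid}
            assert optimal_ce(BreakdownCurve(100.0, pts)) == true_opt

    def test_recovery_on_simulated_entries(self):
        """Noise-free: 100% recovery of designed per-ion optima restricted
        to the measured grid; 5% multiplicative noise: >= 95%."""
        grid = list(map(float, (10, 15, 20, 30, 35, 40, 50, 60, 70, 80, 90, 120)))
        for cv, min_rate in ((0.0, 1.0), (0.05, 0.95)):
            total = hits = 0
            for k in range(25):
                c = sim.simulate_compound(5000 + k)
                noise = sim.NoiseModel(multiplicative_cv=cv, mz_jitter_ppm=0.0,
                                       baseline_peaks=0, seed=77)
                entry = entry_from_sim(c, grid, noise=noise)
                curves = breakdown_curves(
                    entry, [f.product_mz for f in c.fragments])
                for f, curve in zip(c.fragments, curves):
                    total += 1
                    if optimal_ce(curve) == f.ce_optimum:
                        hits += 1
            assert hits / total >= min_rate


class TestSelectTransitions:
    def test_quant_plus_three_confirming(self, clean_compound):
        entry = entry_from_sim(clean_compound, [20, 30, 40, 50, 60])
        ts = select_transitions(entry)
        assert len(ts) == 4
        assert [t.role for t in ts] == ["quant", "confirm", "confirm", "confirm"]

    def test_fewer_products_fewer_transitions(self):
        c = sim.simulate_compound(321, fail_mode="two_fragments")
        entry = entry_from_sim(c, [20, 30, 40, 50])
        ts = select_transitions(entry)
        assert len(ts) == 2
        assert [t.role for t in ts] == ["quant", "confirm"]

    def test_never_selects_residual_precursor(self, library):
        for entry in library:
            for t in select_transitions(entry):
                assert abs(t.product_mz - t.precursor_mz) > PRECURSOR_WINDOW

    def test_top_intensity_ions_chosen(self):
        # a four-ion entry modelled on a protoberberine alkaloid: the four
        # most intense products are the designed transitions
        jat_like_products = [265.07, 279.09, 307.08, 322.11]
        record = CompoundRecord(
            "jat", "jatrorrhizine-like",
            ElementCounts({"C": 20, "H": 20, "N": 1, "O": 4}, 1),
        )
        spectra = []
        for nce, scales in [(20, (0.2, 0.3, 0.4, 1.0)), (30, (0.5, 0.8, 0.9, 0.9)),
                            (40, (0.9, 1.0, 1.0, 0.4)), (50, (1.0, 0.7, 0.5, 0.1))]:
            mz = np.array(jat_like_products + [150.0, 180.0])
            inten = np.array([s * 1e6 for s in scales] + [1e3, 2e3])
            spectra.append(Spectrum(mz=mz, intensity=inten, ms_level=2,
                                    polarity="positive", nce=float(nce),
                                    precursor_mz=338.1387))
        entry = LibraryEntry(compound=record, spectra=spectra)
        ts = select_transitions(entry)
        assert sorted(t.product_mz for t in ts) == pytest.approx(jat_like_products)

    def test_per_ion_optimal_energies(self):
        # breakdown maxima at different energies propagate to transitions
        record = CompoundRecord("x", "x", ElementCounts({"C": 10, "H": 14, "O": 2}))
        mzs = [80.0, 110.0]
        profiles = {20: (1000.0, 10.0), 40: (200.0, 900.0)}
        spectra = [
            Spectrum(mz=np.array(mzs), intensity=np.array(profiles[nce]),
                     ms_level=2, polarity="positive", nce=float(nce),
                     precursor_mz=200.0)
            for nce in (20, 40)
        ]
        entry = LibraryEntry(compound=record, spectra=spectra)
        ce_by_product = {t.product_mz: t.collision_energy
                         for t in select_transitions(entry)}
        assert ce_by_product[80.0] == 20.0
        assert ce_by_product[110.0] == 40.0


class TestBuildTargetedAssay:
    def test_two_transitions_per_compound(self, library):
        ids = sorted(library.entries)[:5]
        assay = build_targeted_assay(library, ids)
        assert len(assay.transitions) == 10
        for cid in ids:
            ts = [t for t in assay.transitions if t.compound_id == cid]
            assert len(ts) == 2
            assert sum(1 for t in ts if t.role == "quant") == 1

    def test_single_nce_entry_falls_back_to_30ev(self):
        record = CompoundRecord("y", "y", ElementCounts({"C": 12, "H": 22, "O": 11}))
        s = Spectrum(mz=np.array([100.0, 150.0, 200.0]),
                     intensity=np.array([5.0, 9.0, 2.0]), ms_level=2,
                     polarity="positive", nce=35.0, precursor_mz=343.1235)
        lib_entry = LibraryEntry(compound=record, spectra=[s])
        from phytospeclib.spectra_io import Library

        lib = Library()
        lib.add(lib_entry)
        assay = build_targeted_assay(lib, ["y"])
        assert len(assay.transitions) == 2
        assert all(t.collision_energy == 30.0 for t in assay.transitions)

    def test_quant_only_when_per_compound_one(self, library):
        ids = sorted(library.entries)[:3]
        assay = build_targeted_assay(library, ids, per_compound=1)
        assert all(t.role == "quant" for t in assay.transitions)
        assert len(assay.transitions) == 3

    def test_missing_target_is_error(self, library):
        with pytest.raises(KeyError):
            build_targeted_assay(library, ["NOPE"])

    def test_duplicate_quant_rejected_by_assay_invariant(self):
        t = Transition("a", "positive", 300.0, 150.0, 30.0, "quant")
        with pytest.raises(ValueError):
            Assay(transitions=[t, t])


class TestIntegrateTrace:
    def test_flat_trace_zero_area(self):
        times = np.linspace(0, 10, 101)
        assert integrate_trace(times, np.full(101, 55.0)) == 0.0

    def test_gaussian_area_within_one_percent(self):
        noise = sim.NoiseModel(multiplicative_cv=0.0, seed=0)
        for area in (100.0, 2500.0):
            t, y = sim.simulate_srm_trace(area, rt=5.0, width=0.05, noise=noise)
            assert integrate_trace(t, y) == pytest.approx(area, rel=0.01)

    def test_two_to_one_ratio_recovered(self):
        noise = sim.NoiseModel(seed=9)  # 5% multiplicative noise
        t1, y1 = sim.simulate_srm_trace(1000.0, 5.0, 0.05, noise)
        t2, y2 = sim.simulate_srm_trace(500.0, 5.0, 0.05, noise)
        ratio = integrate_trace(t1, y1) / integrate_trace(t2, y2)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_empty_trace_is_error(self):
        with pytest.raises(ValueError):
            integrate_trace(np.array([]), np.array([]))

    def test_peak_on_elevated_baseline(self):
        noise = sim.NoiseModel(multiplicative_cv=0.0, seed=1)
        t, y = sim.simulate_srm_trace(800.0, 5.0, 0.05, noise, baseline=40.0)
        assert integrate_trace(t, y) == pytest.approx(800.0, rel=0.05)
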