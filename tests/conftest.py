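"""Shared fixtures: simulated batches, a built library, and helpers."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from phytospeclib import library_builder as lb
from phytospeclib import simulate as sim

BATCH_SEED = 1
FAIL_MODES = {0: "two_fragments", 1: "bad_ppm", 2: "low_snr"}


@pytest.fixture(scope="session")
def noise():
    return sim.NoiseModel(seed=BATCH_SEED)


@pytest.fixture(scope="session")
def batch():
    """20 simulated compounds, 3 with designed QC violations."""
    return sim.simulate_batch(20, BATCH_SEED, FAIL_MODES)


@pytest.fixture(scope="session")
def acquisition(batch, noise):
    return sim.simulate_acquisition(batch, noise=noise)


@pytest.fixture(scope="session")
def built(batch, acquisition):
    spectra, _truth = acquisition
    library, report = lb.build_library([c.record for c in batch], spectra)
    return library, report


@pytest.fixture(scope="session")
def library(built):
    return built[0]


def assert_spectra_equal(a, b, mz_tol=1e-4, intensity_rtol=1e-5):
    assert a.ms_level == b.ms_level
    assert a.polarity == b.polarity
    assert a.n_peaks == b.n_peaks
    np.testing.assert_allclose(a.mz, b.mz, atol=mz_tol)
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=intensity_rtol)
    if a.nce is None or b.nce is None:
        assert a.nce == b.nce
    else:
        assert a.nce == pytest.approx(b.nce)
    if a.precursor_mz is None or b.precursor_mz is None:
        assert a.precursor_mz == b.precursor_mz
    else:
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=mz_tol)


def assert_libraries_equal(a, b, mz_tol=1e-4, intensity_rtol=1e-5):
    assert set(a.entries) == set(b.entries)
    for cid, ea in a.entries.items():
        eb = b.entries[cid]
        assert ea.compound.name == eb.compound.name
        assert ea.compound.formula == eb.compound.formula
        assert ea.quant_ion == pytest.approx(eb.quant_ion, abs=1e-3) if ea.quant_ion else eb.quant_ion is None
        assert len(ea.spectra) == len(eb.spectra)
        key = lambda s: (s.polarity, s.nce if s.nce is not None else -1)
        for sa, sb in zip(sorted(ea.spectra, key=key), sorted(eb.spectra, key=key)):
            assert_spectra_equal(sa, sb, mz_tol, intensity_rtol)


# ---------------------------------------------------------------------------
# minimal mzML document builder (text fixture generated at test time)

def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _binary_xml(arr, kind: str) -> str:
    data = _b64(arr)
    name = "m/z array" if kind == "mz" else "intensity array"
    acc = "MS:1000514" if kind == "mz" else "MS:1000515"
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>'
        f"<binary>{data}</binary></binaryDataArray>"
    )


def mzml_scan(
    index: int,
    mz,
    intensity,
    ms_level: int = 2,
    polarity: str = "positive",
    precursor_mz: float | None = None,
    nce: float | None = None,
    rt_seconds: float | None = None,
    profile: bool = False,
) -> str:
    pol_acc = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
        if polarity == "negative"
        else ""
    )
    mode = (
        '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
        if profile
        else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
    )
    scan_block = ""
    if rt_seconds is not None:
        scan_block = (
            "<scanList count=\"1\"><scan>"
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt_seconds}" unitName="second"/>'
            "</scan></scanList>"
        )
    prec_block = ""
    if precursor_mz is not None:
        act = ""
        if nce is not None:
            act = (
                "<activation>"
                f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
                f'value="{nce}" unitName="electronvolt"/>'
                "</activation>"
            )
        prec_block = (
            '<precursorList count="1"><precursor>'
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{precursor_mz}"/>'
            "</selectedIon></selectedIonList>"
            f"{act}</precursor></precursorList>"
        )
    return (
        f'<spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{len(mz)}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>'
        f"{pol_acc}{mode}{scan_block}{prec_block}"
        f'<binaryDataArrayList count="2">{_binary_xml(mz, "mz")}'
        f'{_binary_xml(intensity, "int")}</binaryDataArrayList></spectrum>'
    )


def mzml_document(scans: list[str]) -> str:
    body = "".join(scans)
    return (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="run1"><spectrumList count="{len(scans)}">{body}'
        "</spectrumList></run></mzML>"
    )
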