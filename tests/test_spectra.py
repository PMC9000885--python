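"""Spectrum model, MSP/MGF round trips, normalization, peak matching."""

import math

import pytest

from flavotier.formulae import F
from flavotier.spectra import (
    LibraryRecord,
    MspFormatError,
    Peak,
    Spectrum,
    match_peaks,
    normalize,
    read_mgf,
    read_msp,
    write_mgf,
    write_msp,
)


def _spectrum(identifier="s", precursor=300.0, peaks=((100.0, 50.0), (200.0, 25.0)),
              rt=None):
    return Spectrum(
        identifier=identifier,
        precursor_mz=precursor,
        retention_time=rt,
        peaks=tuple(Peak(*p) for p in peaks),
    )


class TestSpectrumModel:
    def test_peaks_sorted_on_construction(self):
        sp = _spectrum(peaks=((200.0, 1.0), (100.0, 2.0)))
        assert [p.mz for p in sp.peaks] == [100.0, 200.0]

    def test_peak_above_precursor_guard(self):
        with pytest.raises(ValueError, match="above precursor"):
            _spectrum(precursor=150.0, peaks=((151.0, 1.0),))

    def test_isotope_spillover_tolerated(self):
        sp = _spectrum(precursor=150.0, peaks=((150.4, 1.0),))
        assert len(sp.peaks) == 1

    def test_reference_record_requires_formula(self):
        with pytest.raises(ValueError, match="formula"):
            LibraryRecord(spectrum=_spectrum(), name="x", provenance="reference")
        LibraryRecord(spectrum=_spectrum(), name="x", formula=F("C6H6"),
                      provenance="reference")


class TestNormalize:
    def test_base_peak_100(self):
        sp = normalize(_spectrum())
        assert [p.intensity for p in sp.peaks] == [100.0, 50.0]

    def test_idempotent_and_scale_invariant(self):
        sp = _spectrum(peaks=((100.0, 7.0), (150.0, 3.5), (200.0, 0.7)))
        once = normalize(sp)
        assert normalize(once) == once
        scaled = sp.with_peaks(Peak(p.mz, 13.7 * p.intensity) for p in sp.peaks)
        renorm = normalize(scaled)
        for p, q in zip(renorm.peaks, once.peaks):
            assert p.mz == q.mz
            assert math.isclose(p.intensity, q.intensity, rel_tol=1e-12)

    def test_single_peak(self):
        sp = normalize(_spectrum(peaks=((120.0, 3.0),)))
        assert sp.peaks[0].intensity == 100.0

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            normalize(_spectrum(peaks=((100.0, 0.0),)))


class TestMatchPeaks:
    def test_identical_spectra_fully_matched(self):
        sp = _spectrum(peaks=((100.0, 1.0), (150.0, 2.0), (200.0, 3.0)))
        pairs = match_peaks(sp, sp, 10.0)
        assert len(pairs) == 3
        assert all(a == b for a, b in pairs)

    def test_just_outside_tolerance_unmatched(self):
        a = _spectrum(peaks=((100.000, 1.0),))
        b = _spectrum(peaks=((100.011, 1.0),))
        assert match_peaks(a, b, 10.0) == []

    def test_boundary_is_inclusive(self):
        a = _spectrum(peaks=((100.000, 1.0),))
        b = _spectrum(peaks=((100.010, 1.0),))
        assert len(match_peaks(a, b, 10.0)) == 1

    def test_greedy_prefers_intense_partner(self):
        a = _spectrum(peaks=((100.000, 5.0),))
        b = _spectrum(peaks=((100.004, 1.0), (100.006, 9.0)))
        pairs = match_peaks(a, b, 10.0)
        assert len(pairs) == 1
        assert pairs[0][1].mz == 100.006

    def test_pair_count_bounded(self):
        a = _spectrum(peaks=((100.0, 1.0), (100.002, 1.0), (100.004, 1.0)))
        b = _spectrum(peaks=((100.001, 1.0),))
        assert len(match_peaks(a, b, 10.0)) <= 1


class TestMspIO:
    def _records(self):
        recs = []
        for i, name in enumerate(["daidzein", "apigenin", "pinocembrin"]):
            sp = Spectrum(
                identifier=name,
                precursor_mz=255.0 + i,
                retention_time=5.0 + i,
                peaks=(Peak(117.123456, 10.0), Peak(137.0233, 100.0)),
                metadata={"Comments": f"record {i}"},
            )
            recs.append(
                LibraryRecord(sp, name, formula=F("C15H10O4"),
                              subclass="isoflavone", provenance="reference")
            )
        return recs

    def test_round_trip_lossless(self, tmp_path):
        path = tmp_path / "lib.msp"
        recs = self._records()
        write_msp(recs, path)
        back = read_msp(path)
        assert len(back) == 3
        for orig, got in zip(recs, back):
            assert got.name == orig.name
            assert got.formula == orig.formula
            assert got.subclass == orig.subclass
            assert got.provenance == orig.provenance
            assert got.spectrum.metadata["Comments"] == \
                orig.spectrum.metadata["Comments"]
            assert math.isclose(got.spectrum.precursor_mz,
                                orig.spectrum.precursor_mz, abs_tol=1e-6)
            for p, q in zip(orig.spectrum.peaks, got.spectrum.peaks):
                assert math.isclose(p.mz, q.mz, abs_tol=1e-6)
                assert math.isclose(p.intensity, q.intensity,
                                    rel_tol=1e-4, abs_tol=1e-6)

    def test_fixture_file_two_records(self, tmp_path):
        path = tmp_path / "two.msp"
        path.write_text(
            "Name: a\nPrecursorMZ: 255.1\nNum Peaks: 1\n100.0 1.0\n\n"
            "Name: b\nPrecursorMZ: 255.2\nNum Peaks: 2\n100.0 1\n110.0 2\n\n"
        )
        assert [r.name for r in read_msp(path)] == ["a", "b"]

    def test_peak_count_mismatch_names_record(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text(
            "Name: broken\nPrecursorMZ: 255.1\nNum Peaks: 5\n"
            "100.0 1\n110.0 2\n120.0 3\n130.0 4\n\n"
        )
        with pytest.raises(MspFormatError, match="broken"):
            read_msp(path)

    def test_missing_name_is_error(self, tmp_path):
        path = tmp_path / "anon.msp"
        path.write_text("PrecursorMZ: 255.1\nNum Peaks: 1\n100.0 1\n\n")
        with pytest.raises(MspFormatError, match="Name"):
            read_msp(path)


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "q.mgf"
        spectra = [
            _spectrum("q1", 269.0808, ((137.0233, 100.0), (118.0413, 5.5)),
                      rt=12.5),
            _spectrum("q2", 255.0652, ((119.0491, 60.0),)),
        ]
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.identifier for s in back] == ["q1", "q2"]
        assert math.isclose(back[0].retention_time, 12.5, abs_tol=1e-9)
        assert back[1].retention_time is None
        for orig, got in zip(spectra, back):
            assert math.isclose(got.precursor_mz, orig.precursor_mz,
                                abs_tol=1e-6)
            for p, q in zip(orig.peaks, got.peaks):
                assert math.isclose(p.mz, q.mz, abs_tol=1e-6)
                assert math.isclose(p.intensity, q.intensity, rel_tol=1e-4)

    def test_rtinseconds_converted_to_minutes(self, tmp_path):
        path = tmp_path / "rt.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=x\nPEPMASS=200.0\nRTINSECONDS=60\n"
            "100.0 1.0\nEND IONS\n"
        )
        assert read_mgf(path)[0].retention_time == 1.0

    def test_empty_block_accepted_with_warning(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=200.0\nEND IONS\n")
        with pytest.warns(UserWarning, match="no peaks"):
            spectra = read_mgf(path)
        assert spectra[0].peaks == ()
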