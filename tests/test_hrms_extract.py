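"""Targeted extraction: ppm windows, peak integration, fragment
confirmation, calibration, and the synthetic mzML round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solaphen.hrms_extract import (
    DEFAULT_QUALIFIER_FRAGMENT_MZ,
    PROTON_MASS,
    AnalyteDefinition,
    GaussianPeak,
    Scan,
    SpectrumRun,
    build_xic,
    confirm_fragment,
    extract_analyte,
    integrate_peak,
    make_synthetic_run,
    mz_from_formula,
    ppm_difference,
    quantify_solanidine,
    read_mzml,
    write_mzml,
)

SOLA_FORMULA = "C27H43NO"


class TestPpm:
    def test_five_ppm_at_mass_100(self):
        assert ppm_difference(100.0005, 100.0) == pytest.approx(5.0)

    def test_identity_is_zero(self):
        assert ppm_difference(398.34174, 398.34174) == 0.0

    def test_formula_mass_against_atomic_mass_table(self):
        """[M+H]+ of solanidine from hand-summed monoisotopic masses."""
        monoisotopic = 27 * 12.0 + 43 * 1.00782503207 + 14.0030740048 + 15.9949146196
        assert mz_from_formula(SOLA_FORMULA) == pytest.approx(
            monoisotopic + PROTON_MASS, abs=1e-4)

    def test_millidalton_perturbation(self):
        mz = mz_from_formula(SOLA_FORMULA)
        assert ppm_difference(mz + 1e-3, mz) == pytest.approx(1e3 / mz, rel=1e-9)

    def test_non_positive_mz_rejected(self):
        with pytest.raises(ValueError):
            ppm_difference(0.0, 100.0)


def _single_centroid_run(mz, intensity=1000.0, rt=5.0):
    return SpectrumRun([Scan(rt=rt, ms_level=1, mz=[mz], intensity=[intensity])])


class TestBuildXic:
    def test_exact_mass_centroid_recovered(self):
        ana = AnalyteDefinition(name="x", mz_theoretical=400.0, rt_expected=5.0)
        rt, inten = build_xic(_single_centroid_run(400.0), ana)
        assert inten.tolist() == [1000.0]

    def test_window_inclusive_at_five_ppm_exclusive_beyond(self):
        """Centroids at exactly +/-5 ppm are inside; +/-5.01 ppm outside."""
        ana = AnalyteDefinition(name="x", mz_theoretical=400.0, rt_expected=5.0)
        half = ana.mz_theoretical * 5.0 * 1e-6  # the window's own arithmetic
        for sign in (+1, -1):
            _, inside = build_xic(
                _single_centroid_run(400.0 + sign * half), ana)
            assert inside.tolist() == [1000.0], f"{sign}5.00 ppm must be included"
            _, outside = build_xic(
                _single_centroid_run(400.0 * (1 + sign * 5.01e-6)), ana)
            assert outside.tolist() == [0.0], f"{sign}5.01 ppm must be excluded"

    def test_no_ms1_scans_rejected(self):
        run = SpectrumRun([Scan(rt=1.0, ms_level=2, mz=[98.1], intensity=[1.0],
                                precursor_mz=400.0)])
        with pytest.raises(ValueError):
            build_xic(run, AnalyteDefinition(name="x", mz_theoretical=400.0,
                                             rt_expected=1.0))


class TestIntegratePeak:
    def _analyte(self, rt=5.0):
        return AnalyteDefinition(name="x", mz_theoretical=400.0, rt_expected=rt)

    def test_flat_zero_not_detected(self):
        rt = np.arange(0, 10, 0.02)
        res = integrate_peak((rt, np.zeros_like(rt)), self._analyte())
        assert res.peak_area == 0.0 and not res.detected

    def test_gaussian_area_within_one_percent(self):
        peak = GaussianPeak(mz=400.0, rt=5.0, amplitude=5e5, sigma=0.04)
        run = make_synthetic_run([peak])
        res = extract_analyte(run, self._analyte())
        assert res.detected
        assert res.peak_area == pytest.approx(peak.analytic_area, rel=0.01)
        assert res.apex_rt == pytest.approx(5.0, abs=0.03)

    def test_two_to_one_amplitude_ratio_preserved(self):
        areas = []
        for amp in (2e5, 1e5):
            run = make_synthetic_run(
                [GaussianPeak(mz=400.0, rt=5.0, amplitude=amp, sigma=0.05)])
            areas.append(extract_analyte(run, self._analyte()).peak_area)
        assert areas[0] / areas[1] == pytest.approx(2.0, rel=0.01)

    def test_constant_baseline_subtracted(self):
        peak = GaussianPeak(mz=400.0, rt=5.0, amplitude=1e5, sigma=0.05)
        rt_grid = np.arange(0, 10, 0.02)
        profile = peak.amplitude * np.exp(-0.5 * ((rt_grid - 5.0) / 0.05) ** 2)
        res = integrate_peak((rt_grid, profile + 500.0), self._analyte())
        assert res.peak_area == pytest.approx(peak.analytic_area, rel=0.02)

    def test_window_not_covered(self):
        rt = np.arange(0, 1, 0.02)
        res = integrate_peak((rt, np.ones_like(rt)), self._analyte(rt=5.0))
        assert not res.detected and res.peak_area == 0.0


class TestConfirmFragment:
    def _analyte(self):
        return AnalyteDefinition(name="SOLA", formula=SOLA_FORMULA, rt_expected=5.0)

    def _run(self, fragment_mz, precursor=None):
        precursor = precursor or mz_from_formula(SOLA_FORMULA)
        return SpectrumRun([
            Scan(rt=5.0, ms_level=1, mz=[precursor], intensity=[1.0]),
            Scan(rt=5.01, ms_level=2, mz=[fragment_mz], intensity=[100.0],
                 precursor_mz=precursor),
        ])

    def test_diagnostic_fragment_confirms(self):
        check = confirm_fragment(self._run(DEFAULT_QUALIFIER_FRAGMENT_MZ),
                                 self._analyte())
        assert check.confirmed and check.acquired

    def test_distant_fragment_rejected(self):
        check = confirm_fragment(self._run(98.9000), self._analyte())
        assert not check.confirmed and check.acquired

    def test_wrong_precursor_ignored(self):
        check = confirm_fragment(
            self._run(DEFAULT_QUALIFIER_FRAGMENT_MZ, precursor=410.0),
            self._analyte())
        assert not check.confirmed

    def test_no_ms2_flagged_not_acquired(self):
        run = SpectrumRun([Scan(rt=5.0, ms_level=1, mz=[400.0], intensity=[1.0])])
        check = confirm_fragment(run, self._analyte())
        assert not check.confirmed and not check.acquired


class TestQuantify:
    CAL = [(2.0, 2000.0), (20.0, 20000.0), (60.0, 60000.0)]

    def test_proportional_calibration(self):
        assert quantify_solanidine(10000.0, self.CAL) == pytest.approx(10.0)

    def test_intercept_inverted(self):
        cal = [(2.0, 2500.0), (20.0, 20500.0), (60.0, 60500.0)]
        assert quantify_solanidine(10500.0, cal) == pytest.approx(10.0)

    def test_negative_prediction_clipped_with_warning(self):
        cal = [(2.0, 2500.0), (20.0, 20500.0), (60.0, 60500.0)]
        with pytest.warns(UserWarning, match="clipped"):
            assert quantify_solanidine(0.0, cal) == 0.0

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError):
            quantify_solanidine(100.0, [(2.0, 10.0), (2.0, 20.0)])

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_uniform_area_scaling(self, scale):
        cal = [(c, a * scale) for c, a in self.CAL]
        assert quantify_solanidine(10000.0 * scale, cal) == pytest.approx(
            10.0, rel=1e-9)


class TestMzmlRoundTrip:
    def test_arrays_and_metadata_survive(self, tmp_path):
        peak = GaussianPeak(mz=mz_from_formula(SOLA_FORMULA), rt=5.0,
                            amplitude=1e6, sigma=0.05)
        ms2 = [Scan(rt=5.01, ms_level=2,
                    mz=[DEFAULT_QUALIFIER_FRAGMENT_MZ, 150.0],
                    intensity=[1e5, 2e4], precursor_mz=peak.mz)]
        run = make_synthetic_run([peak], ms2=ms2, noise_intensity=50.0)
        path = tmp_path / "synthetic.mzML"
        write_mzml(run, str(path))
        back = read_mzml(str(path))
        assert len(back.scans) == len(run.scans)
        assert len(back.ms2()) == 1
        assert back.ms2()[0].precursor_mz == pytest.approx(peak.mz)
        for a, b in zip(run.scans, back.scans):
            assert a.ms_level == b.ms_level
            np.testing.assert_allclose(a.mz, b.mz, rtol=0, atol=0)
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=0, atol=0)

    def test_extraction_identical_after_round_trip(self, tmp_path):
        peak = GaussianPeak(mz=400.0, rt=4.0, amplitude=3e5, sigma=0.06)
        run = make_synthetic_run([peak])
        ana = AnalyteDefinition(name="x", mz_theoretical=400.0, rt_expected=4.0)
        direct = extract_analyte(run, ana)
        path = tmp_path / "rt.mzML"
        write_mzml(run, str(path))
        from_file = extract_analyte(read_mzml(str(path)), ana)
        assert from_file.peak_area == direct.peak_area

    def test_seconds_scan_time_converted_to_minutes(self, tmp_path):
        run = SpectrumRun([Scan(rt=2.0, ms_level=1, mz=[400.0], intensity=[1.0])])
        path = tmp_path / "sec.mzML"
        write_mzml(run, str(path))
        text = path.read_text().replace(
            'value="2.0" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
            'value="120.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"')
        path.write_text(text)
        assert read_mzml(str(path)).scans[0].rt == pytest.approx(2.0)


def test_run_requires_sorted_retention_times():
    with pytest.raises(ValueError):
        SpectrumRun([
            Scan(rt=2.0, ms_level=1, mz=[1.0], intensity=[1.0]),
            Scan(rt=1.0, ms_level=1, mz=[1.0], intensity=[1.0]),
        ])
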