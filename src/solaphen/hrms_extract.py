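"""Targeted re-extraction of analytes from centroided full-scan HRMS runs.

Full-scan high-resolution data acquired for routine TDM can be
reprocessed for analytes that were never targeted originally.  For each
configured analyte this module extracts an ion chromatogram (XIC) for
the protonated molecule within a +/-5 ppm window, integrates the
chromatographic peak inside the expected retention-time window,
optionally confirms identity via the diagnostic steroidal-alkaloid
MS2 fragment at m/z 98.0967, and converts the solanidine peak area to
an absolute concentration through a small external calibration line.

Baseline and detection are deliberately parameter-light: the baseline
is the median intensity outside the retention-time window and a peak is
"detected" only if some scan inside the window exceeds baseline +
3 * MAD (median absolute deviation of the out-of-window intensities).

The statistical pipeline does not require spectra — the ratios module
accepts peak-area tables directly — so this module is an optional
front-end.  A synthetic-fixture writer is included that emits valid
centroided mzML containing configurable Gaussian peaks and MS2 scans.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
import xml.etree.ElementTree as _ET
from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "DEFAULT_QUALIFIER_FRAGMENT_MZ",
    "AnalyteDefinition",
    "Scan",
    "SpectrumRun",
    "FragmentCheck",
    "IntegrationResult",
    "mz_from_formula",
    "ppm_difference",
    "build_xic",
    "integrate_peak",
    "confirm_fragment",
    "extract_analyte",
    "quantify_solanidine",
    "read_mzml",
    "write_mzml",
    "GaussianPeak",
    "make_synthetic_run",
]

PROTON_MASS = 1.00727646688
#: Iminium fragment shared by solanidine and its metabolites.
DEFAULT_QUALIFIER_FRAGMENT_MZ = 98.0967


def mz_from_formula(formula: str) -> float:
    """Theoretical [M+H]+ m/z from a molecular formula (monoisotopic)."""
    return float(_pmass.calculate_mass(formula=formula)) + PROTON_MASS


@dataclass
class AnalyteDefinition:
    """Targeted-extraction settings for one analyte.

    ``mz_theoretical`` may be omitted when ``formula`` is given (e.g.
    solanidine, C27H43NO).  ``rt_window`` is the half-width (minutes) of
    the integration window around ``rt_expected``.
    """

    name: str
    rt_expected: float
    formula: str | None = None
    mz_theoretical: float | None = None
    rt_window: float = 0.3
    qualifier_fragment_mz: float = DEFAULT_QUALIFIER_FRAGMENT_MZ
    truncation_area: float | None = None

    def __post_init__(self) -> None:
        if self.mz_theoretical is None:
            if self.formula is None:
                raise ValueError(f"{self.name}: need formula or mz_theoretical")
            self.mz_theoretical = mz_from_formula(self.formula)
        if self.mz_theoretical <= 0 or self.rt_window <= 0:
            raise ValueError(f"{self.name}: m/z and rt_window must be positive")


@dataclass
class Scan:
    rt: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must align")


@dataclass
class SpectrumRun:
    scans: list[Scan]
    run_id: str = "run"

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    def ms1(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]


@dataclass
class FragmentCheck:
    confirmed: bool
    acquired: bool  # False when the run contains no MS2 scans


@dataclass
class IntegrationResult:
    analyte: str
    peak_area: float
    apex_rt: float
    detected: bool
    fragment_confirmed: bool | None = None
    fragment_acquired: bool | None = None


def ppm_difference(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def build_xic(run: SpectrumRun, analyte: AnalyteDefinition,
              tol_ppm: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram: (rt, intensity) over the MS1 scans.

    Sums centroid intensities with |mass error| <= tol_ppm (inclusive at
    exactly +/-tol_ppm); all other centroids contribute zero.
    """
    ms1 = run.ms1()
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    half = analyte.mz_theoretical * tol_ppm * 1e-6
    lo, hi = analyte.mz_theoretical - half, analyte.mz_theoretical + half
    rt = np.array([s.rt for s in ms1])
    intensity = np.array([
        float(s.intensity[(s.mz >= lo) & (s.mz <= hi)].sum()) for s in ms1
    ])
    return rt, intensity


def integrate_peak(xic: tuple[np.ndarray, np.ndarray],
                   analyte: AnalyteDefinition) -> IntegrationResult:
    """Integrate the analyte peak inside the retention-time window.

    Baseline is the median intensity outside the window (zero if the
    XIC has no out-of-window points); the peak is the maximal contiguous
    in-window region with intensity above baseline, integrated by the
    trapezoidal rule.  Detection requires some in-window scan above
    baseline + 3 * MAD of the out-of-window intensities.
    """
    rt, inten = np.asarray(xic[0], float), np.asarray(xic[1], float)
    in_win = np.abs(rt - analyte.rt_expected) <= analyte.rt_window
    if not in_win.any():
        return IntegrationResult(analyte.name, 0.0, analyte.rt_expected, False)
    outside = inten[~in_win]
    baseline = float(np.median(outside)) if outside.size else 0.0
    mad = float(np.median(np.abs(outside - baseline))) if outside.size else 0.0

    above = in_win & (inten > baseline)
    if not above.any():
        return IntegrationResult(analyte.name, 0.0, analyte.rt_expected, False)
    # maximal contiguous run of above-baseline in-window scans containing
    # the in-window apex
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, splits + 1)
    apex_idx = int(np.flatnonzero(in_win)[np.argmax(inten[in_win])])
    segment = max(segments,
                  key=lambda seg: (apex_idx in seg, inten[seg].max(), len(seg)))
    area = float(np.trapezoid(inten[segment] - baseline, rt[segment]))
    detected = bool((inten[segment] > baseline + 3.0 * mad).any()) and area > 0
    return IntegrationResult(
        analyte.name, max(area, 0.0), float(rt[apex_idx]), detected)


def confirm_fragment(run: SpectrumRun, analyte: AnalyteDefinition,
                     precursor_tol_ppm: float = 10.0,
                     fragment_tol_mz: float = 0.005) -> FragmentCheck:
    """Look for the qualifier fragment in MS2 scans of the analyte.

    True iff some MS2 scan whose precursor lies within
    ``precursor_tol_ppm`` of the analyte's theoretical m/z contains a
    centroid within ``fragment_tol_mz`` (absolute Da; the qualifier is
    low-mass, where ppm windows become sub-millidalton) of the qualifier
    m/z.  A run without MS2 scans is reported as not acquired.
    """
    ms2 = run.ms2()
    if not ms2:
        return FragmentCheck(confirmed=False, acquired=False)
    for scan in ms2:
        if scan.precursor_mz is None:
            continue
        if abs(ppm_difference(scan.precursor_mz, analyte.mz_theoretical)) \
                > precursor_tol_ppm:
            continue
        if np.any(np.abs(scan.mz - analyte.qualifier_fragment_mz)
                  <= fragment_tol_mz):
            return FragmentCheck(confirmed=True, acquired=True)
    return FragmentCheck(confirmed=False, acquired=True)


def extract_analyte(run: SpectrumRun, analyte: AnalyteDefinition,
                    tol_ppm: float = 5.0) -> IntegrationResult:
    """XIC + integration + fragment confirmation for one analyte."""
    result = integrate_peak(build_xic(run, analyte, tol_ppm), analyte)
    frag = confirm_fragment(run, analyte)
    result.fragment_confirmed = frag.confirmed
    result.fragment_acquired = frag.acquired
    return result


def quantify_solanidine(area: float,
                        calibration_points: list[tuple[float, float]]) -> float:
    """Map a peak area to nmol/L through a straight calibration line.

    The line (free intercept) is fitted by ordinary least squares to
    >= 2 calibrator (concentration, area) points — routine practice is
    three calibrators spanning 2-60 nmol/L — then inverted.  Negative
    predictions are clipped to zero with a warning.
    """
    pts = np.asarray(calibration_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two calibration points")
    conc, cal_area = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("calibration concentrations must not be identical")
    slope, intercept = np.polyfit(conc, cal_area, 1)
    value = (area - intercept) / slope
    if value < 0:
        warnings.warn(
            f"area {area} maps to negative concentration {value:.3g}; "
            "clipped to 0", stacklevel=2)
        return 0.0
    return float(value)


# ---------------------------------------------------------------------------
# mzML input/output
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_params(element) -> dict[str, dict]:
    return {cv.get("accession"): cv.attrib
            for cv in element.iter(f"{_NS}cvParam")}


def _decode_binary(array_element) -> tuple[str, np.ndarray]:
    params = _cv_params(array_element)
    binary = array_element.find(f"{_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = ("mz" if _ACC_MZ_ARRAY in params
            else "intensity" if _ACC_INT_ARRAY in params else "other")
    return kind, values


def _parse_spectrum(element) -> Scan:
    level, rt, precursor = 1, 0.0, None
    for cv in element.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_MS_LEVEL:
            level = int(cv.get("value"))
        elif acc == _ACC_SCAN_START:
            rt = float(cv.get("value"))
            if cv.get("unitName", "minute").startswith("second"):
                rt /= 60.0
        elif acc == _ACC_SELECTED_MZ:
            precursor = float(cv.get("value"))
    arrays = dict(
        _decode_binary(arr)
        for arr in element.iter(f"{_NS}binaryDataArray"))
    return Scan(rt=rt, ms_level=level,
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
                precursor_mz=precursor if level == 2 else None)


def read_mzml(path: str, run_id: str | None = None) -> SpectrumRun:
    """Read a centroided mzML file into a SpectrumRun.

    A purpose-built streaming parser for the subset of mzML this
    pipeline consumes: ms level, scan start time (minutes or seconds),
    MS2 selected-ion m/z, and 32/64-bit float m/z / intensity arrays
    with optional zlib compression.
    """
    scans: list[Scan] = []
    for event, element in _ET.iterparse(str(path), events=("end",)):
        if element.tag == f"{_NS}spectrum":
            scans.append(_parse_spectrum(element))
            element.clear()
    return SpectrumRun(scans, run_id or str(path))


def _encode_array(values: np.ndarray, dtype: str) -> str:
    packed = struct.pack(f"<{len(values)}{dtype}", *values)
    return base64.b64encode(zlib.compress(packed)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: SpectrumRun, path: str) -> None:
    """Write a SpectrumRun as minimal centroided mzML.

    Intended for synthetic test fixtures; emits only the elements the
    reader needs (ms level, scan start time, precursor for MS2, and
    zlib-compressed 64-bit m/z / intensity arrays).
    """
    chunks = [_MZML_HEADER.format(run_id=run.run_id, count=len(run.scans))]
    for i, scan in enumerate(run.scans):
        mz_b64 = _encode_array(scan.mz, "d")
        int_b64 = _encode_array(scan.intensity, "d")
        precursor = ""
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            precursor = f"""        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan.precursor_mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
"""
        chunks.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan.mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    chunks.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(chunks))


@dataclass
class GaussianPeak:
    """A synthetic chromatographic peak for the fixture generator."""

    mz: float
    rt: float  # apex, minutes
    amplitude: float
    sigma: float = 0.05  # minutes
    mz_error_ppm: float = 0.0

    @property
    def analytic_area(self) -> float:
        """Closed-form area amplitude * sigma * sqrt(2*pi)."""
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


def make_synthetic_run(
    peaks: list[GaussianPeak],
    rt_grid: np.ndarray | None = None,
    ms2: list[Scan] | None = None,
    noise_mz: float = 500.0,
    noise_intensity: float = 0.0,
    run_id: str = "synthetic",
) -> SpectrumRun:
    """Build a synthetic centroided run containing Gaussian peaks.

    Each MS1 scan holds one centroid per peak (intensity following the
    peak's Gaussian elution profile, m/z offset by ``mz_error_ppm``)
    plus an optional constant far-away noise centroid.  MS2 scans are
    appended as given, re-sorted into retention-time order.
    """
    if rt_grid is None:
        rt_grid = np.arange(0.0, 10.0, 0.02)
    scans: list[Scan] = []
    for rt in rt_grid:
        mzs, intens = [], []
        for p in peaks:
            mzs.append(p.mz * (1.0 + p.mz_error_ppm * 1e-6))
            intens.append(p.amplitude * np.exp(-0.5 * ((rt - p.rt) / p.sigma) ** 2))
        if noise_intensity > 0:
            mzs.append(noise_mz)
            intens.append(noise_intensity)
        order = np.argsort(mzs)
        scans.append(Scan(rt=float(rt), ms_level=1,
                          mz=np.asarray(mzs)[order],
                          intensity=np.asarray(intens)[order]))
    if ms2:
        scans.extend(ms2)
        scans.sort(key=lambda s: s.rt)
    return SpectrumRun(scans, run_id)
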