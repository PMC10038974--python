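"""Truncation of undetected analytes and ln metabolic-ratio computation.

Undetected peak areas are truncated to half the minimum detected area of
the corresponding analyte so metabolic ratios stay defined; the
published analysis used per-analyte truncation constants derived this
way (solanidine 1278, M402 970, M412 798, M414 782, M416 1117, M432 844,
M440 963, M444 629 area units), available here as
``PUBLISHED_TRUNCATION`` for reproducing worked examples.

A patient is excluded from metabolite m's analyses only when solanidine
AND metabolite m are both undetected; detection of other metabolites is
irrelevant, so the included n varies per metabolite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth_cohort import ANALYTES, AREA_PER_NMOL, LN_SOLA_CONC, METABOLITES

__all__ = [
    "PUBLISHED_TRUNCATION",
    "derive_truncation",
    "derive_truncation_table",
    "compute_ratios",
]

#: Published half-minimum truncation constants (peak-area units).
PUBLISHED_TRUNCATION: dict[str, float] = {
    "SOLA": 1278.0, "M402": 970.0, "M412": 798.0, "M414": 782.0,
    "M416": 1117.0, "M432": 844.0, "M440": 963.0, "M444": 629.0,
}


def derive_truncation(areas, detected) -> float:
    """Half the minimum detected area of one analyte across patients."""
    areas = np.asarray(areas, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if areas.shape != detected.shape:
        raise ValueError("areas and detected flags must align")
    if not detected.any():
        raise ValueError(
            "analyte has no detected measurements; no truncation value "
            "can be derived and the analyte is unusable")
    return float(areas[detected].min()) / 2.0


def derive_truncation_table(records: pd.DataFrame) -> dict[str, float]:
    """Per-analyte truncation constants derived from a patient table."""
    return {
        a: derive_truncation(records[f"area_{a}"], records[f"detected_{a}"])
        for a in ANALYTES
    }


def compute_ratios(
    records: pd.DataFrame,
    truncation: dict[str, float] | None = None,
    area_per_nmol: float = AREA_PER_NMOL,
) -> pd.DataFrame:
    """Ln metabolic ratios with truncation and per-analysis inclusion flags.

    Adds, per metabolite m: ``lnMR_m`` = ln(area_m / area_SOLA) after
    truncating undetected areas, and ``include_m`` (False iff solanidine
    and m are both undetected).  ``ln_sola_conc`` is recomputed from the
    (truncated) solanidine area through the area-to-concentration scale;
    ``include_conc`` is False only when every analyte is undetected.
    Covariate and genotype columns are carried through.

    Parameters
    ----------
    truncation
        Per-analyte constants; derived from the data (half-minimum rule)
        when None.  Pass ``PUBLISHED_TRUNCATION`` to pin the published
        values.
    area_per_nmol
        Peak-area units per nmol/L for the solanidine concentration
        scale (the slope of a zero-intercept calibration line).
    """
    if truncation is None:
        truncation = derive_truncation_table(records)
    missing = [a for a in ANALYTES if a not in truncation]
    if missing:
        raise ValueError(f"truncation constants missing for: {missing}")
    if any(truncation[a] <= 0 for a in ANALYTES):
        raise ValueError("truncation constants must be positive")

    out = records.copy()
    used = {}
    for a in ANALYTES:
        area = out[f"area_{a}"].to_numpy(dtype=float)
        det = out[f"detected_{a}"].to_numpy(dtype=bool)
        used[a] = np.where(det, area, truncation[a])
        if (used[a] <= 0).any():
            raise ValueError(f"non-positive {a} areas remain after truncation")

    for m in METABOLITES:
        out[f"lnMR_{m}"] = np.log(used[m] / used["SOLA"])
        out[f"include_{m}"] = (
            out[f"detected_{m}"] | out["detected_SOLA"]).to_numpy()
    out[LN_SOLA_CONC] = np.log(used["SOLA"] / area_per_nmol)
    out["include_conc"] = np.logical_or.reduce(
        [out[f"detected_{a}"].to_numpy() for a in ANALYTES])
    return out
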