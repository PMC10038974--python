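"""End-to-end orchestration: ingest/generate -> ratios -> split -> ROC ->
validate -> regression, with provenance and per-stage exclusion logging.

The interchange format between all stages is one tidy patient table
(one row per patient) with columns: ``id``, ``cyp2d6_diplotype``,
``genotype_group``, ``phenotype``, ``sex`` (F/M), ``age`` (years),
``inhibitor_user`` (bool), ``area_<analyte>``, ``detected_<analyte>``
and ``solanidine_conc`` (nmol/L).  mzML ingestion is a front-end that
produces this table; the synthetic generator produces it directly.

Exclusion ladder (each step counted in the run summary):
age outside 18-65 -> out of the study; CYP2D6-inhibitor users -> out of
the cohorts but retained for the inhibitor comparison; inconclusive
genotypes -> split normally but ineligible for ROC and regression;
per-metabolite detection rule -> row-wise inclusion flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, ratios, regression, split as split_mod
from .classify import Direction
from .genotypes import Phenotype, annotate_genotypes
from .synth_cohort import (
    ANALYTES,
    AREA_PER_NMOL,
    LN_SOLA_CONC,
    METABOLITES,
    OUTCOMES,
    GeneratorConfig,
    generate_cohort,
)

__all__ = [
    "MARKER_DIRECTIONS",
    "AGE_BOUNDS",
    "RunConfig",
    "run_all",
    "pin_thresholds",
    "read_patient_table",
    "write_patient_table",
]

#: Prediction direction per marker: metabolic ratios are low in PMs
#: (no metabolite formation); the parent compound accumulates.
MARKER_DIRECTIONS: dict[str, Direction] = {
    **{f"lnMR_{m}": Direction.LOW_PREDICTS_PM for m in METABOLITES},
    LN_SOLA_CONC: Direction.HIGH_PREDICTS_PM,
}

AGE_BOUNDS = (18.0, 65.0)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one input source must be set: ``generator`` (synthetic
    cohort), or ``table_path`` (delimited patient table).  When
    ``pinned_thresholds`` is given the ROC derivation is skipped and the
    supplied thresholds are evaluated instead.
    """

    generator: GeneratorConfig | None = None
    table_path: str | None = None
    seed: int = 0
    markers: list[str] = field(
        default_factory=lambda: list(MARKER_DIRECTIONS))
    pinned_thresholds: dict[str, float] | None = None
    truncation: dict[str, float] | None = None  # None -> derive from data
    area_per_nmol: float = AREA_PER_NMOL
    output_dir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.generator, self.table_path)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be configured")
        unknown = [m for m in self.markers if m not in MARKER_DIRECTIONS]
        if unknown:
            raise ValueError(f"markers without a known direction: {unknown}")


def read_patient_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for a in ANALYTES:
        col = f"detected_{a}"
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "inhibitor_user" in df.columns:
        df["inhibitor_user"] = df["inhibitor_user"].astype(bool)
    return df


def write_patient_table(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    """Write the canonical patient table; the seed is recorded in a header."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.generator is not None:
        return generate_cohort(config.generator)
    df = read_patient_table(config.table_path)
    if "genotype_group" not in df.columns or "phenotype" not in df.columns:
        df = annotate_genotypes(df)
    return df


def _evaluation_record(marker, threshold, direction, ev) -> dict:
    return {
        "marker": marker,
        "direction": direction.value,
        "threshold": threshold,
        "tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
        "sensitivity": ev.sensitivity,
        "specificity": ev.specificity,
        "ppv_percent": 100.0 * ev.ppv,
        "npv_percent": 100.0 * ev.npv,
        "mcc": ev.mcc,
        "flags": ev.flags,
    }


def pin_thresholds(
    ratio_table: pd.DataFrame,
    thresholds: dict[str, float],
    directions: dict[str, Direction] | None = None,
) -> dict[str, dict]:
    """Evaluate externally supplied thresholds on one cohort.

    ``ratio_table`` must carry lnMR / ln-concentration columns, inclusion
    flags and phenotypes; inconclusive genotypes are excluded.  Returns
    one confusion-metric record per marker.
    """
    directions = directions or MARKER_DIRECTIONS
    eligible = ratio_table[
        ratio_table["phenotype"] != Phenotype.INCONCLUSIVE.value]
    out = {}
    for marker, thr in thresholds.items():
        if marker not in directions:
            raise ValueError(f"marker {marker} has no configured direction")
        direction = directions[marker]
        inc = regression._inclusion_mask(eligible, marker)
        sub = eligible.loc[inc]
        ev = classify.evaluate_threshold(
            sub[marker], sub["phenotype"].eq(Phenotype.PM.value),
            thr, direction)
        out[marker] = _evaluation_record(marker, thr, direction, ev)
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) a report.

    Stages: input -> genotype annotation -> age exclusion -> truncation
    and ln ratios -> inhibitor set-aside -> stratified 4:1 split -> ROC
    with optimal thresholds on the test cohort (or pinned thresholds)
    -> threshold evaluation on the validation cohort -> cohort balance
    -> regression, Dunnett contrasts and inhibitor t-tests.  Identical
    configs (including seeds) produce identical reports.
    """
    raw = _load_input(config)
    n_input = len(raw)

    age_ok = raw["age"].between(*AGE_BOUNDS)
    study = raw.loc[age_ok].copy()
    exclusions = {"age_out_of_range": int((~age_ok).sum())}

    ratio_table = ratios.compute_ratios(
        study, truncation=config.truncation, area_per_nmol=config.area_per_nmol)
    derived_truncation = (config.truncation
                          or ratios.derive_truncation_table(study))

    inhibitor = ratio_table["inhibitor_user"].astype(bool)
    cohort_pool = ratio_table.loc[~inhibitor]
    exclusions["inhibitor_users"] = int(inhibitor.sum())
    exclusions["inconclusive_genotype_in_pool"] = int(
        cohort_pool["phenotype"].eq(Phenotype.INCONCLUSIVE.value).sum())

    cohort_split = split_mod.stratified_split(cohort_pool, seed=config.seed)
    assignment = cohort_split.assignment()
    cohort_pool = cohort_pool.set_index("id", drop=False)
    test = cohort_pool.loc[assignment.index[assignment == "test"]]
    validation = cohort_pool.loc[assignment.index[assignment == "validation"]]

    balance = split_mod.compare_cohorts(test, validation)

    test_eligible = test[test["phenotype"] != Phenotype.INCONCLUSIVE.value]
    roc_results: dict[str, classify.RocResult] = {}
    thresholds: dict[str, float] = {}
    test_eval: dict[str, dict] = {}
    if config.pinned_thresholds is None:
        for marker in config.markers:
            direction = MARKER_DIRECTIONS[marker]
            inc = regression._inclusion_mask(test_eligible, marker)
            sub = test_eligible.loc[inc]
            labels = sub["phenotype"].eq(Phenotype.PM.value)
            roc = classify.roc_curve(sub[marker], labels, direction, marker)
            classify.optimal_threshold(roc)
            roc.auc_ci95 = classify.auc_ci(sub[marker], labels, direction)
            roc.p_vs_chance = classify.delong_p_vs_chance(
                sub[marker], labels, direction)
            roc_results[marker] = roc
            thresholds[marker] = roc.threshold_opt
        test_eval = pin_thresholds(test, thresholds)
    else:
        thresholds = dict(config.pinned_thresholds)
        test_eval = pin_thresholds(test, thresholds)
    validation_eval = pin_thresholds(validation, thresholds)

    fits = {outcome: regression.fit_genotype_model(test, outcome)
            for outcome in OUTCOMES}
    best_outcome = max(
        (o for o in fits if o != LN_SOLA_CONC), key=lambda o: fits[o].r_squared)
    dunnett = regression.anova_dunnett(
        test[test["phenotype"] != Phenotype.INCONCLUSIVE.value], best_outcome)

    inhibitor_report = None
    if inhibitor.any():
        pool = pd.concat([ratio_table.loc[inhibitor], test], ignore_index=True)
        inhibitor_report = regression.inhibitor_comparison(pool)

    report = {
        "seed": config.seed,
        "n_input": n_input,
        "exclusions": exclusions,
        "truncation": derived_truncation,
        "split": {
            "strata": cohort_split.strata,
            "n_test": len(test),
            "n_validation": len(validation),
        },
        "thresholds": thresholds,
        "roc": {
            m: {
                "auc": r.auc,
                "auc_ci95": r.auc_ci95,
                "p_vs_chance": r.p_vs_chance,
                "threshold_opt": r.threshold_opt,
                "sens_at_opt": r.sens_at_opt,
                "spec_at_opt": r.spec_at_opt,
                "degenerate": r.degenerate,
            }
            for m, r in roc_results.items()
        },
        "test_evaluation": test_eval,
        "validation_evaluation": validation_eval,
        "regression": {
            o: {
                "n": f.n,
                "r_squared": f.r_squared,
                "r_squared_adj": f.r_squared_adj,
                "coefficients": {
                    t: {"B": b, "SE": se, "p": p}
                    for t, (b, se, p) in f.coefficients.items()
                },
                "dropped_terms": f.dropped_terms,
                "age_center": f.age_center,
            }
            for o, f in fits.items()
        },
        "anova_dunnett": dunnett,
        "inhibitor_comparison": (
            inhibitor_report.to_dict(orient="records")
            if inhibitor_report is not None else None),
    }

    if config.output_dir is not None:
        _write_outputs(config, report, ratio_table, assignment, balance,
                       roc_results)
    return report


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def _write_outputs(config, report, ratio_table, assignment, balance,
                   roc_results) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = ratio_table.merge(
        assignment.rename("cohort"), left_on="id", right_index=True, how="left")
    write_patient_table(table, out / "ratio_table.csv", seed=config.seed)
    balance.to_csv(out / "cohort_balance.csv", index=False)
    for marker, roc in roc_results.items():
        pd.DataFrame({
            "threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr,
        }).to_csv(out / f"roc_{marker}.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder)
    if config.make_plots and roc_results:
        classify.plot_roc(list(roc_results.values()), str(out / "roc.png"))
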