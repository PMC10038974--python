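"""Stratified 4:1 test/validation randomization and cohort balance checks.

The split stratifies on the genotype-predicted PM and UM phenotypes
(everyone else forms a third stratum) so both cohorts keep the rare
phenotypes in proportion; the validation share of each stratum is the
round-half-up nearest integer to n/5, which reproduces 46/12 for the 58
eligible PMs.  Balance between cohorts is checked with Student's t-tests
for continuous variables and two-sided Fisher's exact tests for
proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Phenotype
from .synth_cohort import ANALYTES, GENOTYPE_COUNTS

__all__ = [
    "CohortSplit",
    "validation_share",
    "stratified_split",
    "fisher_exact_2x2",
    "compare_cohorts",
]


@dataclass
class CohortSplit:
    test_ids: list[str]
    validation_ids: list[str]
    strata: dict[str, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0

    def assignment(self) -> pd.Series:
        s = pd.Series(index=self.test_ids + self.validation_ids, dtype=object)
        s.loc[self.test_ids] = "test"
        s.loc[self.validation_ids] = "validation"
        s.name = "cohort"
        return s


def validation_share(n: int, ratio: int = 5) -> int:
    """Validation count for a stratum of n: nearest n/ratio, half up."""
    return int(math.floor(n / ratio + 0.5))


def _stratum(phenotype: str) -> str:
    if phenotype == Phenotype.PM.value:
        return "PM"
    if phenotype == Phenotype.UM.value:
        return "UM"
    return "other"


def stratified_split(
    records: pd.DataFrame, seed: int, ratio: int = 5,
) -> CohortSplit:
    """Randomize patients 4:1 into test/validation within PM/UM/other strata.

    CYP2D6-inhibitor users must already be excluded.  Inconclusive
    genotypes are split like everyone else (callers flag them
    analysis-ineligible downstream).  Reproducible under ``seed``.
    """
    if records["inhibitor_user"].any():
        raise ValueError("exclude CYP2D6-inhibitor users before splitting")
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    val_ids: list[str] = []
    strata: dict[str, tuple[int, int]] = {}
    strat = records["phenotype"].map(_stratum)
    for name in ("PM", "UM", "other"):
        ids = records.loc[strat == name, "id"].to_numpy()
        n_val = validation_share(len(ids), ratio)
        perm = rng.permutation(len(ids))
        val_ids.extend(ids[perm[:n_val]])
        test_ids.extend(ids[perm[n_val:]])
        strata[name] = (len(ids) - n_val, n_val)
    return CohortSplit(test_ids, val_ids, strata, seed)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sided by the tail-sum definition: the sum of probabilities of
    all tables (with the observed margins) no more probable than the
    observed one — the convention scipy implements.
    """
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def compare_cohorts(test: pd.DataFrame, validation: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics balance report (one row per comparison).

    Student's (equal-variance) t-tests for age and solanidine
    concentration; Fisher's exact tests for the sex split, each genotype
    group versus the rest, and (when detection flags are present) each
    analyte's undetected proportion.  Zero-variance continuous variables
    yield an undefined (NaN) p, reported as such.
    """
    if len(test) == 0 or len(validation) == 0:
        raise ValueError("both cohorts must be non-empty")
    rows = []

    for var in ("age", "solanidine_conc"):
        a, b = test[var].to_numpy(float), validation[var].to_numpy(float)
        if np.var(a) == 0 and np.var(b) == 0:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append({"variable": var, "test": f"{a.mean():.3g} ({a.std(ddof=1):.3g})",
                     "validation": f"{b.mean():.3g} ({b.std(ddof=1):.3g})",
                     "p_value": p})

    def _fisher_row(name, in_test, in_val):
        tbl = [[int(in_test.sum()), int((~in_test).sum())],
               [int(in_val.sum()), int((~in_val).sum())]]
        rows.append({"variable": name,
                     "test": f"{tbl[0][0]}/{tbl[0][1]}",
                     "validation": f"{tbl[1][0]}/{tbl[1][1]}",
                     "p_value": fisher_exact_2x2(tbl)})

    _fisher_row("sex (F/M)", test["sex"].eq("F"), validation["sex"].eq("F"))
    for group in (g.value for g in GENOTYPE_COUNTS):
        _fisher_row(f"genotype {group}",
                    test["genotype_group"].eq(group),
                    validation["genotype_group"].eq(group))
    if "detected_SOLA" in test.columns:
        for a in ANALYTES:
            _fisher_row(f"undetected {a}",
                        ~test[f"detected_{a}"], ~validation[f"detected_{a}"])
    return pd.DataFrame(rows)
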