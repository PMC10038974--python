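"""Genotype-effect linear models, Dunnett contrasts and inhibitor t-tests.

``fit_genotype_model`` reproduces the published modelling choices:
ordinary least squares of one ln-scale outcome on sex, centered age and
six genotype-group dummies (reference: female, mean age, *1/*1), with
the genotype-contrast p-values Bonferroni-multiplied by the number of
genotype terms.  Inconclusive-genotype patients and rows excluded by the
per-metabolite detection rule never enter the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeGroup, Phenotype
from .synth_cohort import LN_SOLA_CONC

__all__ = [
    "GENOTYPE_TERMS",
    "RegressionFit",
    "fit_genotype_model",
    "anova_dunnett",
    "inhibitor_comparison",
]

#: Genotype dummy terms in reporting order (reference *1/*1 omitted).
GENOTYPE_TERMS: tuple[GenotypeGroup, ...] = (
    GenotypeGroup.STAR1_xN,
    GenotypeGroup.STAR1_RED,
    GenotypeGroup.STAR1_DEF,
    GenotypeGroup.RED_RED,
    GenotypeGroup.DEF_RED,
    GenotypeGroup.DEF_DEF,
)


@dataclass
class RegressionFit:
    outcome: str
    n: int
    coefficients: dict[str, tuple[float, float, float]]  # term -> (B, SE, p)
    r_squared: float
    r_squared_adj: float
    reference: str = "female, mean age, *1/*1"
    dropped_terms: list[str] = field(default_factory=list)
    age_center: float = float("nan")


def _inclusion_mask(table: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == LN_SOLA_CONC:
        col = "include_conc"
    else:
        col = "include_" + outcome.removeprefix("lnMR_")
    if col in table.columns:
        return table[col].astype(bool)
    return pd.Series(True, index=table.index)


def fit_genotype_model(ratio_table: pd.DataFrame, outcome: str) -> RegressionFit:
    """OLS of an ln-scale outcome on sex, centered age and genotype dummies.

    Rows with inconclusive genotype or an inclusion flag of False are
    excluded; age is centered on the analysis sample mean.  Genotype
    p-values are Bonferroni-adjusted (x number of genotype terms, capped
    at 1); sex and age p-values are unadjusted.  Empty genotype cells
    are dropped from the design with a warning.
    """
    mask = (ratio_table["phenotype"] != Phenotype.INCONCLUSIVE.value) \
        & _inclusion_mask(ratio_table, outcome)
    data = ratio_table.loc[mask]
    if len(data) == 0:
        raise ValueError(f"no rows available for outcome {outcome}")

    age_center = float(data["age"].mean())
    design = pd.DataFrame({
        "intercept": 1.0,
        "male": data["sex"].eq("M").astype(float),
        "age_centered": data["age"] - age_center,
    }, index=data.index)
    dropped = []
    genotype_cols = []
    for g in GENOTYPE_TERMS:
        col = data["genotype_group"].eq(g.value).astype(float)
        if col.sum() == 0:
            dropped.append(g.value)
            warnings.warn(f"genotype cell {g.value} empty; term dropped",
                          stacklevel=2)
            continue
        design[g.value] = col
        genotype_cols.append(g.value)

    fit = sm.OLS(data[outcome].to_numpy(float), design.to_numpy(float)).fit()
    n_tests = len(genotype_cols)
    coefficients = {}
    for i, term in enumerate(design.columns):
        p = float(fit.pvalues[i])
        if term in genotype_cols:
            p = min(1.0, n_tests * p)
        coefficients[term] = (float(fit.params[i]), float(fit.bse[i]), p)
    return RegressionFit(
        outcome=outcome,
        n=int(fit.nobs),
        coefficients=coefficients,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        dropped_terms=dropped,
        age_center=age_center,
    )


def anova_dunnett(
    ratio_table: pd.DataFrame,
    outcome: str,
    control: GenotypeGroup = GenotypeGroup.STAR1_STAR1,
    n_mc: int = 100_000,
    seed: int = 12061922,
) -> dict:
    """One-way ANOVA across genotype groups with Dunnett-adjusted contrasts.

    Each genotype group is compared to the control (*1/*1 by default)
    with pooled-variance t statistics; the many-to-one multiplicity
    adjustment evaluates the null distribution of max |t| by Monte Carlo
    (group means ~ N(0, 1/n_i), pooled variance ~ chi^2/df, which is
    exact under normality).  Groups with < 2 members are excluded with a
    warning.  Returns the F test and per-group adjusted p-values.
    """
    mask = _inclusion_mask(ratio_table, outcome)
    data = ratio_table.loc[mask]
    samples: dict[str, np.ndarray] = {}
    for g, sub in data.groupby("genotype_group"):
        y = sub[outcome].to_numpy(float)
        if len(y) < 2:
            warnings.warn(f"group {g} has < 2 members; excluded", stacklevel=2)
            continue
        samples[g] = y
    if control.value not in samples:
        raise ValueError(f"control group {control.value} missing or too small")
    if len(samples) < 2:
        raise ValueError("need at least two groups including the control")

    groups = [g for g in samples if g != control.value]
    y0 = samples[control.value]
    f_stat, f_p = stats.f_oneway(*samples.values())

    ns = np.array([len(samples[g]) for g in groups])
    n0 = len(y0)
    df_resid = sum(len(v) for v in samples.values()) - len(samples)
    pooled_var = sum(np.sum((v - v.mean()) ** 2) for v in samples.values()) / df_resid
    t_obs = np.array([
        (samples[g].mean() - y0.mean())
        / np.sqrt(pooled_var * (1 / len(samples[g]) + 1 / n0))
        for g in groups
    ])

    rng = np.random.default_rng(seed)
    z0 = rng.normal(0, 1, size=n_mc) / np.sqrt(n0)
    zi = rng.normal(0, 1, size=(n_mc, len(groups))) / np.sqrt(ns)
    s2 = rng.chisquare(df_resid, size=n_mc) / df_resid
    t_null = (zi - z0[:, None]) / np.sqrt(s2[:, None] * (1 / ns + 1 / n0))
    max_abs = np.abs(t_null).max(axis=1)
    adj_p = {g: float(np.mean(max_abs >= abs(t)))
             for g, t in zip(groups, t_obs)}
    return {
        "outcome": outcome,
        "control": control.value,
        "f_statistic": float(f_stat),
        "f_p_value": float(f_p),
        "t_statistics": dict(zip(groups, t_obs.tolist())),
        "adjusted_p": adj_p,
        "n_mc": n_mc,
        "seed": seed,
    }


def inhibitor_comparison(
    ratio_table: pd.DataFrame,
    outcomes: list[str] | None = None,
    reference_group: GenotypeGroup = GenotypeGroup.STAR1_STAR1,
) -> pd.DataFrame:
    """Student t-tests of inhibitor users vs non-users among *1/*1 carriers.

    Compares, per outcome, ln-scale means of CYP2D6-inhibitor users
    carrying the reference genotype against non-using carriers of the
    same genotype.  Returns means, difference and the two-sided
    equal-variance p-value; groups with n < 2 yield NaN p, reported.
    """
    carriers = ratio_table[ratio_table["genotype_group"].eq(reference_group.value)]
    users = carriers[carriers["inhibitor_user"].astype(bool)]
    nonusers = carriers[~carriers["inhibitor_user"].astype(bool)]
    if len(users) == 0 or len(nonusers) == 0:
        raise ValueError("both inhibitor users and non-users are required")
    if outcomes is None:
        outcomes = [c for c in ratio_table.columns
                    if c.startswith("lnMR_") or c == LN_SOLA_CONC]
    rows = []
    for outcome in outcomes:
        inc_u = users.loc[_inclusion_mask(users, outcome), outcome].to_numpy(float)
        inc_n = nonusers.loc[_inclusion_mask(nonusers, outcome), outcome].to_numpy(float)
        if len(inc_u) < 2 or len(inc_n) < 2:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(inc_u, inc_n, equal_var=True).pvalue)
        rows.append({
            "outcome": outcome,
            "n_users": len(inc_u),
            "n_nonusers": len(inc_n),
            "mean_users": float(np.mean(inc_u)) if len(inc_u) else float("nan"),
            "mean_nonusers": float(np.mean(inc_n)) if len(inc_n) else float("nan"),
            "difference": (float(np.mean(inc_u) - np.mean(inc_n))
                           if len(inc_u) and len(inc_n) else float("nan")),
            "p_value": p,
        })
    return pd.DataFrame(rows)
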