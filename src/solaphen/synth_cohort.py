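"""Synthetic patient cohorts for solanidine-based CYP2D6 phenotyping.

Generates cohorts whose genotype mix, covariates, ln metabolic ratios
(lnMR = ln of metabolite-to-solanidine peak-area ratio), ln solanidine
concentration, peak areas and non-detection pattern follow the structure
of the published 839-patient TDM dataset, so that every downstream stage
(truncation, ratios, splitting, ROC, regression) has a self-contained,
seeded test input.

Model
-----
For each outcome y (seven lnMRs and the ln solanidine concentration,
nmol/L) a patient's value is drawn from the fitted multiple linear
regression

    y = intercept + B_male * male + B_age * (age - mean age)
        + B_genotype[group] + e,      e ~ N(0, sigma^2)

with the published coefficient estimates as truth (reference level:
female, mean age, *1/*1).  The residual SD sigma is not published
directly; it is calibrated from the published model R^2 via

    sigma^2 = Var(X beta) * (1 - R^2) / R^2

where Var(X beta) is the variance of the linear predictor under the
cohort's genotype/sex/age mixture (conclusive genotypes only, the
population the regression was fitted on).  Residuals are homoscedastic
on the ln scale and independent across outcomes given the covariates.

Peak areas are reconstructed as
    area_solanidine = concentration * AREA_PER_NMOL
    area_metabolite = area_solanidine * exp(lnMR)
and non-detection is imposed by per-analyte limits of detection (LOD)
calibrated once to the published detection fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeGroup, Phenotype, parse_diplotype, phenotype_of

__all__ = [
    "ANALYTES",
    "METABOLITES",
    "OUTCOMES",
    "LN_SOLA_CONC",
    "GENOTYPE_COUNTS",
    "DEFAULT_GENOTYPE_PROBS",
    "DEFAULT_FEMALE_PROB",
    "DEFAULT_AGE_MEAN",
    "DEFAULT_AGE_SD",
    "AGE_RANGE",
    "AREA_PER_NMOL",
    "DETECTION_FRACTIONS",
    "DEFAULT_LOD",
    "CONCLUSIVE_GROUPS",
    "INCONCLUSIVE_PROXY",
    "REPRESENTATIVE_DIPLOTYPES",
    "LinearModelParams",
    "GeneratorConfig",
    "published_model_params",
    "truncated_age_moments",
    "linear_predictor_variance",
    "residual_sd_from_variance",
    "calibrate_residual_sd",
    "generate_cohort",
    "apply_lod",
    "calibrate_lod",
]

#: Analyte short names; metabolites are labelled by nominal mass.
ANALYTES: tuple[str, ...] = (
    "SOLA", "M402", "M412", "M414", "M416", "M432", "M440", "M444",
)
METABOLITES: tuple[str, ...] = ANALYTES[1:]

LN_SOLA_CONC = "ln_sola_conc"
#: Model outcomes: seven ln metabolic ratios plus ln solanidine conc.
OUTCOMES: tuple[str, ...] = tuple(f"lnMR_{m}" for m in METABOLITES) + (LN_SOLA_CONC,)

#: Genotype-group counts in the combined test+validation cohorts (n=839).
GENOTYPE_COUNTS: dict[GenotypeGroup, int] = {
    GenotypeGroup.STAR1_xN: 26,
    GenotypeGroup.STAR1_STAR1: 348,
    GenotypeGroup.STAR1_RED: 101,
    GenotypeGroup.STAR1_DEF: 231,
    GenotypeGroup.RED_RED: 17,
    GenotypeGroup.DEF_RED: 36,
    GenotypeGroup.DEF_DEF: 58,
    GenotypeGroup.STAR1_RED_xN: 8,
    GenotypeGroup.STAR1_DEF_xN: 8,
    GenotypeGroup.RED_DEF_xN: 6,
}

_N_TOTAL = sum(GENOTYPE_COUNTS.values())  # 839

DEFAULT_GENOTYPE_PROBS: dict[GenotypeGroup, float] = {
    g: c / _N_TOTAL for g, c in GENOTYPE_COUNTS.items()
}

DEFAULT_FEMALE_PROB = 341 / 839  # 283+58 females of 839
DEFAULT_AGE_MEAN = 41.3
DEFAULT_AGE_SD = 11.0
AGE_RANGE = (18.0, 65.0)

#: Arbitrary chromatographic response: peak-area units per nmol/L solanidine.
AREA_PER_NMOL = 1000.0

#: Published per-analyte detection fractions in the full sample set.
DETECTION_FRACTIONS: dict[str, float] = {
    "SOLA": 0.76, "M402": 0.71, "M412": 0.42, "M414": 0.91,
    "M416": 0.87, "M432": 0.98, "M440": 0.61, "M444": 0.71,
}

#: Genotype groups entering the regression / ROC analyses.
CONCLUSIVE_GROUPS: tuple[GenotypeGroup, ...] = (
    GenotypeGroup.STAR1_xN,
    GenotypeGroup.STAR1_STAR1,
    GenotypeGroup.STAR1_RED,
    GenotypeGroup.STAR1_DEF,
    GenotypeGroup.RED_RED,
    GenotypeGroup.DEF_RED,
    GenotypeGroup.DEF_DEF,
)

#: Inconclusive duplication groups have no published effect estimate; the
#: generator borrows the effect of the content-matched conclusive group.
INCONCLUSIVE_PROXY: dict[GenotypeGroup, GenotypeGroup] = {
    GenotypeGroup.STAR1_RED_xN: GenotypeGroup.STAR1_RED,
    GenotypeGroup.STAR1_DEF_xN: GenotypeGroup.STAR1_DEF,
    GenotypeGroup.RED_DEF_xN: GenotypeGroup.DEF_RED,
    GenotypeGroup.RED_RED_xN: GenotypeGroup.RED_RED,
    GenotypeGroup.DEF_DEF_xN: GenotypeGroup.DEF_DEF,
}

#: One concrete diplotype per group so the genotype parser is exercised
#: end to end on generated tables.
REPRESENTATIVE_DIPLOTYPES: dict[GenotypeGroup, str] = {
    GenotypeGroup.STAR1_xN: "*1xN/*1",
    GenotypeGroup.STAR1_STAR1: "*1/*1",
    GenotypeGroup.STAR1_RED: "*1/*41",
    GenotypeGroup.STAR1_DEF: "*1/*4",
    GenotypeGroup.RED_RED: "*41/*41",
    GenotypeGroup.DEF_RED: "*4/*41",
    GenotypeGroup.DEF_DEF: "*4/*4",
    GenotypeGroup.STAR1_RED_xN: "*1xN/*41",
    GenotypeGroup.STAR1_DEF_xN: "*1xN/*4",
    GenotypeGroup.RED_DEF_xN: "*41xN/*4",
}


@dataclass
class LinearModelParams:
    """Parameters of one outcome's linear model on the ln scale.

    ``beta_genotype`` maps genotype group -> additive shift relative to
    the *1/*1 reference; ``residual_sd`` may be left None and calibrated
    from ``r_squared_target``.
    """

    intercept: float
    beta_male: float
    beta_age_per_year: float
    beta_genotype: dict[GenotypeGroup, float]
    r_squared_target: float
    residual_sd: float | None = None

    def genotype_effect(self, group: GenotypeGroup) -> float:
        if group == GenotypeGroup.STAR1_STAR1:
            return 0.0
        if group in self.beta_genotype:
            return self.beta_genotype[group]
        proxy = INCONCLUSIVE_PROXY.get(group)
        if proxy is not None:
            return self.beta_genotype.get(proxy, 0.0)
        raise KeyError(f"no genotype effect for {group}")


def _params(intercept, male, age, xn, s1_red, s1_def, red_red, def_red,
            def_def, r2) -> LinearModelParams:
    return LinearModelParams(
        intercept=intercept,
        beta_male=male,
        beta_age_per_year=age,
        beta_genotype={
            GenotypeGroup.STAR1_xN: xn,
            GenotypeGroup.STAR1_RED: s1_red,
            GenotypeGroup.STAR1_DEF: s1_def,
            GenotypeGroup.RED_RED: red_red,
            GenotypeGroup.DEF_RED: def_red,
            GenotypeGroup.DEF_DEF: def_def,
        },
        r_squared_target=r2,
    )


def published_model_params() -> dict[str, LinearModelParams]:
    """Published regression estimates for the eight outcomes (fresh copy).

    Coefficients are unstandardized Bs on the ln scale; reference is a
    female *1/*1 carrier of mean age.  R^2 is the published model R^2.
    """
    return {
        "lnMR_M402": _params(0.51, -0.005, 0.005, 0.93, -0.56, -1.88,
                             -3.87, -3.44, -8.75, 0.371),
        "lnMR_M412": _params(-3.06, 0.073, 0.008, 0.13, -0.20, -0.71,
                             -1.37, -1.04, -5.54, 0.325),
        "lnMR_M414": _params(2.90, 0.039, 0.001, 0.31, -0.27, -0.88,
                             -1.06, -1.87, -11.2, 0.688),
        "lnMR_M416": _params(2.61, -0.006, 0.011, 0.8, -0.38, -1.58,
                             -2.50, -2.92, -10.4, 0.475),
        "lnMR_M432": _params(1.58, 0.22, 0.007, 0.69, -0.27, -1.16,
                             -0.83, -2.04, -4.16, 0.117),
        "lnMR_M440": _params(-0.49, -0.058, 0.003, -0.050, -0.23, -1.50,
                             -1.70, -2.53, -7.71, 0.442),
        "lnMR_M444": _params(0.80, -0.05, 0.013, 0.94, -0.95, -2.32,
                             -3.85, -4.76, -9.38, 0.377),
        LN_SOLA_CONC: _params(-1.01, -0.033, 0.0001, -0.31, 0.16, 0.39,
                              0.57, 0.93, 2.78, 0.227),
    }


#: Per-analyte peak-area limits of detection, calibrated once by
#: simulation (seed 20230220, n = 200000, clean generator defaults) so
#: that the detected fraction of each analyte matches DETECTION_FRACTIONS.
#: See ``calibrate_lod``.  Units: arbitrary peak-area units.
DEFAULT_LOD: dict[str, float] = {
    "SOLA": 181.2,
    "M402": 30.3,
    "M412": 21.7,
    "M414": 59.9,
    "M416": 33.7,
    "M432": 1.2,
    "M440": 48.9,
    "M444": 25.2,
}


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the published population: genotype mix of the
    combined cohorts (n=839, inconclusive duplication groups included),
    female fraction 341/839, age ~ N(41.3, 11.0) truncated to 18-65 y,
    outcome models with published coefficients and residual SDs
    calibrated to the published R^2, LODs reproducing the published
    detection fractions, and no CYP2D6-inhibitor users.
    """

    n_patients: int = 839
    genotype_probs: dict[GenotypeGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROBS))
    female_prob: float = DEFAULT_FEMALE_PROB
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    model_params: dict[str, LinearModelParams] = field(
        default_factory=published_model_params)
    lod: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOD))
    inhibitor_frac: float = 0.0
    inhibitor_effects: dict[str, float] | None = None
    area_per_nmol: float = AREA_PER_NMOL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.genotype_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype_probs sum to {total}, expected 1")
        for p in (*self.genotype_probs.values(), self.female_prob,
                  self.inhibitor_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.inhibitor_frac > 0 and self.inhibitor_effects is None:
            raise ValueError(
                "inhibitor_frac > 0 requires explicit inhibitor_effects; "
                "no published effect sizes exist to default to")

    def clean(self) -> "GeneratorConfig":
        """Copy of the config with no missingness (all LODs zero)."""
        return replace(self, lod={a: 0.0 for a in ANALYTES})


def truncated_age_moments(
    mean: float = DEFAULT_AGE_MEAN,
    sd: float = DEFAULT_AGE_SD,
    bounds: tuple[float, float] = AGE_RANGE,
) -> tuple[float, float]:
    """(mean, variance) of the truncated-normal age distribution."""
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(dist.mean()), float(dist.var())


def linear_predictor_variance(
    params: LinearModelParams,
    genotype_probs: dict[GenotypeGroup, float] | None = None,
    female_prob: float = DEFAULT_FEMALE_PROB,
    age_var: float | None = None,
) -> float:
    """Var(X beta) under the conclusive-genotype covariate mixture.

    Inconclusive duplication groups are excluded (with renormalization)
    because the published R^2 describes the regression population, which
    omitted them.  Genotype, sex and centered age are independent in the
    generator, so their variance contributions add.
    """
    if genotype_probs is None:
        genotype_probs = DEFAULT_GENOTYPE_PROBS
    conclusive = {g: p for g, p in genotype_probs.items()
                  if g in CONCLUSIVE_GROUPS and p > 0}
    total = sum(conclusive.values())
    if total <= 0:
        raise ValueError("no conclusive genotype groups with positive probability")
    effects = np.array([params.genotype_effect(g) for g in conclusive])
    probs = np.array([p / total for p in conclusive.values()])
    mean_g = float(probs @ effects)
    var_g = float(probs @ (effects - mean_g) ** 2)
    p_male = 1.0 - female_prob
    var_sex = params.beta_male**2 * p_male * (1.0 - p_male)
    if age_var is None:
        age_var = truncated_age_moments()[1]
    var_age = params.beta_age_per_year**2 * age_var
    return var_g + var_sex + var_age


def residual_sd_from_variance(var_xb: float, r_squared: float) -> float:
    """Residual SD giving population R^2 = r_squared at Var(X beta) = var_xb."""
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared target must lie strictly in (0, 1)")
    if var_xb < 0:
        raise ValueError("variance of the linear predictor must be >= 0")
    return math.sqrt(var_xb * (1.0 - r_squared) / r_squared)


def calibrate_residual_sd(
    params: LinearModelParams,
    genotype_probs: dict[GenotypeGroup, float] | None = None,
    female_prob: float = DEFAULT_FEMALE_PROB,
    age_var: float | None = None,
) -> float:
    """Deterministic residual-SD calibration to the model's R^2 target."""
    var_xb = linear_predictor_variance(params, genotype_probs, female_prob, age_var)
    return residual_sd_from_variance(var_xb, params.r_squared_target)


def _calibrated_models(config: GeneratorConfig) -> dict[str, LinearModelParams]:
    age_var = truncated_age_moments(config.age_mean, config.age_sd)[1]
    out = {}
    for name, params in config.model_params.items():
        if params.residual_sd is None:
            sd = calibrate_residual_sd(
                params, config.genotype_probs, config.female_prob, age_var)
            params = replace(params, residual_sd=sd)
        elif params.residual_sd <= 0:
            raise ValueError(f"residual_sd must be > 0 for {name}")
        out[name] = params
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort as one patient per row.

    Columns: id, cyp2d6_diplotype, genotype_group, phenotype, sex, age,
    inhibitor_user, the eight outcome draws, solanidine_conc (nmol/L),
    per-analyte ``area_*`` and ``detected_*``.  Runs with the same
    config (including seed) are bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    models = _calibrated_models(config)

    groups = list(config.genotype_probs)
    probs = np.array([config.genotype_probs[g] for g in groups], dtype=float)
    probs /= probs.sum()
    group_idx = rng.choice(len(groups), size=n, p=probs)
    group_col = [groups[i] for i in group_idx]

    male = rng.random(n) >= config.female_prob
    lo, hi = AGE_RANGE
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    inhibitor = (rng.random(n) < config.inhibitor_frac
                 if config.inhibitor_frac > 0 else np.zeros(n, dtype=bool))

    df = pd.DataFrame({
        "id": [f"P{i + 1:06d}" for i in range(n)],
        "cyp2d6_diplotype": [REPRESENTATIVE_DIPLOTYPES[g] for g in group_col],
        "genotype_group": [g.value for g in group_col],
        "sex": np.where(male, "M", "F"),
        "age": age,
        "inhibitor_user": inhibitor,
    })
    df["phenotype"] = [
        phenotype_of(parse_diplotype(d)).phenotype.value
        for d in df["cyp2d6_diplotype"]
    ]

    age_c = age - config.age_mean
    for name, params in models.items():
        effect = np.array([params.genotype_effect(g) for g in group_col])
        mu = (params.intercept + params.beta_male * male.astype(float)
              + params.beta_age_per_year * age_c + effect)
        if config.inhibitor_frac > 0 and name in (config.inhibitor_effects or {}):
            mu = mu + np.where(inhibitor, config.inhibitor_effects[name], 0.0)
        df[name] = mu + rng.normal(0.0, params.residual_sd, size=n)

    df["solanidine_conc"] = np.exp(df[LN_SOLA_CONC])
    df["area_SOLA"] = df["solanidine_conc"] * config.area_per_nmol
    for m in METABOLITES:
        df[f"area_{m}"] = df["area_SOLA"] * np.exp(df[f"lnMR_{m}"])
    return apply_lod(df, config.lod)


def apply_lod(records: pd.DataFrame, lod: dict[str, float]) -> pd.DataFrame:
    """Set ``detected_*`` flags from per-analyte limits of detection.

    Areas below the LOD are retained (downstream truncation replaces
    them); an analyte is detected iff area >= LOD.
    """
    out = records.copy()
    for a in ANALYTES:
        out[f"detected_{a}"] = out[f"area_{a}"] >= lod.get(a, 0.0)
    return out


def calibrate_lod(
    config: GeneratorConfig | None = None,
    detection_fractions: dict[str, float] | None = None,
    n: int = 200_000,
    seed: int = 20230220,
) -> dict[str, float]:
    """Per-analyte LODs reproducing target detection fractions.

    Simulates a large clean cohort and returns, for each analyte, the
    empirical (1 - fraction) area quantile.  Used once to produce
    ``DEFAULT_LOD``; exposed so alternative generator settings can be
    recalibrated.
    """
    if config is None:
        config = GeneratorConfig()
    if detection_fractions is None:
        detection_fractions = DETECTION_FRACTIONS
    big = replace(config.clean(), n_patients=n, seed=seed)
    df = generate_cohort(big)
    return {
        a: float(np.quantile(df[f"area_{a}"], 1.0 - detection_fractions[a]))
        for a in ANALYTES
    }
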