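"""Genotype-effect OLS models, Dunnett contrasts and inhibitor t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solaphen.genotypes import GenotypeGroup
from solaphen.ratios import compute_ratios
from solaphen.regression import (
    GENOTYPE_TERMS,
    anova_dunnett,
    fit_genotype_model,
    inhibitor_comparison,
)
from solaphen.synth_cohort import (
    OUTCOMES,
    GeneratorConfig,
    generate_cohort,
    published_model_params,
)


def _truth(outcome):
    return published_model_params()[outcome]


class TestFitGenotypeModel:
    def test_noiseless_recovery_is_exact(self):
        """With (near-)zero residual noise the fit returns the generator's
        coefficients to numerical precision."""
        params = {
            name: p for name, p in published_model_params().items()
        }
        for p in params.values():
            p.residual_sd = 1e-9
        cfg = GeneratorConfig(n_patients=3000, seed=21, model_params=params).clean()
        table = compute_ratios(generate_cohort(cfg))
        fit = fit_genotype_model(table, "lnMR_M414")
        truth = _truth("lnMR_M414")
        assert fit.coefficients["Def/def"][0] == pytest.approx(-11.2, abs=1e-6)
        assert fit.coefficients["male"][0] == pytest.approx(
            truth.beta_male, abs=1e-6)
        assert fit.r_squared > 1 - 1e-9

    def test_large_sample_recovery_within_monte_carlo_error(
            self, big_clean_ratio_table):
        """Every generator coefficient of every outcome is recovered
        within 3 standard errors by the OLS refit."""
        for outcome in OUTCOMES:
            fit = fit_genotype_model(big_clean_ratio_table, outcome)
            truth = _truth(outcome)
            for g in GENOTYPE_TERMS:
                b, se, _ = fit.coefficients[g.value]
                assert b == pytest.approx(
                    truth.genotype_effect(g), abs=3 * se), (outcome, g)
            b, se, _ = fit.coefficients["male"]
            assert b == pytest.approx(truth.beta_male, abs=3 * se)

    def test_refit_r2_converges_to_target(self, big_clean_ratio_table):
        for outcome in OUTCOMES:
            fit = fit_genotype_model(big_clean_ratio_table, outcome)
            assert fit.r_squared == pytest.approx(
                _truth(outcome).r_squared_target, abs=0.015), outcome

    def test_bonferroni_is_six_times_raw_capped(self, small_cohort):
        import statsmodels.api as sm

        table = compute_ratios(small_cohort)
        fit = fit_genotype_model(table, "lnMR_M432")
        # independent raw refit
        data = table[(table["phenotype"] != "inconclusive")
                     & table["include_M432"]]
        X = pd.DataFrame({
            "const": 1.0,
            "male": data["sex"].eq("M").astype(float),
            "age_c": data["age"] - data["age"].mean(),
        })
        for g in GENOTYPE_TERMS:
            X[g.value] = data["genotype_group"].eq(g.value).astype(float)
        raw = sm.OLS(data["lnMR_M432"].to_numpy(), X.to_numpy()).fit()
        for i, term in enumerate(X.columns):
            if term in {g.value for g in GENOTYPE_TERMS}:
                expected = min(1.0, 6 * raw.pvalues[i])
            elif term == "const":
                continue
            else:
                expected = raw.pvalues[i]
            got = fit.coefficients[term if term != "age_c" else "age_centered"][2]
            assert got == pytest.approx(expected, abs=1e-9), term

    def test_inconclusive_and_excluded_rows_never_enter(self, lod_cohort):
        table = compute_ratios(lod_cohort)
        fit = fit_genotype_model(table, "lnMR_M412")
        eligible = table[(table["phenotype"] != "inconclusive")
                         & table["include_M412"]]
        assert fit.n == len(eligible)
        assert fit.n < len(table)

    def test_empty_genotype_cell_dropped_with_warning(self):
        probs = {g: 0.0 for g in GeneratorConfig().genotype_probs}
        probs[GenotypeGroup.STAR1_STAR1] = 0.7
        probs[GenotypeGroup.DEF_DEF] = 0.3
        cfg = GeneratorConfig(n_patients=300, seed=2, genotype_probs=probs).clean()
        table = compute_ratios(generate_cohort(cfg))
        with pytest.warns(UserWarning, match="empty"):
            fit = fit_genotype_model(table, "lnMR_M414")
        assert "Def/red" in fit.dropped_terms
        assert "Def/def" in fit.coefficients


class TestAnovaDunnett:
    @staticmethod
    def _table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = []
        for g, ys in groups.items():
            rows += [{"genotype_group": g, "phenotype": "NM", "y": y} for y in ys]
        return pd.DataFrame(rows)

    def test_identical_groups_p_near_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0] * 4)
        table = self._table({"*1/*1": y, "Def/def": y})
        res = anova_dunnett(table, "y")
        assert res["adjusted_p"]["Def/def"] > 0.95

    def test_adjusted_p_not_below_unadjusted_t_test(self):
        rng = np.random.default_rng(6)
        table = self._table({
            "*1/*1": rng.normal(0, 1, 20),
            "*1/def": rng.normal(-0.5, 1, 12),
            "Def/def": rng.normal(-1.2, 1, 8),
        })
        res = anova_dunnett(table, "y")
        control = table[table["genotype_group"] == "*1/*1"]["y"]
        for g in ("*1/def", "Def/def"):
            raw = stats.ttest_ind(
                table[table["genotype_group"] == g]["y"], control,
                equal_var=True).pvalue
            assert res["adjusted_p"][g] >= raw - 0.02

    def test_matches_scipy_dunnett(self):
        """Monte-Carlo adjustment agrees with the multivariate-t
        quadrature implementation within Monte-Carlo error."""
        rng = np.random.default_rng(13)
        g0 = rng.normal(0, 1, 15)
        g1 = rng.normal(-0.8, 1, 15)
        g2 = rng.normal(-0.3, 1, 15)
        table = self._table({"*1/*1": g0, "*1/def": g1, "Def/def": g2})
        res = anova_dunnett(table, "y", n_mc=200_000, seed=3)
        oracle = stats.dunnett(g1, g2, control=g0, alternative="two-sided")
        assert res["adjusted_p"]["*1/def"] == pytest.approx(
            oracle.pvalue[0], abs=0.01)
        assert res["adjusted_p"]["Def/def"] == pytest.approx(
            oracle.pvalue[1], abs=0.01)

    def test_small_integer_data_vs_permutation_oracle(self):
        """Adjusted p tracks a brute-force permutation of max |t|."""
        rng = np.random.default_rng(4)
        g0 = np.array([3.0, 5, 4, 6, 5, 4, 5, 6, 4, 5, 3, 6, 5, 4, 5])
        g1 = np.array([2.0, 4, 3, 4, 3, 5, 3, 2, 4, 3, 4, 3, 2, 4, 3])
        g2 = np.array([4.0, 5, 4, 6, 5, 4, 6, 5, 4, 5, 6, 4, 5, 4, 6])
        table = self._table({"*1/*1": g0, "*1/def": g1, "Def/def": g2})
        res = anova_dunnett(table, "y", n_mc=200_000, seed=5)

        def max_abs_t(y0, y1, y2):
            samples = [y0, y1, y2]
            df = sum(len(s) for s in samples) - 3
            s2 = sum(np.sum((s - s.mean()) ** 2) for s in samples) / df
            return max(
                abs(s.mean() - y0.mean()) / np.sqrt(s2 * (1 / len(s) + 1 / len(y0)))
                for s in samples[1:])

        pooled = np.concatenate([g0, g1, g2])
        t_obs = {"*1/def": None, "Def/def": None}
        samples = {"*1/def": g1, "Def/def": g2}
        for g, s in samples.items():
            dfree = len(pooled) - 3
            s2 = (np.sum((g0 - g0.mean())**2) + np.sum((g1 - g1.mean())**2)
                  + np.sum((g2 - g2.mean())**2)) / dfree
            t_obs[g] = abs(s.mean() - g0.mean()) / np.sqrt(
                s2 * (1 / len(s) + 1 / len(g0)))
        n_perm, hits = 4000, {g: 0 for g in t_obs}
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            m = max_abs_t(perm[:15], perm[15:30], perm[30:])
            for g, t in t_obs.items():
                hits[g] += m >= t
        for g in t_obs:
            assert res["adjusted_p"][g] == pytest.approx(
                hits[g] / n_perm, abs=0.05), g

    def test_undersized_group_excluded_with_warning(self):
        table = self._table({"*1/*1": np.arange(6.0), "Def/def": np.array([1.0])})
        table2 = pd.concat(
            [table, self._table({"*1/def": np.arange(4.0)})], ignore_index=True)
        with pytest.warns(UserWarning, match="excluded"):
            res = anova_dunnett(table2, "y")
        assert "Def/def" not in res["adjusted_p"]


class TestInhibitorComparison:
    def test_recovers_injected_shift(self):
        cfg = GeneratorConfig(
            n_patients=6000, seed=31, inhibitor_frac=0.1,
            inhibitor_effects={"lnMR_M414": -2.0}).clean()
        table = compute_ratios(generate_cohort(cfg))
        report = inhibitor_comparison(table).set_index("outcome")
        assert report.loc["lnMR_M414", "difference"] == pytest.approx(-2.0, abs=0.3)
        assert report.loc["lnMR_M414", "p_value"] < 1e-6
        # no shift injected for the concentration outcome
        assert report.loc["ln_sola_conc", "p_value"] > 0.001

    def test_identical_groups_p_one(self):
        y = [1.0, 2.0, 3.0]
        table = pd.DataFrame({
            "genotype_group": "*1/*1",
            "inhibitor_user": [True] * 3 + [False] * 3,
            "lnMR_M414": y + y,
        })
        report = inhibitor_comparison(table, outcomes=["lnMR_M414"])
        assert report.loc[0, "difference"] == 0.0
        assert report.loc[0, "p_value"] == pytest.approx(1.0)

    def test_equal_variance_t_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 3.0])
        table = pd.DataFrame({
            "genotype_group": "*1/*1",
            "inhibitor_user": [True] * 3 + [False] * 3,
            "lnMR_M414": np.concatenate([a, b]),
        })
        sp = np.sqrt((np.sum((a - a.mean())**2) + np.sum((b - b.mean())**2)) / 4)
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), df=4)
        report = inhibitor_comparison(table, outcomes=["lnMR_M414"])
        assert report.loc[0, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_requires_both_groups(self):
        table = pd.DataFrame({
            "genotype_group": ["*1/*1"] * 3,
            "inhibitor_user": [False] * 3,
            "lnMR_M414": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError):
            inhibitor_comparison(table)
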