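"""Factorial permutation inference, contrasts and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ectoscope.errors import (
    AliasingError,
    MissingPairError,
    UndefinedEffectError,
)
from ectoscope.permstats import (
    ModelSpec,
    cohens_d,
    fit_factorial_model,
    marginal_means_contrast,
    mismatch_effect_size,
    permutation_test,
    thyroid_effect_size,
    two_sample_permutation_test,
)
from ectoscope.synthetic import (
    DesignSpec,
    EffectModel,
    generate_design,
    simulate_traits,
)
from ectoscope.synthetic.design import coded_interaction


def make_data(n_per_group=4, model=None, seed=0):
    d = generate_design(DesignSpec(n_per_group=n_per_group))
    model = model or EffectModel(baseline=1.0, noise_sd=1.0, within_fish_sd=0.5)
    d["y"] = simulate_traits(d, model, seed=seed)
    return d


class TestFactorialFit:
    def test_single_injected_effect_is_unique_nonzero_f(self):
        d = make_data(
            model=EffectModel(
                baseline=1.0, main_effects={"day_length": {"long": 1.0}}
            )
        )
        fit = fit_factorial_model(d, ModelSpec(response="y"))
        assert fit.f_stats["day_length"] == np.inf
        for term, f in fit.f_stats.items():
            if term != "day_length":
                assert f == 0.0

    def test_fourteen_terms_in_two_strata(self):
        fit = fit_factorial_model(make_data(), ModelSpec(response="y"))
        assert len(fit.terms) == 14
        strata = pd.Series(fit.stratum)
        assert (strata == "between").sum() == 7
        assert (strata == "within").sum() == 7

    def test_marginal_ss_match_type3_reference(self):
        """Drop-term SS equal statsmodels Type III SS in both strata,
        including under imbalance (whole fish removed)."""
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")

        d = make_data(n_per_group=4, seed=5)
        drop_fish = d["fish_id"].unique()[[0, 5, 11]]
        d = d[~d["fish_id"].isin(drop_fish)]
        fit = fit_factorial_model(d, ModelSpec(response="y"))

        per_fish = (
            d.sort_values(["fish_id", "test_temp"])
            .groupby("fish_id")
            .agg(
                day_length=("day_length", "first"),
                thyroid=("thyroid", "first"),
                acclimation_temp=("acclimation_temp", "first"),
                m=("y", "mean"),
            )
            .reset_index()
        )
        wide = d.pivot_table(index="fish_id", columns="test_temp", values="y")
        per_fish["c"] = ((wide[28] - wide[18]) / 2.0).values

        # the within stratum omits the between three-way column: it would
        # carry the four-way interaction, which the model excludes
        formulas = {
            "between": (
                "m ~ C(day_length, Sum) * C(thyroid, Sum) * "
                "C(acclimation_temp, Sum)"
            ),
            "within": (
                "c ~ (C(day_length, Sum) + C(thyroid, Sum) + "
                "C(acclimation_temp, Sum)) ** 2"
            ),
        }
        for stratum in ("between", "within"):
            ols_fit = smf.ols(formulas[stratum], data=per_fish).fit()
            table = sm.stats.anova_lm(ols_fit, typ=3)
            for sm_term, ss in table["sum_sq"].items():
                if sm_term == "Residual":
                    continue
                factors = tuple(
                    t.split("(")[1].split(",")[0]
                    for t in sm_term.split(":")
                ) if sm_term != "Intercept" else ()
                if stratum == "between":
                    if sm_term == "Intercept":
                        continue
                    name = ":".join(
                        f for f in ("day_length", "thyroid", "acclimation_temp")
                        if f in factors
                    )
                else:
                    name = ":".join(
                        [
                            f
                            for f in ("day_length", "thyroid", "acclimation_temp")
                            if f in factors
                        ]
                        + ["test_temp"]
                    )
                    name = name if factors else "test_temp"
                assert fit.ss[name] == pytest.approx(ss, rel=1e-8), (stratum, name)

    def test_balanced_sequential_equals_marginal(self):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        d = make_data(n_per_group=4, seed=2)
        fit = fit_factorial_model(d, ModelSpec(response="y"))
        per_fish = (
            d.groupby("fish_id")
            .agg(
                day_length=("day_length", "first"),
                thyroid=("thyroid", "first"),
                acclimation_temp=("acclimation_temp", "first"),
                m=("y", "mean"),
            )
            .reset_index()
        )
        ols_fit = smf.ols(
            "m ~ C(day_length, Sum) * C(thyroid, Sum) * C(acclimation_temp, Sum)",
            data=per_fish,
        ).fit()
        seq = sm.stats.anova_lm(ols_fit, typ=1)
        # sequential SS for the day_length main effect equals the marginal SS
        assert fit.ss["day_length"] == pytest.approx(
            seq.loc["C(day_length, Sum)", "sum_sq"], rel=1e-8
        )

    def test_empty_cell_aliasing_error(self):
        d = make_data(n_per_group=2)
        cell = (
            (d["day_length"] == "short")
            & (d["thyroid"] == "hypo")
            & (d["acclimation_temp"] == 18)
        )
        with pytest.raises(AliasingError, match="empty cells"):
            fit_factorial_model(d[~cell], ModelSpec(response="y"))

    def test_incomplete_within_pairs_rejected(self):
        d = make_data(n_per_group=2)
        d = d.drop(d.index[0])  # one fish loses a test temperature
        with pytest.raises(MissingPairError):
            fit_factorial_model(d, ModelSpec(response="y"))


class TestPermutationTest:
    def test_seed_determinism_and_row_order_invariance(self):
        d = make_data(n_per_group=8, seed=3)
        spec = ModelSpec(response="y", n_permutations=199, seed=42)
        p1 = permutation_test(d, spec).table["p_perm"]
        p2 = permutation_test(d.sample(frac=1, random_state=1), spec).table["p_perm"]
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())

    def test_injected_effect_detected(self):
        model = EffectModel(
            baseline=0.0,
            interactions=coded_interaction(("acclimation_temp", "test_temp"), 1.0),
            noise_sd=0.5,
            within_fish_sd=0.3,
        )
        d = make_data(n_per_group=8, model=model, seed=6)
        res = permutation_test(d, ModelSpec(response="y", n_permutations=999, seed=0))
        assert res.p("acclimation_temp:test_temp") <= 0.005

    @staticmethod
    def nine_fish_data(seed=9):
        """One doubled cell plus singletons: 9 fish, 2^9 = 512 sign flips."""
        d = make_data(n_per_group=2, seed=seed)
        fish = d.drop_duplicates("fish_id")
        keep = fish.groupby(
            ["day_length", "thyroid", "acclimation_temp"]
        )["fish_id"].first()
        first_cell = fish["fish_id"].iloc[:2]
        ids = set(keep) | set(first_cell)
        return d[d["fish_id"].isin(ids)]

    def test_within_terms_exhaustive_for_small_designs(self):
        d = self.nine_fish_data()
        res = permutation_test(d, ModelSpec(response="y", n_permutations=999, seed=1))
        within = res.table[res.table["stratum"] == "within"]
        assert within["exhaustive"].all()
        assert (within["n_perm"] == 512).all()

    def test_monte_carlo_tracks_exhaustive(self):
        d = self.nine_fish_data()
        exact = permutation_test(d, ModelSpec(response="y", n_permutations=999, seed=1))
        mc = permutation_test(d, ModelSpec(response="y", n_permutations=199, seed=4))
        for term in ("test_temp", "thyroid:test_temp"):
            p_ex = exact.p(term)
            p_mc = mc.p(term)
            se = np.sqrt(p_ex * (1 - p_ex) / 199)
            assert abs(p_mc - p_ex) < 3 * se + 1 / 200

    def test_null_pvalues_uniform(self, null_pvalues):
        """Kolmogorov-Smirnov uniformity of null permutation p-values."""
        terms, pvals = null_pvalues
        for term in ("day_length", "test_temp", "day_length:thyroid:test_temp"):
            j = terms.index(term)
            assert stats.kstest(pvals[:, j], "uniform").pvalue > 0.01


class TestTwoSamplePermutation:
    def test_exhaustive_toy_case(self):
        res = two_sample_permutation_test([1, 2], [3, 4])
        assert res.exhaustive
        assert res.p_perm == pytest.approx(1 / 3)

    def test_monte_carlo_agrees_within_error(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.8, 1, 6), rng.normal(0, 1, 6)
        exact = two_sample_permutation_test(a, b, n_permutations=10**6)
        assert exact.exhaustive
        mc = two_sample_permutation_test(a, b, n_permutations=4999, seed=2)
        se = np.sqrt(exact.p_perm * (1 - exact.p_perm) / 4999)
        assert abs(mc.p_perm - exact.p_perm) < 3 * se + 1 / 5000


class TestMarginalMeans:
    def test_recovers_injected_between_effect_exactly(self):
        model = EffectModel(
            baseline=1.0, main_effects={"day_length": {"long": 0.8}}
        )
        d = make_data(n_per_group=3, model=model)
        res = marginal_means_contrast(
            d, ModelSpec(response="y", n_permutations=99), "day_length", "long", "short"
        )
        assert res.estimate == pytest.approx(0.8)

    def test_sign_flips_with_level_order(self):
        d = make_data(n_per_group=3, seed=8)
        spec = ModelSpec(response="y", n_permutations=99, seed=5)
        ab = marginal_means_contrast(d, spec, "day_length", "long", "short")
        ba = marginal_means_contrast(d, spec, "day_length", "short", "long")
        assert ab.estimate == pytest.approx(-ba.estimate)

    def test_day_length_contrast_at_cold_test_temperature(self):
        # the post hoc comparison structure: short vs long days at 18 degC
        d = make_data(n_per_group=4, seed=10)
        res = marginal_means_contrast(
            d,
            ModelSpec(response="y", n_permutations=499, seed=3),
            "day_length",
            "short",
            "long",
            conditioning={"test_temp": 18},
        )
        assert 0 < res.p_perm <= 1
        assert "test_temp=18" in res.description

    def test_within_factor_contrast(self):
        model = EffectModel(baseline=0.0, main_effects={"test_temp": {28: 0.6}})
        d = make_data(n_per_group=3, model=model)
        res = marginal_means_contrast(
            d, ModelSpec(response="y", n_permutations=199), "test_temp", 28, 18
        )
        assert res.estimate == pytest.approx(0.6)


class TestCohensD:
    def test_matches_independent_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 14), rng.normal(0, 1.3, 18)
        mine = cohens_d(a, b).cohens_d
        assert mine == pytest.approx(pg.compute_effsize(a, b, eftype="cohen"))

    def test_identical_groups_give_zero_with_covering_ci(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = cohens_d(vals, vals.copy())
        assert res.cohens_d == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_tiny_groups_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([1.0], [0.0, 1.0])

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        res = cohens_d(rng.normal(1, 1, 16), rng.normal(0, 1, 16), seed=3)
        assert res.ci_low <= res.cohens_d <= res.ci_high

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 16), rng.normal(0, 1, 16)
        r1, r2 = cohens_d(a, b, seed=7), cohens_d(a, b, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestScenarioEffectSizes:
    def test_thyroid_orientation(self):
        # normothyroid fish do better -> positive d (positive TH effect)
        d = make_data(
            n_per_group=8,
            model=EffectModel(
                baseline=1.0, main_effects={"thyroid": {"normo": 0.7}}, noise_sd=0.3
            ),
            seed=4,
        )
        res = thyroid_effect_size(d, "y", seed=1)
        assert res.cohens_d > 0

    def test_mismatch_effect_recovers_injected_sign(self):
        model = EffectModel(
            baseline=1.0,
            interactions={
                (("day_length", "short"), ("acclimation_temp", 28), ("test_temp", 28)): 0.9
            },
            noise_sd=0.3,
        )
        d = make_data(n_per_group=8, model=model, seed=12)
        res = mismatch_effect_size(d, "y", seed=1)
        assert res.cohens_d > 0
        assert res.ci_low > 0

    def test_null_mismatch_ci_straddles_zero(self):
        rng = np.random.default_rng(3)
        covered = 0
        n_rep = 40
        for i in range(n_rep):
            d = make_data(n_per_group=8, seed=int(rng.integers(2**31)))
            res = mismatch_effect_size(d, "y", n_boot=499, seed=i)
            if res.ci_low <= 0 <= res.ci_high:
                covered += 1
        assert covered >= 0.9 * n_rep

    def test_empty_cell_is_error(self):
        d = make_data(n_per_group=4)
        d = d[~((d["day_length"] == "short") & (d["acclimation_temp"] == 28))]
        with pytest.raises(MissingPairError):
            mismatch_effect_size(d, "y")

    def test_single_fish_cells_undefined(self):
        d = make_data(n_per_group=1)
        warm = (d["acclimation_temp"] == 28) & (d["test_temp"] == 28)
        keep_ids = d.loc[warm].groupby("day_length")["fish_id"].first()
        d = d[~warm | d["fish_id"].isin(keep_ids)]
        with pytest.raises(UndefinedEffectError):
            mismatch_effect_size(d, "y")
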