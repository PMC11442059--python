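import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import rnlpipe as r
from rnlpipe.mmi import (
    MAINS,
    ModelFit,
    ModelSpec,
    design_matrix,
    ranking_frame,
)


def _dummy_fit(spec, loglik=0.0, k=3, n=100, coef=None, se=None):
    names = ["(Intercept)"]
    coef = {"(Intercept)": 0.0} if coef is None else coef
    se = dict.fromkeys(coef, 1.0) if se is None else se
    return ModelFit(
        spec=spec,
        coef=pd.Series(coef),
        se=pd.Series(se),
        loglik=loglik,
        k=k,
        n=n,
        sigma2_between=0.0,
        sigma2_resid=1.0,
    )


class TestEnumerate:
    def test_four_mains_gives_113(self):
        specs = r.enumerate_candidates()
        assert len(specs) == 113
        assert len(set(specs)) == 113

    def test_brute_force_oracle(self):
        """Independent enumeration: subsets of mains x subsets of their pairs."""
        count = 0
        for rmask in range(16):
            subset = [m for i, m in enumerate(MAINS) if rmask >> i & 1]
            pairs = list(itertools.combinations(subset, 2))
            count += 2 ** len(pairs)
        assert count == 113
        assert len(r.enumerate_candidates()) == count

    def test_one_main(self):
        assert len(r.enumerate_candidates(mains=("morph",))) == 2

    def test_two_mains(self):
        specs = r.enumerate_candidates(mains=("morph", "predator"))
        assert len(specs) == 5
        formulas = {s.formula() for s in specs}
        assert "~ 1" in formulas
        assert "~ morph + predator + morph:predator" in formulas

    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(mains=("morph",), interactions=(("morph", "predator"),))


class TestDesignMatrix:
    def test_reference_levels(self):
        df = pd.DataFrame(
            {
                "species": ["granulifera", "pumilio"],
                "morph": ["green", "red"],
                "substrate": ["green_leaf", "trunk"],
                "predator": ["bird", "crab"],
            }
        )
        spec = ModelSpec(mains=MAINS)
        X, names = design_matrix(spec, df)
        assert names[0] == "(Intercept)"
        # reference row (all baseline levels) is all-zero beyond the intercept
        np.testing.assert_array_equal(X[0], [1, 0, 0, 0, 0, 0, 0])
        assert "species[pumilio]" in names
        assert "substrate[trunk]" in names

    def test_interaction_columns_are_products(self):
        df = pd.DataFrame(
            {
                "morph": ["green", "red", "red", "green"],
                "predator": ["bird", "crab", "bird", "crab"],
            }
        )
        spec = ModelSpec(mains=("morph", "predator"), interactions=(("morph", "predator"),))
        X, names = design_matrix(spec, df)
        i_m = names.index("morph[red]")
        i_p = names.index("predator[crab]")
        i_mp = names.index("morph[red]:predator[crab]")
        np.testing.assert_array_equal(X[:, i_mp], X[:, i_m] * X[:, i_p])

    def test_unknown_level_errors(self):
        df = pd.DataFrame({"morph": ["blue"]})
        with pytest.raises(ValueError, match="unknown levels"):
            design_matrix(ModelSpec(mains=("morph",)), df)


class TestFitLmm:
    def test_zero_between_variance_matches_ols(self):
        data = r.generate_contrast_table(
            {"(Intercept)": 5.0, "morph[red]": 2.0},
            sigma_individual=0.0,
            sigma_resid=1.0,
            seed=3,
        )
        spec = ModelSpec(mains=("morph",))
        fit = r.fit_lmm(spec, data, "deltaS")
        X, _ = design_matrix(spec, data)
        y = data["deltaS"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.sigma2_between == pytest.approx(0.0, abs=1e-4)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta_ols, atol=1e-6)

    def test_balanced_recovery_within_3se(self):
        beta = {
            "(Intercept)": 5.0,
            "morph[red]": 3.0,
            "predator[crab]": -2.0,
            "morph[red]:predator[crab]": -2.0,
        }
        data = r.generate_contrast_table(
            beta, sigma_individual=0.5, sigma_resid=1.0, seed=7
        )
        assert len(data) == 648
        spec = ModelSpec(mains=("morph", "predator"), interactions=(("morph", "predator"),))
        fit = r.fit_lmm(spec, data, "deltaS")
        for name, true in beta.items():
            assert abs(fit.coef[name] - true) < 3 * fit.se[name]

    def test_loglik_matches_dense_gaussian_oracle(self):
        data = r.generate_contrast_table(
            {"(Intercept)": 2.0, "morph[red]": 1.0},
            sigma_individual=0.7,
            sigma_resid=0.9,
            design=r.StudyDesign(
                # one green and one red locality so the morph factor varies
                localities=(r.StudyDesign().localities[0], r.StudyDesign().localities[2]),
                n_males_per_locality=4,
            ),
            seed=5,
        )
        spec = ModelSpec(mains=("morph", "substrate"))
        fit = r.fit_lmm(spec, data, "deltaS")
        # independent dense-covariance evaluation at the fitted parameters
        X, _ = design_matrix(spec, data)
        y = data["deltaS"].to_numpy()
        _, ginv = np.unique(data["individual"].to_numpy(), return_inverse=True)
        Z = np.zeros((len(y), ginv.max() + 1))
        Z[np.arange(len(y)), ginv] = 1.0
        V = fit.sigma2_resid * np.eye(len(y)) + fit.sigma2_between * (Z @ Z.T)
        ll = multivariate_normal.logpdf(y, mean=X @ fit.coef.to_numpy(), cov=V)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_k_counts_fixed_effects_plus_two(self):
        data = r.generate_contrast_table({}, 0.1, 1.0, seed=1)
        fit = r.fit_lmm(ModelSpec(mains=("substrate",)), data, "deltaS")
        assert fit.k == 3 + 2  # intercept + 2 substrate dummies + 2 variances

    def test_ml_loglik_at_least_boundary(self):
        data = r.generate_contrast_table({"(Intercept)": 1.0}, 0.8, 0.5, seed=9)
        fit = r.fit_lmm(ModelSpec(), data, "deltaS")
        assert fit.sigma2_between > 0  # strong clustering should be detected


class TestAicc:
    def test_formula_value(self):
        fit = _dummy_fit(ModelSpec(), loglik=0.0, k=3, n=10)
        assert r.aicc(fit) == pytest.approx(10.0)

    def test_large_n_limit_equals_aic(self):
        # correction term 2k(k+1)/(n-k-1) vanishes as n grows
        fit = _dummy_fit(ModelSpec(), loglik=-5.0, k=4, n=10**8)
        aic = -2 * fit.loglik + 2 * fit.k
        assert abs(r.aicc(fit) - aic) < 1e-6

    def test_monotone_penalty(self):
        f2 = _dummy_fit(ModelSpec(), loglik=-1.0, k=2, n=50)
        f3 = _dummy_fit(ModelSpec(), loglik=-1.0, k=3, n=50)
        assert r.aicc(f2) < r.aicc(f3)

    def test_small_n_errors(self):
        fit = _dummy_fit(ModelSpec(), k=9, n=10)
        with pytest.raises(ValueError):
            r.aicc(fit)


class TestWeights:
    def test_single_model(self):
        fits = r.weights_and_ratios([_dummy_fit(ModelSpec(), loglik=0.0)])
        assert fits[0].weight == pytest.approx(1.0)
        assert fits[0].evidence_ratio == pytest.approx(1.0)

    def test_delta_zero_two_pair(self):
        # logliks chosen so AICc's differ by exactly 2
        f1 = _dummy_fit(ModelSpec(), loglik=0.0, k=3, n=1000)
        f2 = _dummy_fit(ModelSpec(mains=("morph",)), loglik=-1.0, k=3, n=1000)
        fits = r.weights_and_ratios([f1, f2])
        assert fits[0].weight == pytest.approx(0.73105857863, abs=1e-8)
        assert fits[1].weight == pytest.approx(0.26894142137, abs=1e-8)
        assert fits[1].evidence_ratio == pytest.approx(np.e, rel=1e-10)

    def test_weights_sum_to_one(self, rng):
        fits = [
            _dummy_fit(ModelSpec(), loglik=float(ll), k=3, n=500)
            for ll in rng.normal(0, 10, 17)
        ]
        fits = r.weights_and_ratios(fits)
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_loglik_shift(self, rng):
        lls = rng.normal(0, 5, 9)
        fits1 = r.weights_and_ratios(
            [_dummy_fit(ModelSpec(), loglik=float(ll), k=3, n=500) for ll in lls]
        )
        fits2 = r.weights_and_ratios(
            [_dummy_fit(ModelSpec(), loglik=float(ll) + 123.4, k=3, n=500) for ll in lls]
        )
        np.testing.assert_allclose(
            [f.weight for f in fits1], [f.weight for f in fits2], atol=1e-12
        )


class TestConfidenceSet:
    @staticmethod
    def _with_weights(weights):
        fits = [_dummy_fit(ModelSpec(), loglik=0.0) for _ in weights]
        for f, w in zip(fits, weights):
            f.weight = w
            f.aicc = 0.0
        return fits

    def test_096_004(self):
        assert len(r.confidence_set(self._with_weights([0.96, 0.04]))) == 1

    def test_cumulative_095(self):
        assert len(r.confidence_set(self._with_weights([0.5, 0.3, 0.15, 0.05]))) == 3

    def test_uniform_20(self):
        assert len(r.confidence_set(self._with_weights([0.05] * 20))) == 19


class TestModelAverage:
    @staticmethod
    def _fit(terms_spec, w, coef, se):
        f = _dummy_fit(terms_spec, coef=coef, se=se)
        f.weight = w
        return f

    def test_identical_term_everywhere(self):
        spec = ModelSpec(mains=("morph",))
        fits = [
            self._fit(spec, 0.6, {"(Intercept)": 0.0, "morph[red]": 2.0}, {"(Intercept)": 1.0, "morph[red]": 0.1}),
            self._fit(spec, 0.4, {"(Intercept)": 0.0, "morph[red]": 2.0}, {"(Intercept)": 1.0, "morph[red]": 0.1}),
        ]
        avg = r.model_average(fits)
        row = avg[avg.coef == "morph[red]"].iloc[0]
        assert row.estimate == pytest.approx(2.0)
        assert row.se == pytest.approx(0.1)
        assert row.ci_lower == pytest.approx(1.804)
        assert row.ci_upper == pytest.approx(2.196)
        assert row.strong

    def test_unconditional_se_hand_value(self):
        """Hand-evaluated two-model average: w=(0.7,0.3), beta=(1,2), se=0.1."""
        spec = ModelSpec(mains=("morph",))
        fits = [
            self._fit(spec, 0.7, {"morph[red]": 1.0}, {"morph[red]": 0.1}),
            self._fit(spec, 0.3, {"morph[red]": 2.0}, {"morph[red]": 0.1}),
        ]
        avg = r.model_average(fits)
        row = avg[avg.coef == "morph[red]"].iloc[0]
        expected_se = 0.7 * np.sqrt(0.01 + 0.09) + 0.3 * np.sqrt(0.01 + 0.49)
        assert row.estimate == pytest.approx(1.3)
        assert row.se == pytest.approx(expected_se, abs=1e-12)
        assert row.ci_lower == pytest.approx(1.3 - 1.96 * expected_se, abs=1e-9)
        assert row.ci_upper == pytest.approx(1.3 + 1.96 * expected_se, abs=1e-9)
        assert row.strong  # CI excludes zero

    def test_importance_083_flagged_important(self):
        with_term = ModelSpec(mains=("morph",))
        without = ModelSpec()
        fits = [
            self._fit(with_term, 0.83, {"(Intercept)": 0.0, "morph[red]": 1.0}, {"(Intercept)": 1.0, "morph[red]": 0.1}),
            self._fit(without, 0.17, {"(Intercept)": 0.0}, {"(Intercept)": 1.0}),
        ]
        avg = r.model_average(fits)
        row = avg[avg.coef == "morph[red]"].iloc[0]
        assert row.importance == pytest.approx(0.83)
        assert row.important
        assert row.n_models == 1

    def test_zero_substitution_mode(self):
        with_term = ModelSpec(mains=("morph",))
        without = ModelSpec()
        fits = [
            self._fit(with_term, 0.5, {"morph[red]": 2.0}, {"morph[red]": 0.0}),
            self._fit(without, 0.5, {"(Intercept)": 0.0}, {"(Intercept)": 1.0}),
        ]
        avg = r.model_average(fits, conditional=False)
        row = avg[avg.coef == "morph[red]"].iloc[0]
        assert row.estimate == pytest.approx(1.0)  # 0.5*2 + 0.5*0


class TestParameterRecovery:
    def test_interaction_recovered_null_species_covered(self):
        """Generator with a strong morph x predator interaction and a null
        species effect: 20 replicates, >= 18 must recover the structure."""
        true_beta = {
            "(Intercept)": 5.0,
            "morph[red]": 3.0,
            "predator[lizard]": -0.5,
            "predator[crab]": -2.0,
            "morph[red]:predator[crab]": -2.0,
        }
        gen_spec = ModelSpec(
            mains=("morph", "predator"), interactions=(("morph", "predator"),)
        )
        ok_importance = ok_species = ok_beta = 0
        for rep in range(20):
            data = r.generate_contrast_table(
                true_beta, sigma_individual=0.5, sigma_resid=1.0, seed=7 + rep
            )
            res = r.multimodel_analysis(data, "deltaS")
            avg = res["averaged"].set_index("coef")
            imp = avg["importance"]
            morph_imp = imp.get("morph[red]", 0.0)
            pred_imp = imp.get("predator[crab]", 0.0)
            if morph_imp > 0.8 and pred_imp > 0.8:
                ok_importance += 1
            if "species[pumilio]" in avg.index:
                row = avg.loc["species[pumilio]"]
                covered = row.ci_lower <= 0.0 <= row.ci_upper
            else:
                covered = True  # species dropped entirely: no false positive
            ok_species += covered
            fit = r.fit_lmm(gen_spec, data, "deltaS")
            if all(
                abs(fit.coef[nm] - b) < 3 * fit.se[nm] for nm, b in true_beta.items()
            ):
                ok_beta += 1
        assert ok_importance >= 18
        assert ok_species >= 18
        assert ok_beta >= 18


class TestEndToEndStats:
    def test_reference_level_signs_on_synthetic(self, contrast_records):
        """Crab coefficient should be negative when crabs perceive lower
        contrast than the bird baseline (as the generator builds it)."""
        res = r.multimodel_analysis(contrast_records, "deltaS")
        avg = res["averaged"].set_index("coef")
        assert avg.loc["predator[crab]", "estimate"] < 0

    def test_ranking_frame_columns(self, contrast_records):
        res = r.multimodel_analysis(contrast_records, "deltaL")
        rk = res["ranking"]
        assert list(rk.columns) == [
            "model", "k", "loglik", "aicc", "delta_aicc", "weight", "evidence_ratio",
        ]
        assert (rk.delta_aicc >= 0).all()
        assert rk.delta_aicc.min() == 0.0
        assert rk.weight.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(rk) == 100  # capped candidate set

    def test_cap_configurable(self, contrast_records):
        res = r.multimodel_analysis(contrast_records, "deltaS", candidate_cap=None)
        assert len(res["ranking"]) == 113

    def test_weight_floor_option(self, contrast_records):
        res = r.multimodel_analysis(contrast_records, "deltaS", weight_floor=0.01)
        assert all(f.weight > 0.01 for f in res["confidence_set"])
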