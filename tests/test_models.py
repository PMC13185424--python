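import numpy as np
import pandas as pd
import pytest

from freelist.models import (
    EffectSpec,
    EffectType,
    Term,
    backward_select,
    fit_nb,
    merge_terms,
    select_effect_type,
    spline_basis,
)
from freelist.types import ParameterError


def _nb_data(seed, n=1500, beta_edu=0.3, beta_noise=0.0, theta=2.0):
    rng = np.random.default_rng(seed)
    edu = rng.integers(1, 7, n).astype(float)
    noise = rng.integers(1, 7, n).astype(float)
    gender = np.where(rng.random(n) < 0.55, "female", "male")
    mu = np.exp(0.8 + beta_edu * (edu - 3) + beta_noise * (noise - 3))
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame(
        dict(y=y, education=edu, noise=noise, gender=gender)
    )


class TestSplineBasis:
    def test_df1_spans_the_linear_term(self):
        x = np.array([1.0, 2, 2, 3, 5, 6, 9])
        basis = spline_basis(x, 1)
        # {1, basis} and {1, x} must give identical least-squares fits
        y = np.array([0.3, 1.1, 0.9, 2.0, 4.1, 4.8, 8.2])
        X1 = np.column_stack([np.ones_like(x), basis[:, 0]])
        X2 = np.column_stack([np.ones_like(x), x])
        fitted1 = X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
        fitted2 = X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]
        np.testing.assert_allclose(fitted1, fitted2, atol=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ParameterError):
            spline_basis(np.ones(10), 1)

    def test_df2_on_six_classes_has_rank_two_and_centered_columns(self):
        basis = spline_basis(np.arange(1.0, 7.0), 2)
        assert np.linalg.matrix_rank(basis) == 2
        np.testing.assert_allclose(basis.mean(axis=0), 0, atol=1e-12)

    def test_deterministic(self):
        x = np.array([1.0, 3, 4, 4, 6, 2])
        np.testing.assert_array_equal(spline_basis(x, 2), spline_basis(x, 2))


class TestFitNB:
    def test_poisson_data_yields_near_poisson_dispersion(self):
        rng = np.random.default_rng(0)
        n = 2000
        edu = rng.integers(1, 7, n).astype(float)
        mu = np.exp(0.5 + 0.2 * edu)
        y = rng.poisson(mu)
        data = pd.DataFrame(dict(y=y, education=edu))
        terms = [Term("education", "linear", "education")]
        fit = fit_nb(data, "y", terms, term_tests=False)
        assert fit.alpha < 0.05  # variance ~ mean
        poisson = fit_nb(data, "y", terms, alpha=0.0, term_tests=False)
        frame = data
        mu_nb = np.exp(fit.params["(Intercept)"] + fit.params["education"] * frame["education"])
        mu_po = np.exp(
            poisson.params["(Intercept)"] + poisson.params["education"] * frame["education"]
        )
        assert np.max(np.abs(mu_nb / mu_po - 1)) < 0.05

    def test_huge_fixed_theta_matches_poisson_coefficients(self):
        data = _nb_data(1, n=400)
        terms = [Term("education", "linear", "education")]
        near_poisson = fit_nb(data, "y", terms, alpha=1e-10, term_tests=False)
        poisson = fit_nb(data, "y", terms, alpha=0.0, term_tests=False)
        np.testing.assert_allclose(
            near_poisson.params.values, poisson.params.values, atol=1e-4
        )

    def test_intercept_only_model_explains_nothing(self):
        data = _nb_data(2, n=300)
        fit = fit_nb(data, "y", [], term_tests=False)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-8)

    def test_aic_counts_dispersion_parameter(self):
        data = _nb_data(3, n=300)
        fit = fit_nb(data, "y", [Term("education", "linear", "education")], term_tests=False)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * 3)  # 2 coefs + alpha

    def test_deviance_explained_monotone_for_nested_models(self):
        data = _nb_data(4, n=500, beta_noise=0.05)
        # fixed dispersion so deviances are directly comparable
        t_edu = Term("education", "linear", "education")
        t_noise = Term("noise", "linear", "noise")
        small = fit_nb(data, "y", [t_edu], alpha=0.5, term_tests=False)
        big = fit_nb(data, "y", [t_edu, t_noise], alpha=0.5, term_tests=False)
        assert big.deviance_explained >= small.deviance_explained - 1e-10

    def test_aic_ordering_invariant_to_predictor_rescaling(self):
        data = _nb_data(5, n=400)
        terms_a = [Term("education", "linear", "education")]
        fit_a = fit_nb(data, "y", terms_a, term_tests=False)
        scaled = data.assign(education=data["education"] * 10 + 3)
        fit_b = fit_nb(scaled, "y", terms_a, term_tests=False)
        assert fit_a.aic == pytest.approx(fit_b.aic, rel=1e-6)

    def test_casewise_deletion_of_missing_income(self):
        data = _nb_data(6, n=200).assign(income=lambda d: d["noise"])
        data.loc[:9, "income"] = np.nan
        fit = fit_nb(data, "y", [Term("income", "linear", "income")], term_tests=False)
        assert fit.n == 190

    def test_non_integer_response_rejected(self):
        data = pd.DataFrame(dict(y=[0.5, 1.2], education=[1.0, 2.0]))
        with pytest.raises(ParameterError):
            fit_nb(data, "y", [Term("education", "linear", "education")])


class TestEffectTypeSelection:
    def test_linear_truth_selects_type_I_in_majority(self):
        wins = 0
        reps = 11
        for seed in range(reps):
            data = _nb_data(100 + seed, n=1200)
            spec = select_effect_type(data, "y", "education")
            wins += spec.effect_type is EffectType.LINEAR
        assert wins > reps / 2

    def test_gender_specific_curvature_selects_type_IV_in_majority(self):
        wins = 0
        reps = 11
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            n = 1500
            x = rng.integers(1, 7, n).astype(float)
            male = rng.random(n) < 0.5
            # strong quadratic effect among males only
            mu = np.exp(0.8 + np.where(male, 0.35 * (x - 3.5) ** 2 - 0.3 * x, 0.05 * x))
            y = rng.negative_binomial(3.0, 3.0 / (3.0 + mu))
            data = pd.DataFrame(
                dict(y=y, education=x, gender=np.where(male, "male", "female"))
            )
            spec = select_effect_type(data, "y", "education")
            wins += spec.effect_type is EffectType.SMOOTH_BY_GENDER
        assert wins > reps / 2

    def test_without_gender_only_types_I_and_II_compete(self):
        data = _nb_data(7, n=400).drop(columns="gender")
        spec = select_effect_type(data, "y", "education", include_gender=False)
        assert spec.effect_type in (EffectType.LINEAR, EffectType.SMOOTH)


class TestBackwardSelect:
    def test_all_significant_model_is_fixed_point(self):
        data = _nb_data(8, n=1500, beta_edu=0.4)
        terms = [Term("education", "linear", "education")]
        fit = backward_select(data, "y", terms)
        assert [t.name for t in fit.terms] == ["education"]

    def test_noise_predictor_is_eliminated(self):
        dropped = 0
        reps = 10
        for seed in range(reps):
            data = _nb_data(300 + seed, n=800, beta_edu=0.35, beta_noise=0.0)
            terms = [
                Term("education", "linear", "education"),
                Term("noise", "linear", "noise"),
            ]
            fit = backward_select(data, "y", terms)
            names = [t.name for t in fit.terms]
            if "noise" not in names and "education" in names:
                dropped += 1
        assert dropped >= 0.9 * reps

    def test_marginality_protects_main_effect_under_interaction(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.integers(1, 7, n).astype(float)
        male = rng.random(n) < 0.5
        # pure interaction: slope for males only, no average main effect
        mu = np.exp(1.0 + np.where(male, 0.3 * (x - 3.5), -0.3 * (x - 3.5)) * 0 + np.where(male, 0.4, 0.0) * (x - 3.5))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        data = pd.DataFrame(dict(y=y, x=x, gender=np.where(male, "male", "female")))
        terms = EffectSpec("x", EffectType.LINEAR_BY_GENDER).terms()
        fit = backward_select(data, "y", terms)
        names = {t.name for t in fit.terms}
        if "x:gender" in names:  # interaction retained -> x and gender must stay
            assert {"x", "gender"} <= names


def test_merge_terms_deduplicates_gender():
    specs = [
        EffectSpec("age", EffectType.LINEAR_BY_GENDER),
        EffectSpec("education", EffectType.SMOOTH_BY_GENDER),
    ]
    names = [t.name for t in merge_terms(specs)]
    assert names.count("gender") == 1
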