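"""Age transform, prediction, likelihood and prior contracts."""

import math

import numpy as np
import pytest
from scipy import stats

from sitarbayes import (
    IndividualEffects,
    PopulationParameters,
    PriorConfig,
    RandomEffectDistribution,
    build_basis,
    log_likelihood,
    log_prior,
    log_prior_terms,
    predict_height,
    simulate,
    transform_age,
)
from sitarbayes.errors import ContractError
from sitarbayes.model import inverse_transform_age


@pytest.fixture(scope="module")
def pop():
    return PopulationParameters(
        alpha0=140.0, beta=[30.0, 2.0, -1.0, 0.5, 1.5], zeta0=0.2, gamma0=0.05, sigma=0.6
    )


@pytest.fixture(scope="module")
def basis():
    return build_basis(np.linspace(-5, 5, 200), df=5)


class TestTransform:
    def test_identity_case(self):
        assert transform_age(12.0, 11.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_intensity_halves_the_scale(self):
        assert transform_age(13.0, 11.0, 1.0, math.log(2.0)) == pytest.approx(0.5)

    def test_inverse_recovers_age(self, rng):
        for _ in range(100):
            x, zeta, gamma = rng.uniform(6, 18), rng.normal(0, 1), rng.normal(0, 0.3)
            u = transform_age(x, 11.0, zeta, gamma)
            assert inverse_transform_age(u, 11.0, zeta, gamma) == pytest.approx(x, abs=1e-12)

    def test_strictly_increasing_in_age(self):
        x = np.linspace(5, 20, 100)
        u = transform_age(x, 11.0, 0.7, -0.4)
        assert np.all(np.diff(u) > 0)


class TestPredictHeight:
    def test_zero_effects_give_population_curve(self, pop, basis):
        x = np.linspace(7, 15, 20)
        mean_curve = pop.alpha0 + basis.evaluate(
            transform_age(x, 11.0, pop.zeta0, pop.gamma0), 0
        ) @ pop.beta
        np.testing.assert_allclose(
            predict_height(pop, (0, 0, 0), basis, 11.0, x), mean_curve
        )

    def test_size_effect_is_additive(self, pop, basis):
        x = np.linspace(7, 15, 20)
        base = predict_height(pop, (0, 0, 0), basis, 11.0, x)
        shifted = predict_height(pop, (3.0, 0, 0), basis, 11.0, x)
        np.testing.assert_allclose(shifted, base + 3.0, atol=1e-12)

    def test_independent_composition_oracle(self, pop, basis, rng):
        """Recompose transform + basis + dot product by hand."""
        for _ in range(50):
            x = rng.uniform(6, 16)
            eff = rng.normal(0, [2.0, 0.5, 0.08])
            u = (x - 11.0 - pop.zeta0 - eff[1]) * math.exp(-(pop.gamma0 + eff[2]))
            by_hand = pop.alpha0 + eff[0] + float(basis.evaluate(u, 0) @ pop.beta)
            assert predict_height(pop, eff, basis, 11.0, x) == pytest.approx(by_hand, abs=1e-10)


class TestLogLikelihood:
    def test_single_zero_residual_record(self, basis):
        from sitarbayes.cohort import Cohort
        import pandas as pd

        pop = PopulationParameters(alpha0=130.0, beta=np.zeros(5), zeta0=0, gamma0=0, sigma=1.0)
        frame = pd.DataFrame(
            [
                {"id": "A", "sex": "F", "age_years": 10.0, "stature_cm": 130.0},
                {"id": "B", "sex": "F", "age_years": 10.0, "stature_cm": 130.0},
            ]
        )
        cohort = Cohort(frame)
        eff = IndividualEffects(["A", "B"], np.zeros((2, 3)))
        ll = log_likelihood(cohort, pop, eff, basis, 10.0)
        assert ll == pytest.approx(2 * -0.9189385332046727, abs=1e-12)

    def test_doubling_sigma_with_zero_residuals(self, basis, small_cohort):
        n = small_cohort.n_records
        ids = small_cohort.subject_ids
        eff = IndividualEffects(ids, np.zeros((len(ids), 3)))
        pop1 = PopulationParameters(alpha0=130.0, beta=np.zeros(5), zeta0=0, gamma0=0, sigma=1.0)
        pop2 = PopulationParameters(alpha0=130.0, beta=np.zeros(5), zeta0=0, gamma0=0, sigma=2.0)
        data = small_cohort.data.copy()
        data["stature_cm"] = 130.0
        from sitarbayes.cohort import Cohort

        flat = Cohort(data)
        ll1 = log_likelihood(flat, pop1, eff, basis, 11.0)
        ll2 = log_likelihood(flat, pop2, eff, basis, 11.0)
        assert ll2 - ll1 == pytest.approx(-n * math.log(2.0), abs=1e-10)

    def test_brute_force_per_record_oracle(self, basis, small_cohort, rng):
        # residuals at the model's own scale, so the 1e-10 comparison is
        # meaningful in double precision
        from sitarbayes.cohort import Cohort

        from sitarbayes.simulate import calibrate_for_config, default_config

        ref = calibrate_for_config(default_config("F", seed=0))
        u = np.linspace(-5, 5, 200)
        X = np.column_stack([np.ones_like(u), basis.evaluate(u, 0)])
        coef, *_ = np.linalg.lstsq(X, ref.height(u + 11.0), rcond=None)
        pop = PopulationParameters(
            alpha0=float(coef[0]), beta=coef[1:], zeta0=0.2, gamma0=0.05, sigma=0.6
        )
        ids = small_cohort.subject_ids
        eff = IndividualEffects(ids, rng.normal(0, 0.2, size=(len(ids), 3)))
        data = small_cohort.data.copy()
        data["stature_cm"] = [
            predict_height(pop, eff[r["id"]], basis, 11.0, r["age_years"])
            + rng.normal(0, pop.sigma)
            for _, r in data.iterrows()
        ]
        cohort = Cohort(data)
        ll = log_likelihood(cohort, pop, eff, basis, 11.0)
        brute = 0.0
        for _, row in cohort.data.iterrows():
            mu = predict_height(pop, eff[row["id"]], basis, 11.0, row["age_years"])
            brute += stats.norm.logpdf(row["stature_cm"], loc=mu, scale=pop.sigma)
        assert ll == pytest.approx(brute, abs=1e-10)

    def test_missing_effects_is_contract_error(self, pop, basis, small_cohort):
        eff = IndividualEffects(["nobody"], np.zeros((1, 3)))
        with pytest.raises(ContractError):
            log_likelihood(small_cohort, pop, eff, basis, 11.0)


@pytest.fixture()
def prior(girls_run):
    return PriorConfig.from_cohort(girls_run.kept)


@pytest.fixture()
def red():
    corr = np.array([[1.0, 0.1, 0.0], [0.1, 1.0, 0.3], [0.0, 0.3, 1.0]])
    return RandomEffectDistribution(2.5, 0.7, 0.08, corr)


class TestPriors:

    def test_zeta0_prior_mode_at_zero(self, prior, red):
        def at(z0):
            pop = PopulationParameters(prior.alpha0_loc, np.zeros(5), z0, 0.0, 0.5)
            return log_prior(pop, red, prior)

        assert at(0.0) > at(0.5) and at(0.0) > at(-0.5)

    def test_gamma0_prior_unimodal_decreasing(self, prior, red):
        def at(g0):
            pop = PopulationParameters(prior.alpha0_loc, np.zeros(5), 0.0, g0, 0.5)
            return log_prior(pop, red, prior)

        vals = [at(g) for g in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_total_equals_independent_term_summation(self, prior, red):
        pop = PopulationParameters(prior.alpha0_loc + 3, np.full(5, 2.0), 0.3, -0.2, 0.8)
        terms = log_prior_terms(pop, red, prior)
        # each component recomputed with scipy, independently of the package
        expected = {
            "alpha0": stats.norm.logpdf(pop.alpha0, prior.alpha0_loc, prior.alpha0_scale),
            "beta": stats.norm.logpdf(pop.beta, 0, prior.beta_scale).sum(),
            "zeta0": stats.norm.logpdf(pop.zeta0, 0, prior.zeta0_scale),
            "gamma0": stats.norm.logpdf(pop.gamma0, 0, prior.gamma0_scale),
            "sigma": stats.t.logpdf(pop.sigma / prior.sigma_scale, prior.sigma_df)
            + math.log(2.0) - math.log(prior.sigma_scale),
            "sd_alpha": stats.halfnorm.logpdf(red.sd_alpha, scale=prior.sd_alpha_scale),
            "sd_zeta": stats.halfnorm.logpdf(red.sd_zeta, scale=prior.sd_zeta_scale),
            "sd_gamma": stats.halfnorm.logpdf(red.sd_gamma, scale=prior.sd_gamma_scale),
            "correlation": (prior.lkj_eta - 1.0) * np.linalg.slogdet(red.correlation)[1],
        }
        for name, value in expected.items():
            assert terms[name] == pytest.approx(value, abs=1e-10), name
        assert log_prior(pop, red, prior) == pytest.approx(sum(expected.values()), abs=1e-9)

    def test_domain_boundary_gives_minus_infinity(self, prior):
        bad_corr = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        red = RandomEffectDistribution(1.0, 1.0, 1.0, bad_corr)  # not PD
        pop = PopulationParameters(prior.alpha0_loc, np.zeros(5), 0, 0, 0.5)
        assert log_prior(pop, red, prior) == -np.inf
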