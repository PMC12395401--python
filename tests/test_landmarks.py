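"""Velocity curves and landmark extraction: analytic oracles, closed forms,
equivariances."""

import math

import numpy as np
import pytest

from sitarbayes import (
    GrowthLandmarks,
    find_peak,
    find_takeoff,
    individual_landmarks,
    population_landmarks,
    velocity,
)
from sitarbayes.errors import ContractError, LandmarkNotFoundError
from sitarbayes.landmarks import VelocityCurve, _FunctionCurve
from sitarbayes.model import transform_age


class TestSearchOnAnalyticCurves:
    def test_parabola_peak(self):
        age, vel = find_peak(lambda x: 9.0 - (x - 12.0) ** 2, (8.0, 16.0))
        assert age == pytest.approx(12.0, abs=1e-6)
        assert vel == pytest.approx(9.0, abs=1e-9)

    def test_cubic_peak_and_takeoff(self):
        v = lambda x: -((x - 10.0) ** 3) + 3.0 * (x - 10.0) + 6.0
        age, vel = find_peak(v, (8.0, 13.0))
        assert age == pytest.approx(11.0, abs=1e-6)
        assert vel == pytest.approx(8.0, abs=1e-6)
        t_age, t_vel, boundary = find_takeoff(v, age, (8.0, age))
        assert t_age == pytest.approx(9.0, abs=1e-6)
        assert t_vel == pytest.approx(4.0, abs=1e-6)
        assert not boundary

    def test_monotone_curve_has_no_peak(self):
        with pytest.raises(LandmarkNotFoundError):
            find_peak(lambda x: 2.0 * x, (8.0, 16.0))

    def test_monotone_prepeak_velocity_flags_boundary(self):
        v = lambda x: 9.0 - (x - 12.0) ** 2  # increasing all the way to the peak
        t_age, _, boundary = find_takeoff(v, 12.0, (8.0, 12.0))
        assert boundary
        assert t_age == pytest.approx(8.0, abs=1e-3)

    def test_empty_takeoff_window_rejected(self):
        with pytest.raises(ContractError):
            find_takeoff(lambda x: x, 8.0, (9.0, 12.0))


class TestVelocity:
    def test_matches_finite_difference_of_height(self, girls_run, rng):
        from sitarbayes import predict_height

        fit = girls_run.fit
        pop = fit.population_parameters(0)
        eff = (1.0, 0.3, 0.05)
        h = 1e-5
        for x in rng.uniform(7.5, 15.0, size=50):
            fd = (
                predict_height(pop, eff, fit.basis, fit.x_bar, x + h)
                - predict_height(pop, eff, fit.basis, fit.x_bar, x - h)
            ) / (2 * h)
            assert velocity(pop, eff, fit.basis, fit.x_bar, x) == pytest.approx(fd, abs=1e-5)

    def test_intensity_effect_halves_velocity_at_transformed_point(self, girls_run):
        fit = girls_run.fit
        pop = fit.population_parameters(0)
        x0 = 11.0
        u0 = transform_age(x0, fit.x_bar, pop.zeta0, pop.gamma0)
        v0 = velocity(pop, (0, 0, 0), fit.basis, fit.x_bar, x0)
        g_i = math.log(2.0)
        # same transformed age u0 under the stretched clock
        x1 = fit.x_bar + pop.zeta0 + u0 * math.exp(pop.gamma0 + g_i)
        v1 = velocity(pop, (0, 0, g_i), fit.basis, fit.x_bar, x1)
        assert v1 == pytest.approx(0.5 * v0, abs=1e-9)

    def test_size_effects_never_move_velocity(self, girls_run):
        fit = girls_run.fit
        pop = fit.population_parameters(0)
        x = np.linspace(7, 15, 40)
        np.testing.assert_allclose(
            velocity(pop, (5.0, 0, 0), fit.basis, fit.x_bar, x),
            velocity(pop, (0.0, 0, 0), fit.basis, fit.x_bar, x),
            atol=1e-12,
        )


class TestPopulationLandmarks:
    def test_grid_search_oracle(self, girls_run):
        fit = girls_run.fit
        pop = fit.population_parameters(0)
        lo, hi = fit.meta["age_window"]
        grid = np.linspace(lo, hi, 10_000)
        v = velocity(pop, (0, 0, 0), fit.basis, fit.x_bar, grid)
        marks = girls_run.pop
        assert abs(marks.aphv[0] - grid[np.argmax(v)]) < 1e-3
        pre = grid[grid < marks.aphv[0]]
        vpre = v[grid < marks.aphv[0]]
        # pre-peak velocity falls to the takeoff dip then rises to the peak,
        # so the takeoff is the pre-peak grid minimum
        assert abs(marks.atgv[0] - pre[np.argmin(vpre)]) < 1e-3

    def test_single_draw_interval_collapses(self, girls_run):
        marks = girls_run.pop
        for name in ("atgv", "tgv", "aphv", "phv"):
            est, lo, hi = getattr(marks, name)
            assert lo == pytest.approx(est) and hi == pytest.approx(est)

    def test_ordering_invariants(self, girls_run, boys_run):
        for run in (girls_run, boys_run):
            assert run.pop.atgv[0] < run.pop.aphv[0]
            assert run.pop.tgv[0] < run.pop.phv[0]

    def test_interval_is_16_84_percentile_of_draw_sample(self, girls_run):
        """Quantile oracle on a synthetic multi-draw fit built by jittering
        the MAP draw."""
        import copy

        fit = copy.deepcopy(girls_run.fit)
        rng = np.random.default_rng(0)
        S = 40
        d = fit.draws
        for name in ("alpha0", "zeta0", "gamma0", "sigma"):
            setattr(d, name, np.repeat(getattr(d, name), S))
        d.zeta0 = d.zeta0 + rng.normal(0, 0.1, S)
        d.beta = np.repeat(d.beta, S, axis=0)
        d.sd = np.repeat(d.sd, S, axis=0)
        d.corr_offdiag = np.repeat(d.corr_offdiag, S, axis=0)
        d.effects = np.repeat(d.effects, S, axis=0)
        marks = population_landmarks(fit)
        # per-draw APHV shifts one-for-one with zeta0 here (shared beta/gamma)
        base = girls_run.pop.aphv[0]
        sample = base + (d.zeta0 - girls_run.fit.draws.zeta0[0])
        sample.sort()
        lo = float(np.percentile(sample, 16))
        hi = float(np.percentile(sample, 84))
        assert marks.aphv[1] == pytest.approx(lo, abs=1e-6)
        assert marks.aphv[2] == pytest.approx(hi, abs=1e-6)


class TestIndividualLandmarks:
    def test_zero_effect_subject_equals_population(self, girls_run):
        import copy

        fit = copy.deepcopy(girls_run.fit)
        fit.draws.effects[0, 0, :] = 0.0  # force one subject onto the mean curve
        ind = individual_landmarks(fit)
        pop = population_landmarks(fit)
        row = ind.estimates.iloc[0]
        for name in ("atgv", "tgv", "aphv", "phv"):
            assert row[name] == pytest.approx(getattr(pop, name)[0], abs=1e-9)

    def test_pure_timing_shift(self, girls_run):
        import copy

        fit = copy.deepcopy(girls_run.fit)
        fit.draws.effects[0, 0, :] = 0.0
        fit.draws.effects[0, 1, :] = [0.0, 0.5, 0.0]
        ind = individual_landmarks(fit)
        a, b = ind.estimates.iloc[0], ind.estimates.iloc[1]
        assert b["aphv"] - a["aphv"] == pytest.approx(0.5, abs=1e-9)
        assert b["atgv"] - a["atgv"] == pytest.approx(0.5, abs=1e-9)
        assert b["phv"] == pytest.approx(a["phv"], abs=1e-9)

    def test_intensity_scaling_closed_form(self, girls_run):
        import copy

        fit = copy.deepcopy(girls_run.fit)
        g_i = -math.log(0.9)  # exp(-gamma_i) = 0.9
        fit.draws.effects[0, 0, :] = 0.0
        fit.draws.effects[0, 1, :] = [0.0, 0.0, g_i]
        ind = individual_landmarks(fit)
        a, b = ind.estimates.iloc[0], ind.estimates.iloc[1]
        assert b["phv"] == pytest.approx(0.9 * a["phv"], abs=1e-9)
        assert b["tgv"] == pytest.approx(0.9 * a["tgv"], abs=1e-9)

    def test_closed_forms_agree_with_direct_search(self, girls_run, rng):
        """The u-scale mapping must reproduce a per-subject numeric search."""
        fit = girls_run.fit
        pop = fit.population_parameters(0)
        ind = individual_landmarks(fit)
        lo, hi = fit.meta["age_window"]
        for j in rng.choice(len(ind.subject_ids), size=12, replace=False):
            eff = fit.draws.effects[0, j]
            curve = VelocityCurve(
                basis=fit.basis,
                x_bar=fit.x_bar,
                beta=pop.beta,
                zeta_total=pop.zeta0 + eff[1],
                gamma_total=pop.gamma0 + eff[2],
            )
            w_lo = lo + eff[1] - 1.0
            w_hi = hi + eff[1] + 1.0
            aphv, phv = find_peak(curve, (w_lo, w_hi))
            row = ind.estimates.iloc[j]
            assert row["aphv"] == pytest.approx(aphv, abs=1e-6)
            assert row["phv"] == pytest.approx(phv, abs=1e-6)


def test_growth_landmarks_export_shape(girls_run):
    frame = girls_run.pop.to_frame(level="pop", sex="F")
    assert list(frame["landmark"]) == ["atgv", "tgv", "aphv", "phv"]
    assert (frame["level"] == "pop").all()
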