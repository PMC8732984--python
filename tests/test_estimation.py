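"""Objective, bounded simplex search and the staged estimation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from shakeflask.estimation import (
    DEFAULT_FIXED_RADIATIVE,
    DEFAULT_LIGHT_FREE,
    DEFAULT_NITRATE_FREE,
    EstimationSpec,
    FreeParam,
    NonIdentifiableError,
    StageOrderError,
    bounded_simplex_minimize,
    fit_growth_params,
    fit_light_params,
    fit_nitrate_params,
    growth_spec_from_stage2,
    objective,
    _FlaskCache,
)
from shakeflask.radiative import FlaskGeometry, RadiativeParams
from shakeflask.synthdata import (
    ExperimentDesign,
    TRUE_KINETICS,
    generate_cultivations,
    generate_light_scans,
    reference_design,
)

TRUTH_KIN = (TRUE_KINETICS.mu_max, TRUE_KINETICS.mu_d, TRUE_KINETICS.K_I,
             TRUE_KINETICS.K_N, TRUE_KINETICS.Y_NX)


class TestObjective:
    def test_identical_series_score_zero(self):
        assert objective([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_worked_value(self):
        # residuals (0, 1) normalised by max(obs)=2: (0/2)^2 + (1/2)^2
        assert objective([1.0, 3.0], [1.0, 2.0]) == pytest.approx(0.25)

    def test_scale_invariance(self):
        sim, obs = [1.0, 3.0, 2.5], [1.2, 2.8, 2.4]
        base = objective(sim, obs)
        assert objective([2 * s for s in sim], [2 * o for o in obs]) == pytest.approx(base)

    def test_multiple_datasets_sum_with_own_normalisation(self):
        got = objective([[1.0, 3.0], [10.0, 30.0]], [[1.0, 2.0], [10.0, 20.0]])
        assert got == pytest.approx(0.25 + 0.25)

    def test_scaled_mode(self):
        # squared residual divided by max(obs): 1/2
        assert objective([1.0, 3.0], [1.0, 2.0], mode="scaled") == pytest.approx(0.5)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            objective([], [])
        with pytest.raises(ValueError):
            objective([1.0], [0.0])
        with pytest.raises(ValueError):
            objective([1.0, 2.0], [1.0])


class TestBoundedSimplex:
    TIGHT = dict(xatol=1e-10, fatol=1e-12, maxiter=2000, maxfev=4000)

    def test_interior_quadratic_minimum(self):
        res = bounded_simplex_minimize(
            lambda x: (x[0] - 1.3) ** 2 + (x[1] + 0.4) ** 2,
            [0.0, 0.0], bounds=[(-5.0, 5.0), (-5.0, 5.0)], **self.TIGHT,
        )
        assert res.x == pytest.approx([1.3, -0.4], abs=1e-6)

    def test_exterior_minimum_lands_near_boundary(self):
        res = bounded_simplex_minimize(
            lambda x: (x[0] - 10.0) ** 2, [0.5], bounds=[(0.0, 1.0)], **self.TIGHT,
        )
        assert res.x[0] == pytest.approx(1.0, abs=1e-4)
        assert res.x[0] <= 1.0

    def test_iterates_respect_bounds(self):
        seen = []

        def fn(x):
            seen.append(float(x[0]))
            return (x[0] - 0.9) ** 2

        bounded_simplex_minimize(fn, [0.5], bounds=[(0.0, 1.0)], **self.TIGHT)
        assert all(0.0 <= v <= 1.0 for v in seen)

    def test_wide_bounds_agree_with_unconstrained_simplex(self):
        def rosen(x):
            return (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2

        free = minimize(rosen, [0.0, 0.0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000,
                                 "maxfev": 10000})
        wide = bounded_simplex_minimize(rosen, [0.0, 0.0],
                                        bounds=[(-100.0, 100.0)] * 2, **self.TIGHT)
        assert wide.x == pytest.approx(free.x, abs=1e-3)

    def test_rejects_nonfinite_start(self):
        with pytest.raises(ValueError):
            bounded_simplex_minimize(lambda x: np.nan, [0.0])
        with pytest.raises(ValueError):
            bounded_simplex_minimize(lambda x: x[0] ** 2, [2.0], bounds=[(0.0, 1.0)])


@pytest.fixture(scope="module")
def noisefree_scans():
    return generate_light_scans(RadiativeParams(), noise_rsd=0.0, seed=0)


class TestLightStage:
    def test_noise_free_round_trip_recovers_generator(self, noisefree_scans):
        """Self-consistency: a fit started at the generating optical
        parameters reproduces them (the objective is already zero there)."""
        spec = EstimationSpec(
            free=(FreeParam("E_a", 227.0), FreeParam("E_s", 800.0), FreeParam("b", 0.0008)),
            n_restarts=1, perturb_rsd=0.0,
        )
        res = fit_light_params(noisefree_scans, spec)
        assert res.mean["E_a"] == pytest.approx(227.0, rel=1e-4)
        assert res.mean["E_s"] == pytest.approx(800.0, rel=1e-4)
        assert res.mean["b"] == pytest.approx(0.0008, rel=1e-4)
        assert res.samples["objective"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_fit_matches_effective_extinction(self, noisefree_scans):
        """From the literature start the fit pins the identifiable effective
        extinction coefficient even though (E_s, b) individually are not
        identified (only their product enters the model)."""
        spec = EstimationSpec(free=DEFAULT_LIGHT_FREE, n_restarts=3,
                              perturb_params=True, seed=0)
        res = fit_light_params(noisefree_scans, spec)
        fitted = RadiativeParams(E_a=res.mean["E_a"], E_s=res.mean["E_s"], b=res.mean["b"])
        assert fitted.epsilon == pytest.approx(RadiativeParams().epsilon, rel=1e-3)

    def test_pure_medium_scans_not_identifiable(self):
        scans = generate_light_scans(concentrations=[0.0], noise_rsd=0.0, seed=0)
        with pytest.raises(NonIdentifiableError):
            fit_light_params(scans)

    def test_single_concentration_not_identifiable(self):
        scans = generate_light_scans(concentrations=[1.0], noise_rsd=0.0, seed=0)
        with pytest.raises(NonIdentifiableError):
            fit_light_params(scans)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            fit_light_params(pd.DataFrame({"z_m": [0.01]}))


@pytest.fixture(scope="module")
def nitrate_flasks_zero_noise():
    design = reference_design(seed=0)
    d6 = ExperimentDesign(settings=((536.0, 12.0, 3), (1200.0, 12.0, 3)),
                          nitrate_measured=design.nitrate_measured, seed=0, noise_rsd=0.0)
    return generate_cultivations(d6)


class TestCultureStages:
    def test_objective_at_truth_is_zero_on_zero_noise_data(self, nitrate_flasks_zero_noise):
        cache = _FlaskCache(nitrate_flasks_zero_noise[0], FlaskGeometry(),
                            DEFAULT_FIXED_RADIATIVE, RadiativeParams().i0_coeffs, True)
        assert cache.sse(TRUTH_KIN, cache.X0_obs, cache.cN0_obs, 0.25, "relative") < 1e-8

    def test_truth_started_fit_returns_truth_on_zero_noise_data(self, nitrate_flasks_zero_noise):
        free = tuple(
            FreeParam(n, v, 0.5 * v, 1.5 * v)
            for n, v in zip(("mu_max", "mu_d", "K_I", "K_N", "Y_NX"), TRUTH_KIN)
        )
        spec = EstimationSpec(free=free, n_restarts=1, perturb_rsd=0.0, seed=0)
        res = fit_nitrate_params(nitrate_flasks_zero_noise, spec)
        assert res.samples["objective"].iloc[0] < 1e-6
        for name, v in zip(res.param_names, TRUTH_KIN):
            assert res.mean[name] == pytest.approx(v, rel=1e-3)

    def test_requires_nitrate_measurements(self):
        d = ExperimentDesign(settings=((536.0, 12.0, 3),), nitrate_measured=(), seed=0)
        with pytest.raises(NonIdentifiableError):
            fit_nitrate_params(generate_cultivations(d))

    def test_growth_stage_refuses_without_fixed_prerequisites(self, nitrate_flasks_zero_noise):
        plan = pd.DataFrame(
            {"run_id": [0, 0], "dataset_id": [d.flask_id for d in nitrate_flasks_zero_noise[:2]],
             "role": ["train", "validation"]}
        )
        spec = EstimationSpec(free=(FreeParam("mu_max", 0.1, 0.05, 0.2),),
                              fixed={"E_a": 227.0})  # K_N, Y_NX, E_s, b missing
        with pytest.raises(StageOrderError, match="K_N"):
            fit_growth_params(nitrate_flasks_zero_noise, spec, plan)

    def test_growth_stage_rejects_test_leakage(self, nitrate_flasks_zero_noise):
        ids = [d.flask_id for d in nitrate_flasks_zero_noise[:2]]
        plan = pd.DataFrame(
            {"run_id": [0, 0, -1], "dataset_id": [ids[0], ids[1], ids[0]],
             "role": ["train", "validation", "test"]}
        )
        spec = growth_spec_from_stage2_like()
        with pytest.raises(ValueError, match="never be trained"):
            fit_growth_params(nitrate_flasks_zero_noise, spec, plan)

    def test_restart_determinism(self, nitrate_flasks_zero_noise):
        spec = EstimationSpec(free=DEFAULT_NITRATE_FREE, n_restarts=2, seed=7)
        a = fit_nitrate_params(nitrate_flasks_zero_noise, spec)
        b = fit_nitrate_params(nitrate_flasks_zero_noise, spec)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_growth_spec_from_stage2_builds_bounds_and_fixed(self):
        mean = pd.Series({"mu_max": 0.14, "mu_d": 0.0018, "K_I": 100.0,
                          "K_N": 2e-4, "Y_NX": 0.25})
        stage2 = _result_with_mean(mean)
        spec = growth_spec_from_stage2(stage2, n_restarts=5, seed=3)
        assert [p.name for p in spec.free] == ["mu_max", "mu_d", "K_I"]
        mu = spec.free[0]
        assert (mu.start, mu.lb, mu.ub) == (0.14, pytest.approx(0.07), pytest.approx(0.21))
        assert spec.fixed["K_N"] == 2e-4 and spec.fixed["Y_NX"] == 0.25
        assert spec.fixed["E_a"] == 227.0

    def test_growth_parameter_compensation_ridge(self):
        """Doubling K_I is almost recoverable by raising mu_max in step: the
        two parameters trade off along a ridge, so widening the K_I bound
        lets the pair drift jointly."""
        d = ExperimentDesign(settings=((536.0, 12.0, 2), (1200.0, 12.0, 2)),
                             nitrate_measured=(), seed=3)
        caches = [_FlaskCache(x, FlaskGeometry(), DEFAULT_FIXED_RADIATIVE,
                              RadiativeParams().i0_coeffs, False)
                  for x in generate_cultivations(d)]

        def obj(mu, KI):
            kin = (mu, 0.002, KI, 1.49e-4, 0.245)
            return sum(c.sse(kin, c.X0_obs, c.cN0_obs, 0.25, "relative") for c in caches)

        truth, comp = obj(0.135, 96.0), obj(0.20, 192.0)
        assert comp < 0.15 * obj(0.20, 96.0)
        assert comp < 0.15 * obj(0.135, 192.0)
        assert comp > truth


def growth_spec_from_stage2_like():
    return EstimationSpec(
        free=(FreeParam("mu_max", 0.135, 0.07, 0.2),
              FreeParam("mu_d", 0.002, 0.001, 0.003),
              FreeParam("K_I", 96.0, 48.0, 144.0)),
        fixed={**DEFAULT_FIXED_RADIATIVE, "K_N": 1.49e-4, "Y_NX": 0.245},
        n_restarts=1, perturb_rsd=0.0,
    )


def _result_with_mean(mean: pd.Series):
    from shakeflask.estimation import EstimationResult

    return EstimationResult(
        param_names=list(mean.index),
        samples=pd.DataFrame([{"run": 0, "restart": 0, **mean}]),
        mean=mean, cv_percent=mean * 0.0,
    )


class TestSpecValidation:
    def test_free_param_bounds(self):
        with pytest.raises(ValueError):
            FreeParam("x", 0.5, 1.0, 2.0)  # start outside bounds
        with pytest.raises(ValueError):
            FreeParam("x", 0.5, 1.0, None)
        with pytest.raises(ValueError):
            FreeParam("x", 0.5, 2.0, 1.0)

    def test_spec_rejects_duplicates_and_bad_modes(self):
        with pytest.raises(ValueError):
            EstimationSpec(free=(FreeParam("a", 1.0), FreeParam("a", 2.0)))
        with pytest.raises(ValueError):
            EstimationSpec(objective_mode="fancy")
        with pytest.raises(ValueError):
            EstimationSpec(n_restarts=0)
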