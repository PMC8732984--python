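"""Growth law, mass balances, sampling events and trajectory integration."""

import numpy as np
import pytest

from shakeflask.kinetics import (
    CultureState,
    KineticParams,
    SamplingSchedule,
    apply_sampling_event,
    growth_rate,
    ode_rhs,
    simulate,
)
from shakeflask.radiative import FlaskGeometry, LightSetting, RadiativeParams, incident_intensity

#: Effectively transparent suspension: optical depth ~1e-11 over the column,
#: so the average intensity equals the incident intensity to ~1e-10.
CLEAR = RadiativeParams(E_a=1e-9, E_s=0.0, b=0.0)
NO_SAMPLING = SamplingSchedule(sample_times=())


class TestGrowthRate:
    def test_double_half_saturation_gives_quarter_mu_max(self):
        kp = KineticParams(mu_max=0.12, K_I=80.0, K_N=0.001)
        assert growth_rate(80.0, 0.001, kp) == pytest.approx(0.03)

    def test_saturation_approaches_mu_max(self):
        kp = KineticParams(mu_max=0.135)
        assert growth_rate(1e9, 1e9, kp) == pytest.approx(0.135, rel=1e-6)
        assert growth_rate(1e3, 1.0, kp) < kp.mu_max

    def test_worked_value_under_light_limitation(self):
        kp = KineticParams(mu_max=0.135, K_I=96.0, K_N=1.49e-4)
        assert growth_rate(200.0, 100.0, kp) == pytest.approx(0.09122, abs=2e-5)

    def test_zero_light_or_nitrate_stops_growth(self):
        kp = KineticParams()
        assert growth_rate(0.0, 1.0, kp) == 0.0
        assert growth_rate(100.0, 0.0, kp) == 0.0

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            growth_rate(-1.0, 1.0, KineticParams())


class TestOdeRhs:
    def test_no_biomass_means_no_change(self):
        state = CultureState(X=0.0, V=0.2, c_N=0.5)
        dX, dV, dcN = ode_rhs(state, 3.0, LightSetting(536.0, 24.0), KineticParams(),
                              RadiativeParams(), NO_SAMPLING)
        assert dX == 0.0 and dV == 0.0 and dcN == 0.0

    def test_batch_exponential_limit(self):
        """Saturating light and nitrate, no death, no flow: dX/dt = mu_max X."""
        kp = KineticParams(mu_max=0.1, mu_d=0.0, K_I=1e-6, K_N=1e-6, Y_NX=0.0)
        state = CultureState(X=0.5, V=0.2, c_N=100.0)
        dX, _, _ = ode_rhs(state, 1.0, LightSetting(1200.0, 24.0), kp, CLEAR, NO_SAMPLING)
        assert dX == pytest.approx(kp.mu_max * state.X, rel=1e-5)

    def test_matched_feed_and_sampling_keep_volume(self):
        sched = SamplingSchedule(mode="continuous", F_M=0.01, F_S=0.01)
        state = CultureState(X=1.0, V=0.2, c_N=0.5)
        _, dV, _ = ode_rhs(state, 1.0, LightSetting(536.0, 12.0), KineticParams(),
                           RadiativeParams(), sched)
        assert dV == 0.0


class TestSamplingEvent:
    def test_dilution_arithmetic(self):
        s = apply_sampling_event(CultureState(X=1.0, V=0.2, c_N=0.3), 0.0075, 1.0)
        assert s.X == pytest.approx(0.9625)
        assert s.V == 0.2
        assert s.c_N == pytest.approx(0.3 * 0.9625 + 1.0 * 0.0375)

    def test_zero_volume_is_identity(self):
        before = CultureState(X=1.2, V=0.2, c_N=0.4)
        after = apply_sampling_event(before, 0.0, 1.0)
        assert (after.X, after.V, after.c_N) == (before.X, before.V, before.c_N)

    def test_feed_matching_culture_leaves_nitrate(self):
        s = apply_sampling_event(CultureState(X=1.0, V=0.2, c_N=0.7), 0.01, 0.7)
        assert s.c_N == pytest.approx(0.7)

    def test_rejects_overdraw(self):
        with pytest.raises(ValueError):
            apply_sampling_event(CultureState(X=1.0, V=0.2, c_N=0.3), 0.2, 1.0)


@pytest.mark.parametrize("method", ["lsoda", "rk4"])
class TestSimulateOracles:
    def test_exponential_closed_form(self, method):
        """Transparent suspension, continuous light, saturating nitrate and no
        sampling reduce to pure exponential growth."""
        kp = KineticParams(mu_max=0.135, mu_d=0.0, K_I=96.0, K_N=1.49e-4, Y_NX=0.0)
        setting = LightSetting(I_S=1200.0, L=24.0)
        I0 = incident_intensity(1200.0)
        mu = kp.mu_max * I0 / (kp.K_I + I0)
        t_end = 1.35 / mu  # so that mu * t = 1.35
        t_grid = np.linspace(0.0, t_end, 7)
        traj = simulate(CultureState(X=0.1, V=0.2, c_N=1e6), setting, kp, CLEAR,
                        FlaskGeometry(), NO_SAMPLING, t_grid, method=method)
        expected = 0.1 * np.exp(mu * t_grid)
        assert traj["biomass_g_per_L"].to_numpy() == pytest.approx(expected, rel=1e-6)
        assert traj["biomass_g_per_L"].iloc[-1] == pytest.approx(0.38577, rel=1e-4)

    def test_dark_decay(self, method):
        kp = KineticParams(mu_max=0.135, mu_d=0.002)
        t_grid = np.linspace(0.0, 120.0, 6)
        traj = simulate(CultureState(X=1.0, V=0.2, c_N=1.0), LightSetting(536.0, 0.0),
                        kp, RadiativeParams(), FlaskGeometry(), NO_SAMPLING, t_grid,
                        method=method)
        assert traj["biomass_g_per_L"].to_numpy() == pytest.approx(
            np.exp(-0.002 * t_grid), rel=1e-6
        )

    def test_nitrate_bookkeeping(self, method):
        """Without feed or death, nitrate consumed equals yield times biomass
        formed: Y_NX * dX = -dc_N."""
        kp = KineticParams(mu_max=0.135, mu_d=0.0, K_I=96.0, K_N=1.49e-4, Y_NX=0.245)
        t_grid = np.linspace(0.0, 96.0, 9)
        traj = simulate(CultureState(X=0.1, V=0.2, c_N=1.0), LightSetting(536.0, 12.0),
                        kp, RadiativeParams(), FlaskGeometry(), NO_SAMPLING, t_grid,
                        method=method)
        dX = traj["biomass_g_per_L"] - 0.1
        dN = 1.0 - traj["nitrate_g_per_L"]
        assert (kp.Y_NX * dX).to_numpy() == pytest.approx(dN.to_numpy(), abs=1e-4)

    def test_volume_constant_with_sample_replacement(self, method):
        t_grid = np.arange(0.0, 241.0, 24.0)
        sched = SamplingSchedule(sample_times=tuple(t_grid[1:]))
        traj = simulate(CultureState(X=0.1, V=0.2, c_N=1.0), LightSetting(536.0, 12.0),
                        KineticParams(), RadiativeParams(), FlaskGeometry(), sched,
                        t_grid, method=method)
        assert traj["volume_L"].to_numpy() == pytest.approx(0.2)
        assert (traj["biomass_g_per_L"] >= 0).all()
        assert (traj["nitrate_g_per_L"] >= 0).all()


class TestSimulateNumerics:
    def test_output_grid_refinement_invariance(self, standard_initial, setting_536,
                                               geometry, daily_schedule, daily_grid):
        """Adding output points must not change the trajectory at shared
        times: the adaptive integrator steps between physical events only."""
        kp, rp = KineticParams(), RadiativeParams()
        coarse = simulate(standard_initial, setting_536, kp, rp, geometry,
                          daily_schedule, daily_grid)
        fine_grid = np.arange(0.0, 240.1, 2.0)
        fine = simulate(standard_initial, setting_536, kp, rp, geometry,
                        daily_schedule, fine_grid)
        shared = np.isin(fine_grid, daily_grid)
        np.testing.assert_allclose(
            fine["biomass_g_per_L"].to_numpy()[shared],
            coarse["biomass_g_per_L"].to_numpy(),
            rtol=1e-8,
        )

    def test_impulsive_and_continuous_sampling_converge(self, standard_initial,
                                                        setting_536, geometry):
        """As the per-event sample volume shrinks (with the matching
        continuous rate), the two formulations approach each other."""
        kp, rp = KineticParams(), RadiativeParams()
        t_grid = np.arange(0.0, 241.0, 24.0)
        diffs = []
        for V_s in (7.5e-3, 7.5e-4):
            imp = simulate(standard_initial, setting_536, kp, rp, geometry,
                           SamplingSchedule(sample_times=tuple(t_grid[1:]), V_sample=V_s),
                           t_grid)
            cont = simulate(standard_initial, setting_536, kp, rp, geometry,
                            SamplingSchedule(mode="continuous", F_M=V_s / 24.0,
                                             F_S=V_s / 24.0),
                            t_grid)
            diffs.append(np.max(np.abs(
                imp["biomass_g_per_L"].to_numpy() / cont["biomass_g_per_L"].to_numpy() - 1
            )))
        assert diffs[1] < diffs[0] / 3
        assert diffs[1] < 5e-3

    def test_nitrate_floor_and_growth_arrest(self):
        """When nitrate runs out the concentration clamps at zero and biomass
        switches to first-order decay."""
        kp = KineticParams(mu_max=0.135, mu_d=0.002, K_I=96.0, K_N=1.49e-4, Y_NX=0.245)
        t_grid = np.arange(0.0, 241.0, 24.0)
        sched = SamplingSchedule(sample_times=tuple(t_grid[1:]))
        traj = simulate(CultureState(X=0.1, V=0.2, c_N=1.0), LightSetting(1200.0, 12.0),
                        kp, RadiativeParams(), FlaskGeometry(), sched, t_grid)
        n = traj["nitrate_g_per_L"].to_numpy()
        X = traj["biomass_g_per_L"].to_numpy()
        assert n.min() >= 0.0
        assert n[-1] == pytest.approx(0.0, abs=1e-9)
        assert X[-1] < X.max()  # post-depletion decline

    def test_invalid_grid_rejected(self, standard_initial, setting_536, geometry):
        with pytest.raises(ValueError):
            simulate(standard_initial, setting_536, KineticParams(), RadiativeParams(),
                     geometry, NO_SAMPLING, [0.0, 0.0, 1.0])


class TestDomainTypes:
    def test_kinetic_invariants(self):
        with pytest.raises(ValueError):
            KineticParams(mu_max=0.1, mu_d=0.2)
        with pytest.raises(ValueError):
            KineticParams(K_I=-1.0)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            CultureState(X=-0.1, V=0.2, c_N=0.0)
        with pytest.raises(ValueError):
            CultureState(X=0.1, V=0.0, c_N=0.0)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            SamplingSchedule(mode="weekly")
        with pytest.raises(ValueError):
            SamplingSchedule(V_sample=-1.0)
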