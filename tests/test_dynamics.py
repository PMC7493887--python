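"""Unit and property tests for the host-virus dynamical models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysodyn import dynamics as dyn
from lysodyn.dynamics import (
    ConfigurationError,
    GrowthSchedule,
    InductionRule,
    ModelParameters,
    SimulationState,
    TEMPERATE_PHENOMENOLOGICAL,
    TEMPERATE_SELF_REGULATED,
    VIRULENT,
    default_adsorption_rate,
    derivatives,
    effective_growth_rate,
    induction_state,
    preinfection_fraction,
    realized_growth_rates,
    simulate,
    simulate_delayed_virulent,
)

ATOL_CONC = 1e3  # one cell/mL, in per-liter units


def rel_close(a, b, rtol, floor=ATOL_CONC):
    return np.max(np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)),
                                             floor)) <= rtol


class TestGrowthSchedule:
    def test_plateau_and_floor_segments(self):
        s = GrowthSchedule(mu_max=1.0, mu_min=0.1, t_mu=12.0)
        assert effective_growth_rate(1.0, s) == 1.0
        assert effective_growth_rate(17.0, s) == 0.1

    def test_linear_segment_interpolates(self):
        # closed form: mu_max + (mu_min - mu_max)*(t - 2)/(t_mu - 2)
        s = GrowthSchedule(mu_max=1.0, mu_min=0.1, t_mu=12.0)
        assert effective_growth_rate(7.0, s) == pytest.approx(0.55, abs=1e-12)

    @given(mu_max=st.floats(0.2, 3.0), mu_min=st.floats(0.0, 0.2),
           t_mu=st.floats(3.0, 30.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_continuity_at_breakpoints(self, mu_max, mu_min, t_mu):
        s = GrowthSchedule(mu_max=mu_max, mu_min=mu_min, t_mu=t_mu)
        # continuity conditions hold by construction of s_mu, n_mu
        assert s.s_mu * 2.0 + s.n_mu == pytest.approx(mu_max, rel=1e-12)
        assert s.s_mu * t_mu + s.n_mu == pytest.approx(mu_min, rel=1e-9, abs=1e-12)
        eps = 1e-9
        assert effective_growth_rate(2.0 + eps, s) == pytest.approx(mu_max, abs=1e-6)
        assert effective_growth_rate(t_mu - eps, s) == pytest.approx(mu_min, abs=1e-6)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            GrowthSchedule(mu_max=0.5, mu_min=0.6)
        with pytest.raises(ConfigurationError):
            GrowthSchedule(t_mu=1.0)
        with pytest.raises(ConfigurationError):
            GrowthSchedule(K=-1.0)


class TestRealizedGrowth:
    def test_at_capacity_growth_vanishes(self, default_params):
        K = default_params.growth.K
        state = SimulationState(H=K / 2, V=0, I=K / 2, t=0.0)
        mu, mu_I = realized_growth_rates(0.5, state, default_params, r_s=0)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_induced_infected_do_not_replicate(self, default_params):
        state = SimulationState(H=1e8, V=0, I=1e8, t=1.0)
        _, mu_I = realized_growth_rates(1.0, state, default_params, r_s=1)
        assert mu_I == 0.0

    def test_half_capacity_plateau_value(self, default_params):
        K = default_params.growth.K
        state = SimulationState(H=K / 2, V=0, I=0, t=1.0)
        mu, mu_I = realized_growth_rates(1.0, state, default_params, r_s=0)
        assert mu == pytest.approx(0.5, rel=1e-12)
        assert mu_I == pytest.approx(0.5, rel=1e-12)


class TestInductionState:
    def test_virulent_always_on(self, virulent_params):
        state = SimulationState(H=1.0, V=0, I=0)
        assert induction_state(0.0, state, virulent_params) == 1
        assert induction_state(99.0, state, virulent_params) == 1

    def test_phenomenological_threshold(self, default_params):
        p = default_params.with_mode(TEMPERATE_PHENOMENOLOGICAL, t_s=6.0)
        state = SimulationState(H=1.0, V=0, I=0)
        assert induction_state(5.9, state, p) == 0
        assert induction_state(6.0, state, p) == 1

    def test_phenomenological_requires_t_s(self):
        with pytest.raises(ConfigurationError):
            InductionRule(mode=TEMPERATE_PHENOMENOLOGICAL)

    def test_self_regulated_latch_time_logistic(self):
        # constant mu_eff = 1/d, K = 6.6e9/L, H0 = 1e8/L, threshold at K/2:
        # logistic crossing at ln((K - H0)/H0) = ln(65) ~ 4.17 d
        p = ModelParameters(
            growth=GrowthSchedule(mu_max=1.0, mu_min=1.0, t_mu=100.0, K=6.6e9),
            induction=InductionRule(mode=TEMPERATE_SELF_REGULATED,
                                    stress_fraction=0.5),
            k=0.0, d_H=0.0, B=1)
        traj = simulate(p, SimulationState(H=1e8, V=0, I=0),
                        np.linspace(0, 10, 41))
        assert traj.induction_time == pytest.approx(math.log(65.0), abs=1e-3)

    def test_self_regulated_latch_is_permanent(self):
        p = ModelParameters(induction=InductionRule(
            mode=TEMPERATE_SELF_REGULATED, stress_fraction=0.5))
        # force latch with a crowded state, then offer a relaxed one
        crowded = SimulationState(H=p.growth.K, V=0, I=0, t=1.0)
        assert induction_state(1.0, crowded, p) == 1
        sparse = SimulationState(H=1.0, V=0, I=0, t=2.0)
        assert induction_state(2.0, sparse, p) == 1


class TestDerivatives:
    def test_virus_free_reduces_to_logistic_mortality(self, default_params):
        state = SimulationState(H=1e8, V=0, I=0, t=1.0)
        dH, dV, dI = derivatives(1.0, state, default_params)
        mu, _ = realized_growth_rates(1.0, state, default_params, r_s=1)
        assert dH == pytest.approx((mu - default_params.d_H) * 1e8, rel=1e-12)
        assert dV == 0.0 and dI == 0.0

    def test_temperate_mode_has_no_virus_production(self, default_params):
        p = default_params.with_mode(TEMPERATE_PHENOMENOLOGICAL, t_s=100.0)
        state = SimulationState(H=1e8, V=0.0, I=1e8, t=1.0)
        dH, dV, dI = derivatives(1.0, state, p)
        assert dV == 0.0  # no lysis while dormant, V = 0 stays 0
        mu, mu_I = realized_growth_rates(1.0, state, p, r_s=0)
        # dormant infected hosts contribute mu_I*I new uninfected hosts
        assert dH == pytest.approx((mu - p.d_H) * 1e8 + mu_I * 1e8, rel=1e-12)

    def test_infection_flux_arithmetic(self):
        from dataclasses import replace

        p = replace(ModelParameters(induction=InductionRule(mode=VIRULENT)),
                    k=5.5e-12)
        state = SimulationState(H=1e9, V=1e10, I=0, t=1.0)
        _, _, dI = derivatives(1.0, state, p)
        assert dI == pytest.approx(5.5e7 - p.d_H * 0.0, rel=1e-9)

    def test_exclusive_infection_spares_virus_on_infected(self):
        from dataclasses import replace

        base = ModelParameters(induction=InductionRule(mode=VIRULENT), B=1)
        state = SimulationState(H=1e8, V=1e9, I=1e8, t=1.0)
        _, dV_super, _ = derivatives(1.0, state, base)
        _, dV_excl, _ = derivatives(1.0, state,
                                    replace(base, superinfection=False))
        assert dV_excl - dV_super == pytest.approx(base.k * 1e8 * 1e9, rel=1e-9)


class TestSimulate:
    def test_temperate_ts0_equals_virulent(self, virulent_params, moi10_init,
                                           week_grid):
        # the purely lytic model is the t_s = 0 limit of the temperate one
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = ModelParameters(
                growth=GrowthSchedule(mu_max=rng.uniform(0.5, 1.5),
                                      mu_min=rng.uniform(0.05, 0.2),
                                      t_mu=rng.uniform(8, 16),
                                      K=10 ** rng.uniform(9, 10)),
                induction=InductionRule(mode=VIRULENT),
                k=10 ** rng.uniform(-10, -8), B=rng.uniform(50, 1000),
                k_L=rng.uniform(0.3, 1.5), d_V=rng.uniform(0.1, 1.5),
                d_H=rng.uniform(0, 0.1))
            init = SimulationState(H=10 ** rng.uniform(5, 8),
                                   V=10 ** rng.uniform(6, 9), I=0)
            a = simulate(p, init, week_grid)
            b = simulate(p.with_mode(TEMPERATE_PHENOMENOLOGICAL, t_s=0.0),
                         init, week_grid)
            for x, y in ((a.H, b.H), (a.V, b.V), (a.I, b.I)):
                assert rel_close(x, y, 1e-6)

    def test_virus_free_logistic_limit(self, two_week_grid):
        from dataclasses import replace

        p = replace(ModelParameters(induction=InductionRule(mode=VIRULENT)),
                    d_H=0.0)
        traj = simulate(p, SimulationState(H=1e7, V=0, I=0), two_week_grid)
        assert np.all(np.diff(traj.H) >= -1e-6 * traj.H[:-1])
        assert traj.H[-1] <= p.growth.K * (1 + 1e-9)

    def test_virulent_collapse_and_rk4_agreement(self, virulent_params,
                                                 moi10_init, week_grid):
        traj = simulate(virulent_params, moi10_init, week_grid)
        assert traj.total_host[-1] < moi10_init.H  # collapse within a week

        def rk4_final(p, y0, t_end, dt=1e-3):
            y = np.array(y0, float)
            t = 0.0
            f = lambda tt, yy: dyn._rhs(tt, yy, p, 1)
            while t < t_end - 1e-12:
                h = min(dt, t_end - t)
                k1 = f(t, y)
                k2 = f(t + h / 2, y + h / 2 * k1)
                k3 = f(t + h / 2, y + h / 2 * k2)
                k4 = f(t + h, y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            return y

        y_rk4 = rk4_final(virulent_params,
                          [moi10_init.H, moi10_init.V, moi10_init.I], 7.0)
        y_ad = np.array([traj.H[-1], traj.V[-1], traj.I[-1]])
        assert rel_close(y_ad, y_rk4, 1e-4)

    def test_positivity_clamped(self, virulent_params, moi10_init, week_grid):
        traj = simulate(virulent_params, moi10_init, week_grid)
        assert np.all(traj.H >= 0) and np.all(traj.V >= 0) and np.all(traj.I >= 0)

    def test_monotone_dose_response(self, virulent_params):
        # a larger inoculum of virus never postpones the start of host decline
        times = np.linspace(0, 7, 281)
        onset_times = []
        for V0 in (1e6, 1e7, 1e8, 1e9, 1e10):
            traj = simulate(virulent_params,
                            SimulationState(H=1e8, V=V0, I=0), times)
            tot = traj.total_host
            below = tot < 0.9 * tot[0]
            onset_times.append(times[np.argmax(below)] if below.any()
                               else np.inf)
        assert all(b <= a + 1e-9 for a, b in zip(onset_times, onset_times[1:]))

    def test_virus_equivalents_conserved_in_pure_transfer(self):
        # B = 1, no decay/mortality, no growth, exclusive infection, k = 0:
        # the k_L transfer I -> V is the only flux and V + I is conserved
        p = ModelParameters(
            growth=GrowthSchedule(mu_max=0.0, mu_min=0.0, t_mu=3.0, K=1e9),
            induction=InductionRule(mode=VIRULENT),
            B=1, d_V=0.0, d_H=0.0, superinfection=False, k=0.0)
        traj = simulate(p, SimulationState(H=1e8, V=1e6, I=1e6),
                        np.linspace(0, 5, 21))
        tot = traj.V + traj.I
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-9

    def test_extinction_reported_below_floor(self, virulent_params):
        from dataclasses import replace

        p = replace(virulent_params, d_H=0.5)  # accelerate the I tail decay
        times = np.arange(0.0, 21.01, 0.25)
        traj = simulate(p, SimulationState.from_per_ml(1e5, 1e7, 0.0), times)
        assert traj.extinct
        after = times >= traj.extinction_time
        assert np.all(traj.total_host[after] <= p.extinction_floor * (1 + 1e-9))

    def test_trajectory_frame_units(self, virulent_params, moi10_init,
                                    week_grid):
        df = simulate(virulent_params, moi10_init, week_grid).to_frame()
        assert df["H_per_mL"].iloc[0] == pytest.approx(1e5)
        assert set(df.columns) == {"time_d", "H_per_mL", "V_per_mL",
                                   "I_per_mL", "r_s", "extinct_flag"}


class TestDelayedVirulent:
    def test_single_stage_is_classic_virulent(self, virulent_params):
        init = SimulationState(H=1e8, V=0, I=1e7)
        t = np.linspace(0, 10, 41)
        a = simulate(virulent_params, init, t)
        d = simulate_delayed_virulent(virulent_params, init, t, n_stages=1)
        for x, y in ((a.H, d.H), (a.V, d.V), (a.I, d.I)):
            assert rel_close(x, y, 1e-6)

    def test_no_adsorption_is_uninfected_logistic(self, virulent_params):
        from dataclasses import replace

        p = replace(virulent_params, k=0.0)
        t = np.linspace(0, 10, 41)
        d = simulate_delayed_virulent(p, SimulationState(H=1e7, V=1e8, I=0),
                                      t, n_stages=5)
        ref = simulate(p, SimulationState(H=1e7, V=1e8, I=0), t)
        assert rel_close(d.H, ref.H, 1e-6)

    def test_lysis_delayed_by_latent_period(self, virulent_params):
        # with a sharp Erlang delay the host half-decline comes later than
        # under exponential latency, by a fraction of L
        init = SimulationState(H=1e7, V=1e9, I=9.9e7)
        t = np.linspace(0, 10, 401)
        a = simulate(virulent_params, init, t)
        d = simulate_delayed_virulent(virulent_params, init, t, n_stages=10)
        tot0 = init.H + init.I

        def half_time(tr):
            below = tr.total_host < 0.5 * tot0
            return t[np.argmax(below)]

        delay = half_time(d) - half_time(a)
        L = virulent_params.latent_period
        assert 0.2 * L <= delay <= 1.5 * L

    def test_invalid_stage_count(self, virulent_params):
        with pytest.raises(ConfigurationError):
            simulate_delayed_virulent(virulent_params,
                                      SimulationState(H=1.0, V=0, I=0),
                                      np.linspace(0, 1, 3), n_stages=0)


class TestPreinfectionFraction:
    def test_zero_rate_gives_zero(self):
        assert preinfection_fraction(0.0, 1e10, 1.0) == 0.0

    def test_default_rate_hits_protocol_anchor(self):
        # ~99% infection after 2 h at 1e7 viruses/mL
        k = default_adsorption_rate()
        frac = preinfection_fraction(k, 1e7 * 1e3, 2.0 / 24.0)
        assert frac == pytest.approx(0.99, abs=1e-10)

    def test_half_virus_concentration(self):
        # kVt = 2.3026 at half the protocol concentration -> ~0.90
        k = default_adsorption_rate()
        frac = preinfection_fraction(k, 5e6 * 1e3, 2.0 / 24.0)
        assert frac == pytest.approx(1.0 - math.exp(-math.log(100.0) / 2.0),
                                     rel=1e-9)
        assert frac == pytest.approx(0.90, abs=0.005)

    @given(st.floats(0, 1e-6), st.floats(0, 1e12), st.floats(0, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_in_unit_interval(self, k, V, t):
        assert 0.0 <= preinfection_fraction(k, V, t) <= 1.0


def test_self_regulated_induction_density_scales_with_K():
    """Host density at realized induction tracks carrying capacity 1:1."""
    from dataclasses import replace

    from lysodyn.synthetic import initial_state, schedule_for_inoculum

    densities, Ks = [], []
    for K in (6.6e6, 6.6e7, 6.6e8, 6.6e9):
        sched = schedule_for_inoculum(K / 1e3,
                                      replace(GrowthSchedule(), K=K))
        p = ModelParameters(growth=sched,
                            induction=InductionRule(mode=TEMPERATE_SELF_REGULATED))
        init = initial_state("coincubation_moi10", K / 1e3 / 1e3, p)
        traj = simulate(p, init, np.arange(0.0, 21.01, 0.5))
        assert traj.host_at_induction is not None
        Ks.append(K)
        densities.append(traj.host_at_induction)
    slope = np.polyfit(np.log10(Ks), np.log10(densities), 1)[0]
    assert abs(slope - 1.0) <= 0.1
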