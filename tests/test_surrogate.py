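import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.optimize import brentq

import siftwin as st
from siftwin.surrogate import (
    DORMANT,
    GROWTH,
    MATURE,
    SENESCENT,
    PFTTraits,
    PhenoState,
    SurrogateConfig,
    canopy_absorption,
    daily_gpp,
    light_response,
    run_pft_ensemble,
    spin_up,
    step_phenology,
    temperature_response,
    water_stress,
)

HARD_MIN = SurrogateConfig(colimitation_theta=1.0)


class TestResponses:
    def test_temperature_peak_and_edges(self):
        assert temperature_response(25.0, 0.0, 25.0, 40.0) == 1.0
        assert temperature_response(0.0, 0.0, 25.0, 40.0) == 0.0
        assert temperature_response(40.0, 0.0, 25.0, 40.0) == 0.0

    def test_temperature_midpoint(self):
        assert temperature_response(12.5, 0.0, 25.0, 40.0) == pytest.approx(0.5)

    def test_temperature_outside_range_is_zero(self):
        assert temperature_response(-10.0, 0.0, 25.0, 40.0) == 0.0
        assert temperature_response(50.0, 0.0, 25.0, 40.0) == 0.0

    def test_temperature_ordering_enforced(self):
        with pytest.raises(ValueError):
            temperature_response(10.0, 25.0, 20.0, 40.0)

    def test_water_stress_cases(self):
        assert water_stress(1.0, 3.0) == 1.0
        assert water_stress(0.3, 0.0) == 1.0
        assert water_stress(0.5, 1.0) == pytest.approx(0.5)

    def test_water_stress_domain(self):
        with pytest.raises(ValueError):
            water_stress(1.2, 1.0)

    @given(hst.floats(0, 1), hst.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_water_stress_monotone(self, w1, w2):
        lo, hi = sorted([w1, w2])
        assert water_stress(lo, 1.5) <= water_stress(hi, 1.5) + 1e-12

    def test_light_response_cases(self):
        assert light_response(100.0, 100.0) == pytest.approx(0.5)
        assert light_response(0.0, 100.0) == 0.0
        assert light_response(300.0, 100.0) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            light_response(-1.0)

    def test_canopy_absorption_cases(self):
        assert canopy_absorption(0.0) == 0.0
        assert canopy_absorption(2.0, 0.5) == pytest.approx(1.0 - np.exp(-1.0))

    @given(hst.floats(0, 9), hst.floats(0.01, 9))
    @settings(max_examples=50, deadline=None)
    def test_canopy_absorption_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if hi > lo:
            assert canopy_absorption(hi) > canopy_absorption(lo)


def _params(**over):
    base = dict(
        V_cmax=30.0, G_s_slope=9.0, T_opt=25.0, T_min=0.0, T_max=40.0,
        F_stress_h=1.0, SLA=0.02, LAI_max=5.0, K_LAI_happy=0.5,
        K_pheno_crit=1.0, M_Tmin=35.0, L_age_crit=180.0, T_senes=7.0,
        M_senes_nosenes=0.3, L_fall=0.1, SIF_a=0.25, SIF_b=0.25,
    )
    base.update(over)
    return base


def _state(lai=2.0, age=0.0, phase=MATURE):
    s = PhenoState.initial((1, 1), deciduous=True)
    s.lai = np.full((1, 1), float(lai))
    s.mean_leaf_age = np.full((1, 1), float(age))
    s.phase = np.full((1, 1), phase, dtype=np.int8)
    return s


class TestDailyGPP:
    def test_zero_below_tmin(self):
        gpp = daily_gpp(_params(), T=-5.0, R=300.0, W=1.0, state=_state(), config=HARD_MIN)
        assert np.all(gpp == 0.0)

    def test_colimitation_branches_hand_computed(self):
        # independent oracle: compute both limitation branches by hand
        f_l = 1.0 - np.exp(-0.5 * 2.0)
        a_c = 1.0368 * 30.0 * 1.0 * 0.5 * f_l * 1.0
        a_w = 2.0 * 9.0 * 1.0 * f_l
        expected = min(a_c, a_w)  # = a_c ~ 9.83
        assert expected == pytest.approx(9.83, abs=0.01)
        gpp = daily_gpp(_params(), T=25.0, R=100.0, W=1.0, state=_state(), config=HARD_MIN)
        assert np.asarray(gpp).item() == pytest.approx(expected, rel=1e-9)

    def test_doubling_vcmax_no_effect_when_supply_limited(self):
        st1 = _state()
        low_w = dict(T=25.0, R=300.0, W=0.2, state=st1, config=HARD_MIN)
        g1 = daily_gpp(_params(V_cmax=60.0), **low_w)
        g2 = daily_gpp(_params(V_cmax=120.0), **low_w)
        assert np.asarray(g1).item() == pytest.approx(np.asarray(g2).item(), rel=1e-12)

    def test_monotone_in_w_and_r(self):
        gs = [np.asarray(daily_gpp(_params(), T=25.0, R=r, W=w, state=_state(), config=HARD_MIN)).item()
              for r, w in [(100, 0.3), (200, 0.3), (200, 0.6), (300, 0.9)]]
        assert all(b >= a - 1e-12 for a, b in zip(gs, gs[1:]))

    def test_vcmax_sensitivity_sign(self):
        # carboxylation-limited: positive FD derivative; supply-limited: zero
        carbox = dict(T=25.0, R=100.0, W=1.0, state=_state(), config=HARD_MIN)
        g0 = np.asarray(daily_gpp(_params(V_cmax=30.0), **carbox)).item()
        g1 = np.asarray(daily_gpp(_params(V_cmax=30.1), **carbox)).item()
        assert g1 > g0
        supply = dict(T=25.0, R=300.0, W=0.1, state=_state(), config=HARD_MIN)
        s0 = np.asarray(daily_gpp(_params(V_cmax=60.0), **supply)).item()
        s1 = np.asarray(daily_gpp(_params(V_cmax=60.1), **supply)).item()
        assert s1 == pytest.approx(s0, abs=1e-12)


def _day_forcing(tair=20.0, w=0.8, t7=None, w7=None, gdd=0.0, mdays=0.0, reset=False):
    return {
        "tair": np.array([tair]),
        "w": np.array([w]),
        "t7": np.array([t7 if t7 is not None else tair]),
        "w7": np.array([w7 if w7 is not None else w]),
        "gdd": np.array([gdd]),
        "mdays": np.array([mdays]),
        "reset": np.array([reset]),
    }


TEMP_TRAITS = PFTTraits(deciduous=True, temp_onset=True, moist_onset=False,
                        temp_senes=True, moist_senes=False)


class TestPhenologyStep:
    def test_dormant_stays_without_gdd(self):
        s = PhenoState.initial((1, 1), deciduous=True)
        s.days_in_phase[:] = 30
        out = step_phenology(s, _day_forcing(gdd=50.0), _params(), TEMP_TRAITS)
        assert out.phase[0, 0] == DORMANT and out.lai[0, 0] == 0.0

    def test_onset_when_gdd_exceeds_threshold(self):
        s = PhenoState.initial((1, 1), deciduous=True)
        s.days_in_phase[:] = 30
        out = step_phenology(s, _day_forcing(gdd=250.0, t7=15.0), _params(), TEMP_TRAITS)
        assert out.phase[0, 0] == GROWTH and out.lai[0, 0] > 0.0

    def test_senescent_leaf_fall(self):
        s = _state(lai=2.0, phase=SENESCENT)
        out = step_phenology(s, _day_forcing(t7=15.0), _params(L_fall=0.1), TEMP_TRAITS)
        assert out.lai[0, 0] == pytest.approx(1.8)

    def test_senescent_to_dormant_below_cutoff(self):
        s = _state(lai=0.051, phase=SENESCENT)
        out = step_phenology(s, _day_forcing(t7=15.0), _params(L_fall=0.5), TEMP_TRAITS)
        assert out.phase[0, 0] == DORMANT and out.lai[0, 0] == 0.0

    def test_mature_senesces_on_cold(self):
        s = _state(lai=5.0, phase=MATURE)
        out = step_phenology(s, _day_forcing(t7=2.0), _params(T_senes=7.0), TEMP_TRAITS)
        assert out.phase[0, 0] == SENESCENT

    def test_lai_never_exceeds_max(self, small_scenario):
        table = small_scenario.table
        vec = st.build_parameter_vector(table)
        for pft in (2, 6, 10):
            traits = PFTTraits.from_table(table, pft)
            theta = vec.effective_params(pft)
            state = spin_up(theta, small_scenario.forcing, traits)
            assert np.all(state.lai <= theta["LAI_max"] + 1e-9)


class TestSpinUp:
    def test_evergreen_fixed_point_matches_root(self, constant_forcing):
        cfg = SurrogateConfig()
        theta = _params(L_age_crit=400.0, LAI_max=6.0, T_opt=24.0)
        traits = PFTTraits(deciduous=False, temp_onset=False, moist_onset=False,
                           temp_senes=False, moist_senes=False)
        state = spin_up(theta, constant_forcing, traits, cfg)
        # independent oracle: solve growth == turnover for the scalar LAI
        f_t = 1.0  # T == T_opt
        f_w = water_stress(0.9, theta["F_stress_h"])

        def balance(l):
            over = (l - theta["K_LAI_happy"] * theta["LAI_max"]) / cfg.happy_ramp + 0.5
            halved = 1.0 - 0.5 * np.clip(over, 0.0, 1.0)
            g = cfg.r_grow * theta["SLA"] * cfg.b_day * f_t * f_w * halved
            return g * (1.0 - l / theta["LAI_max"]) - l / theta["L_age_crit"]

        root = brentq(balance, 1e-6, theta["LAI_max"] - 1e-6)
        assert np.allclose(state.lai, root, atol=5e-3)
        assert state.converged

    def test_determinism(self, constant_forcing):
        traits = PFTTraits(False, False, False, False, False)
        s1 = spin_up(_params(), constant_forcing, traits)
        s2 = spin_up(_params(), constant_forcing, traits)
        assert np.array_equal(s1.lai, s2.lai)

    def test_converged_state_respun_is_stable(self, constant_forcing):
        traits = PFTTraits(False, False, False, False, False)
        s1 = spin_up(_params(), constant_forcing, traits)
        s2 = spin_up(_params(), constant_forcing, traits, state=s1)
        assert np.allclose(s1.lai, s2.lai, atol=2e-3)
        assert s2.converged

    def test_nonconvergence_flagged(self, constant_forcing):
        traits = PFTTraits(False, False, False, False, False)
        cfg = SurrogateConfig(spin_max_cycles=1, spin_tol=1e-12)
        with pytest.warns(UserWarning, match="spin-up"):
            s = spin_up(_params(), constant_forcing, traits, cfg)
        assert not s.converged


class TestSimulate:
    def test_bare_cell_zero_gpp(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        pm = small_scenario.pft_map
        bare = st.PFTMap(
            fractions=np.zeros_like(pm.fractions[:4]),
            bare=np.ones(4),
            area=pm.area[:4],
        )
        forcing = small_scenario.forcing.subset(np.arange(4))
        out = st.simulate(vec, forcing, bare)
        assert np.all(out.aggregate == 0.0)

    def test_aggregate_is_fraction_weighted_sum(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        cells = np.arange(6)
        forcing = small_scenario.forcing.subset(cells)
        pm = small_scenario.pft_map.subset(cells)
        out = st.simulate(vec, forcing, pm)
        recomputed = np.einsum("tcp,cp->tc", out.gpp, pm.fractions)
        assert np.allclose(out.aggregate, recomputed, atol=1e-9)

    def test_constant_forcing_constant_gpp(self, constant_forcing):
        # equilibrated evergreen under constant forcing -> constant daily GPP
        table = st.default_parameter_table()
        vec = st.build_parameter_vector(table)
        traits = PFTTraits.from_table(table, 2)
        theta = vec.effective_params(2)
        state = spin_up(theta, constant_forcing, traits)
        gpp, _ = run_pft_ensemble(theta, constant_forcing, traits, collect="daily", state=state)
        # LAI is equilibrated; mean leaf age still relaxes slowly, so allow
        # a sub-percent residual drift
        assert np.ptp(gpp[-30:]) < 0.005 * gpp[-30:].mean()

    def test_out_of_bounds_rejected(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        vec.values[0] = vec.upper[0] + 1.0
        with pytest.raises(ValueError, match="bounds"):
            st.simulate(vec, small_scenario.forcing, small_scenario.pft_map)

    def test_bit_reproducible(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        cells = np.arange(8)
        forcing = small_scenario.forcing.subset(cells)
        pm = small_scenario.pft_map.subset(cells)
        a = st.simulate(vec, forcing, pm)
        b = st.simulate(vec, forcing, pm)
        assert np.array_equal(a.gpp, b.gpp)

    def test_gpp_nonnegative(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        cells = np.arange(10)
        out = st.simulate(
            vec, small_scenario.forcing.subset(cells), small_scenario.pft_map.subset(cells)
        )
        assert np.all(out.gpp >= 0.0)

    def test_deciduous_returns_to_dormancy(self, small_scenario):
        # boreal deciduous PFT goes dormant each winter under seasonal forcing
        table = small_scenario.table
        vec = st.build_parameter_vector(table)
        lat = small_scenario.grid.cell_lat
        cells = np.nonzero((lat > 50) & (lat < 60))[0][:4]
        forcing = small_scenario.forcing.subset(cells)
        traits = PFTTraits.from_table(table, 8)
        theta = vec.effective_params(8)
        state = spin_up(theta, forcing, traits)
        lai, final = run_pft_ensemble(theta, forcing, traits, collect="lai", state=state)
        # every cell sheds its canopy completely at some point each winter
        for year in range(2):
            window = lai[year * 365 : year * 365 + 150]
            assert np.all(window.min(axis=0) == 0.0)

    def test_phase_codes_valid(self, small_scenario):
        table = small_scenario.table
        vec = st.build_parameter_vector(table)
        traits = PFTTraits.from_table(table, 6)
        state = spin_up(vec.effective_params(6), small_scenario.forcing, traits)
        assert set(np.unique(state.phase)) <= {DORMANT, GROWTH, MATURE, SENESCENT}
        assert set(state.phase_names().ravel()) <= {"dormant", "growth", "mature", "senescent"}
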