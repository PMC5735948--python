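import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryptkinetics import (
    COMPARTMENTS,
    InitialCondition,
    RateParameters,
    closed_form_state,
    closed_form_timecourse,
    composite_rates,
    integrate_ode,
    ode_rhs,
    renewal_time,
    steady_state,
)
from cryptkinetics.model import (
    ConfluentRateWarning,
    read_timecourse_csv,
    write_timecourse_csv,
)
from cryptkinetics import presets

BASE = presets.BASELINE_PARAMS
INIT = presets.DEFAULT_INIT


def rel_diff(a, b, floor=1e-8):
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return np.abs(a - b) / scale


@st.composite
def valid_parameter_sets(draw):
    """Random rate sets with guaranteed positive composite and loss rates,
    built by drawing the net clearance rates and back-solving the k's."""
    logu = lambda lo, hi: st.floats(np.log(lo), np.log(hi)).map(np.exp)
    k1 = draw(logu(0.2, 2.0))
    prolif = {name: draw(st.floats(0.0, 2.0)) for name in
              ("beta", "gamma", "delta", "zeta")}
    omegas = {name: draw(logu(0.02, 2.0)) for name in ("wd", "we", "ws", "wm")}
    lams = {f"lambda{i}": draw(logu(0.02, 2.0)) for i in range(1, 6)}
    k3 = draw(st.floats(0.0, 1.0)) * (omegas["wd"] + prolif["beta"])
    k2 = omegas["wd"] + prolif["beta"] - k3
    k5 = omegas["we"] + prolif["gamma"]
    sec_total = omegas["ws"] + prolif["delta"]
    f6 = draw(st.floats(0.0, 1.0))
    f7 = draw(st.floats(0.0, 1.0))
    k6 = f6 * sec_total
    k7 = f7 * (sec_total - k6)
    k4 = sec_total - k6 - k7
    gp_total = omegas["wm"] + prolif["zeta"]
    f9 = draw(st.floats(0.0, 1.0))
    k9 = f9 * gp_total
    k8 = gp_total - k9
    return RateParameters(
        k1=k1, alpha=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6, k7=k7,
        k8=k8, k9=k9, **prolif, **lams,
    )


class TestClosedForm:
    def test_initial_state_is_stem_cells_only(self):
        state = closed_form_state(BASE, INIT, 0.0)
        assert state.CBC == pytest.approx(INIT.CBC0)
        for name in COMPARTMENTS[1:]:
            assert getattr(state, name) == pytest.approx(0.0, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            closed_form_state(BASE, INIT, -1.0)

    def test_tac_long_time_limit(self):
        comp = composite_rates(BASE)
        state = closed_form_state(BASE, INIT, 10_000.0)
        expected = BASE.k1 * INIT.CBC0 / comp.omega_d
        assert state.TAC == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0, 100.0])
    def test_agrees_with_ode_integration(self, t):
        ode = integrate_ode(BASE, INIT, [0.0, t]).iloc[-1]
        state = closed_form_state(BASE, INIT, t)
        for name in COMPARTMENTS:
            assert rel_diff(getattr(state, name), ode[name]) < 1e-6

    def test_matches_steady_state_at_long_times(self):
        ss = steady_state(BASE, INIT)
        state = closed_form_state(BASE, INIT, 1e5)
        for name in COMPARTMENTS:
            assert rel_diff(getattr(state, name), getattr(ss, name)) < 1e-6

    def test_confluent_rates_warned_and_bounded(self):
        # make the absorptive clearance coincide with the enterocyte loss
        params = BASE.replace(k5=BASE.gamma + BASE.lambda1)
        with pytest.warns(ConfluentRateWarning):
            state = closed_form_state(params, INIT, 5.0)
        ode = integrate_ode(params, INIT, [0.0, 5.0]).iloc[-1]
        assert rel_diff(state.EC, ode["EC"]) < 1e-5


class TestOdeRhs:
    def test_cbc_constant_in_steady_mode(self):
        state = closed_form_state(BASE, INIT, 3.0)
        assert ode_rhs(state, BASE)[0] == 0.0

    def test_vanishes_at_steady_state(self):
        ss = steady_state(BASE, INIT)
        rhs = ode_rhs(ss, BASE)
        for name, dv in zip(COMPARTMENTS, rhs):
            assert abs(dv) < 1e-9 * max(getattr(ss, name), 1.0)

    def test_matches_finite_difference_slope(self):
        h, t = 1e-5, 2.0
        plus = closed_form_state(BASE, INIT, t + h).as_array()
        minus = closed_form_state(BASE, INIT, t - h).as_array()
        slope = (plus - minus) / (2 * h)
        rhs = ode_rhs(closed_form_state(BASE, INIT, t), BASE)
        assert np.all(rel_diff(slope, rhs, floor=1e-6) < 1e-6)


class TestSteadyState:
    def test_matches_published_tac_target(self):
        # omega_d chosen so that (k1/omega_d) * CBC0 = 310 cells/CVU
        params = RateParameters(
            k1=1.0, alpha=1.0, k2=10 / 310 + 1.75, beta=1.75,
            k4=1, k5=2, k6=1, k8=1,
            lambda1=1, lambda2=1, lambda3=1, lambda4=1, lambda5=1,
        )
        ss = steady_state(params, INIT)
        assert ss.TAC == pytest.approx(310.0, rel=1e-12)

    def test_unfed_secretory_branch_is_empty(self):
        # k2 raised so omega_d = k2 - beta stays positive with k3 = 0
        params = BASE.replace(k3=0.0, k2=1.79)
        ss = steady_state(params, INIT)
        for name in ("SP", "EEC", "TC", "GPP", "GC", "PC"):
            assert getattr(ss, name) == 0.0

    def test_raises_without_finite_steady_state(self):
        with pytest.raises(ValueError, match="omega_d"):
            steady_state(BASE.replace(k2=0.0, k3=0.0), INIT)
        with pytest.raises(ValueError, match="lambda1"):
            steady_state(BASE.replace(lambda1=0.0), INIT)

    def test_branch_ratio_identities(self):
        p = BASE
        ss = steady_state(p, INIT)
        assert ss.EEC / ss.TC == pytest.approx(
            (p.k6 * p.lambda3) / (p.k7 * p.lambda2), rel=1e-12
        )
        assert ss.GC / ss.PC == pytest.approx(
            (p.k8 * p.lambda5) / (p.k9 * p.lambda4), rel=1e-12
        )


class TestIntegrateOde:
    def test_constant_when_only_stem_turnover(self):
        params = RateParameters(k1=1.0, alpha=1.0)
        frame = integrate_ode(params, INIT, np.linspace(0, 50, 6))
        assert np.allclose(frame["CBC"], INIT.CBC0, rtol=1e-8)
        # k1 feeds TAC which has no clearance here -> grows; others stay 0
        assert np.allclose(frame["AP"], 0.0, atol=1e-8)

    def test_total_monotone_for_baseline(self):
        frame = integrate_ode(BASE, INIT, np.linspace(0, 100, 201))
        assert np.all(np.diff(frame["total"]) >= -1e-6)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_ode(BASE, INIT, [1.0, 0.5])


@pytest.mark.parametrize("params", [presets.BASELINE_PARAMS, presets.FAST_PARAMS],
                         ids=["baseline", "fast"])
def test_trajectories_monotone_nondecreasing(params):
    grid = np.arange(0.0, 200.0 + 0.05, 0.1)
    frame = closed_form_timecourse(params, INIT, grid)
    for name in COMPARTMENTS:
        diffs = np.diff(frame[name])
        assert np.all(diffs >= -1e-9 * max(frame[name].iloc[-1], 1.0)), name


class TestRenewalTime:
    def test_small_fraction_gives_small_time(self):
        assert renewal_time(BASE, INIT, "total", 1e-6) < 0.1

    def test_published_whole_epithelium_renewal(self):
        # the total population needs ~97 days to reach 95% of steady state
        t95 = renewal_time(BASE, INIT, "total", 0.95)
        assert t95 == pytest.approx(96.8, rel=0.02)

    def test_matches_dense_grid_scan(self):
        t95 = renewal_time(BASE, INIT, "EC", 0.95)
        grid = np.arange(max(t95 - 0.5, 0.0), t95 + 0.5, 0.001)
        frame = closed_form_timecourse(BASE, INIT, grid)
        ss = steady_state(BASE, INIT)
        crossing = grid[np.argmax(frame["EC"].to_numpy() >= 0.95 * ss.EC)]
        assert abs(t95 - crossing) < 0.01

    def test_unreachable_fraction_raises(self):
        with pytest.raises(RuntimeError):
            renewal_time(BASE, INIT, "total", 0.95, horizon=1.0)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            renewal_time(BASE, INIT, "total", 1.5)
        with pytest.raises(KeyError):
            renewal_time(BASE, INIT, "nope", 0.5)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(params=valid_parameter_sets())
def test_closed_form_matches_ode_for_random_rates(params):
    """Oracle equivalence on [0, 100] days for random valid rate sets."""
    grid = np.array([0.0, 0.5, 2.0, 10.0, 40.0, 100.0])
    ode = integrate_ode(params, INIT, grid, rtol=1e-10, atol=1e-10)
    cf = closed_form_timecourse(params, INIT, grid)
    for name in COMPARTMENTS:
        scale = max(cf[name].max(), 1e-3)
        assert np.all(
            np.abs(cf[name] - ode[name]) / scale < 1e-6
        ), f"{name} diverges from ODE oracle"
        assert np.all(cf[name] >= 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(params=valid_parameter_sets())
def test_long_time_limit_matches_steady_state(params):
    ss = steady_state(params, INIT).as_array()
    state = closed_form_state(params, INIT, 1e5).as_array()
    decay = list(composite_rates(params).as_dict().values()) + [
        getattr(params, f"lambda{i}") for i in range(1, 6)
    ]
    if min(decay) > 1e-3:
        assert np.all(rel_diff(state, ss, floor=1e-8) < 1e-6)


def test_timecourse_csv_round_trip(tmp_path):
    frame = closed_form_timecourse(BASE, INIT, np.linspace(0, 10, 11))
    path = tmp_path / "tc.csv"
    write_timecourse_csv(frame, path)
    back = read_timecourse_csv(path)
    assert list(back.columns) == ["t", *COMPARTMENTS, "total"]
    assert np.allclose(back.to_numpy(), frame.to_numpy())
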