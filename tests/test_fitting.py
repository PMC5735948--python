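import numpy as np
import pytest

from cryptkinetics import (
    InitialCondition,
    baseline_config,
    fast_config,
    fit_scenario,
    propagate_tied_uncertainty,
    renewal_time,
    residual_vector,
    steady_state,
)
from cryptkinetics import fitting, presets
from cryptkinetics.calibration import TARGET_COMPARTMENTS
from cryptkinetics.fitting import (
    ScenarioConfig,
    build_params,
    combination_sigmas,
    combination_values,
    curvature_uncertainty_at,
    identifiability_at,
)
from cryptkinetics.synthetic_data import NoiseModel, generate_targets


def free_vector_from(params, config):
    return np.array([getattr(params, name) for name in config.free])


class TestResidualVector:
    def test_zero_at_exact_solution(self, targets, baseline_fit):
        res = residual_vector(baseline_fit.free_values, baseline_config(), targets)
        assert np.all(np.abs(res) < 1e-6)

    def test_published_values_land_close_to_targets(self, targets):
        """The printed fitted rates reproduce every target to ~1% (printed
        rounding keeps the residuals small but clearly nonzero)."""
        config = baseline_config()
        res = residual_vector(
            free_vector_from(presets.BASELINE_PARAMS, config), config, targets
        )
        target_values = np.array([targets[n] for n in config.target_names])
        rel = np.abs(res) / target_values
        assert np.all(rel < 0.01)
        assert np.sum(res**2) > 0

    def test_perturbation_propagates_down_the_cascade_only(self, targets, baseline_fit):
        config = baseline_config()
        x = baseline_fit.free_values.copy()
        x[config.free.index("k2")] += 0.1
        params = build_params(x, config, targets)
        ss = steady_state(params, config.init)
        assert ss.CBC == pytest.approx(config.init.CBC0)  # stem cells untouched
        res = residual_vector(x, config, targets)
        assert np.max(np.abs(res)) > 1.0

    def test_penalty_when_no_steady_state(self, targets):
        config = baseline_config()
        x = free_vector_from(presets.BASELINE_PARAMS, config)
        x[config.free.index("k5")] = 0.0  # omega_e = -gamma < 0
        res = residual_vector(x, config, targets)
        assert np.all(res >= 1e3) and np.all(np.isfinite(res))


class TestBaselineFit:
    def test_recovers_transit_amplifying_target(self, baseline_fit):
        assert baseline_fit.steady["TAC"] == pytest.approx(310.0, abs=1e-3)

    def test_all_targets_within_tenth_percent(self, baseline_fit, targets):
        for name in TARGET_COMPARTMENTS:
            model = baseline_fit.steady["CBC" if name == "CBC0" else name]
            assert model == pytest.approx(targets[name], rel=1e-3), name

    def test_identically_satisfied_branches(self, baseline_fit, targets):
        # TC and PC are not fitted; the ties satisfy them automatically
        assert baseline_fit.steady["TC"] == pytest.approx(targets["TC"], rel=1e-3)
        assert baseline_fit.steady["PC"] == pytest.approx(targets["PC"], rel=1e-3)

    def test_rank_deficiency_mixing_k2_and_k4(self, baseline_fit):
        ident = baseline_fit.identifiability
        assert ident.rank == 6 and len(baseline_fit.free_names) == 7
        assert ident.null_space.shape == (1, 7)
        null = dict(zip(baseline_fit.free_names, ident.null_space[0]))
        assert abs(null["k2"]) > 1e-3 and abs(null["k4"]) > 1e-3

    def test_manifold_flatness_and_invariants(self, baseline_fit, targets):
        """A step along the null direction leaves SSR and the identifiable
        combinations unchanged while individual rates move."""
        config = baseline_config()
        step = 1e-3 * baseline_fit.identifiability.null_space[0]
        x1 = baseline_fit.free_values + step
        res = residual_vector(x1, config, targets)
        assert np.sum(res**2) < 1e-8
        assert np.max(np.abs(step)) > 1e-5  # parameters really moved
        c0 = combination_values(baseline_fit.params)
        c1 = combination_values(build_params(x1, config, targets))
        for name, value in c0.items():
            assert c1[name] == pytest.approx(value, rel=1e-6), name

    def test_reproduction_mode_recovers_published_tied_rates(self, reproduction_fit):
        p = reproduction_fit.params
        assert round(p.k3, 3) == 0.068
        assert round(p.k7, 2) == 0.14
        assert round(p.k9, 3) == 0.095

    def test_reproduction_mode_is_full_rank(self, reproduction_fit):
        assert reproduction_fit.rank == len(reproduction_fit.free_names) == 6


class TestFastFit:
    def test_enterocytes_renew_in_five_days(self, fast_fit):
        t95 = renewal_time(fast_fit.params, InitialCondition(), "EC", 0.95)
        assert t95 == pytest.approx(5.0, rel=0.01)

    def test_underdetermined(self, fast_fit):
        assert fast_fit.rank < len(fast_fit.free_names) == 15

    def test_targets_still_met(self, fast_fit, targets):
        for name in ("TAC", "EC", "GC", "PC", "EEC", "TC"):
            model = fast_fit.steady[name]
            assert model == pytest.approx(targets[name], rel=1e-3), name


class TestCurvatureUncertainty:
    def test_quadratic_objective_closed_form(self, monkeypatch, targets):
        """With SSR = 5000 * delta^2 injected, sigma = sqrt(1/(2a)) = 0.01."""
        config = baseline_config()
        x0 = np.ones(config.n_free)
        monkeypatch.setattr(
            fitting, "_ssr",
            lambda x, cfg, tgt: float(5000.0 * np.sum((x - x0) ** 2)),
        )
        sigmas, flags = curvature_uncertainty_at(x0, config, targets)
        for name in config.free:
            assert sigmas[name] == pytest.approx(0.01, rel=1e-4)
            assert not flags[name]

    def test_flat_direction_flagged(self, monkeypatch, targets):
        config = baseline_config()
        x0 = np.ones(config.n_free)
        monkeypatch.setattr(fitting, "_ssr", lambda x, cfg, tgt: 1.0)
        sigmas, flags = curvature_uncertainty_at(x0, config, targets)
        assert all(flags.values())
        assert all(np.isnan(s) for s in sigmas.values())

    def test_fitted_sigmas_far_below_literature_uncertainty(self, baseline_fit):
        # one-at-a-time sigmas of fitted rates are orders of magnitude
        # below the 0.25/day literature uncertainty on the proliferation rates
        assert baseline_fit.sigma["k2"] < 1e-3
        assert all(s < 0.01 for s in baseline_fit.sigma.values())


class TestPropagation:
    def test_zero_sigmas_give_zero(self):
        assert propagate_tied_uncertainty(0.14, [(1.0, 0.0), (2.0, 0.0)]) == 0.0

    def test_single_factor_relative_error(self):
        assert propagate_tied_uncertainty(0.4, [(2.0, 0.2)]) == pytest.approx(0.04)

    def test_root_sum_square_of_relative_errors(self):
        factors = [(0.3565, 0.0002), (0.43673, 0.00005), (0.43673, 0.00005),
                   (16.0, 2.0), (40.0, 4.0)]
        expected = 0.14 * np.sqrt(sum((s / v) ** 2 for v, s in factors))
        assert propagate_tied_uncertainty(0.14, factors) == pytest.approx(expected)

    def test_zero_factor_value_raises(self):
        with pytest.raises(ZeroDivisionError):
            propagate_tied_uncertainty(1.0, [(0.0, 0.1)])


class TestIdentifiabilityDiagnostics:
    def test_toy_two_parameter_problem_is_full_rank(self, targets):
        fixed = {n: v for n, v in presets.BASELINE_PARAMS
                 if n not in ("k5", "lambda1", "k3", "k7", "k9")}
        config = ScenarioConfig(
            name="toy", fixed=fixed, free=("k5", "lambda1"),
            start={"k5": 3.7, "lambda1": 0.35},
            target_names=("AP", "EC"),
        )
        x = np.array([3.7112, 0.35364])
        report = identifiability_at(x, config, targets)
        assert report.rank == 2
        assert report.null_space.shape[0] == 0


class TestParameterRecovery:
    def test_noise_free_round_trip(self):
        """Fitting targets generated from a known rate set recovers every
        identifiable combination to 1e-4 relative."""
        truth = presets.BASELINE_PARAMS
        synth = generate_targets(truth, InitialCondition(), NoiseModel(kind="none"))
        fit = fit_scenario(baseline_config(), synth.targets)
        expected = combination_values(truth)
        got = combination_values(fit.params)
        for name, value in expected.items():
            assert got[name] == pytest.approx(value, rel=1e-4), name

    def test_noisy_recovery_within_three_sigma(self):
        """With 2% multiplicative noise, each identifiable combination lies
        within 3 delta-method sigmas of truth in >= 90% of replicates."""
        truth = presets.BASELINE_PARAMS
        expected = combination_values(truth)
        config = baseline_config(weight_by_sigma=True, require_ssr=None)
        n_rep, hits, total = 100, 0, 0
        for seed in range(n_rep):
            synth = generate_targets(
                truth, InitialCondition(),
                NoiseModel(kind="multiplicative-gaussian", cv=0.02, seed=seed),
            )
            try:
                fit = fit_scenario(config, synth.targets)
            except (RuntimeError, ValueError):
                continue  # counts against coverage via `total` below
            got = combination_values(fit.params)
            sig = combination_sigmas(fit, config, synth.targets)
            for name, value in expected.items():
                total += 1
                if abs(got[name] - value) <= 3 * max(sig[name], 1e-12):
                    hits += 1
        assert total >= 0.9 * n_rep * len(expected)
        assert hits / total >= 0.90
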