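"""Constrained least-squares estimation of the kinetic rate constants.

Two scenarios are defined:

* **baseline** — the literature rates are held fixed (k1 = alpha = 1/day,
  beta = gamma = delta = zeta = 1.75/day, lambda5 = 1/21/day, and the
  secretory loss rates shared, lambda2 = lambda3 = lambda4).  Seven free
  rates {k2, k4, k5, k6, k8, lambda1, lambda2} are fitted to seven
  steady-state cell-count targets {TAC, AP, SP, GPP, EEC, GC, EC}; the
  branch rates k3, k7, k9 are tied to the targets at every evaluation, so
  the TC and PC targets are satisfied identically.
* **fast** — every non-tied rate (15 parameters) is freed and an extra
  residual constrains enterocytes to reach 95% of their steady-state
  value at 5 days, emulating the observed whole-epithelium renewal
  timescale.

The baseline constraint system has a one-dimensional solution manifold
(the tie that recomputes k3 makes the SP residual dependent on the AP
one), so individual fitted values are solver-dependent while combinations
such as omega_d, omega_e, omega_s, omega_m, k6/lambda2, k8/lambda4 and
k5/lambda1 are identifiable.  A *reproduction mode* pins k2 at its
published value, which makes the remaining parameters unique.

Parameter uncertainties use the one-at-a-time curvature method: each
fitted value is displaced by +/- 1e-6, the SSR increase is fitted to a
quadratic a*Delta^2, and sigma = sqrt(1/(2a)).  Tied-rate uncertainties
propagate by quadrature of relative errors.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import presets
from .calibration import SteadyStateTargets, tied_rates
from .model import closed_form_state, steady_state
from .params import InitialCondition, RateParameters, composite_rates

__all__ = [
    "ScenarioConfig",
    "FitResult",
    "IdentifiabilityReport",
    "baseline_config",
    "fast_config",
    "build_params",
    "residual_vector",
    "fit_scenario",
    "curvature_uncertainty",
    "propagate_tied_uncertainty",
    "tied_rate_sigmas",
    "identifiability",
    "IDENTIFIABLE_COMBINATIONS",
    "combination_values",
    "combination_sigmas",
]

_PENALTY = 1e3
_TIED = ("k3", "k7", "k9")


@dataclass
class ScenarioConfig:
    """Everything that defines one fitting scenario.

    ``fixed`` holds rates pinned at given values, ``free`` the fitted rate
    names (order defines the optimization vector), ``shared`` rates copying
    another rate's current value (e.g. ``lambda3 -> lambda2``), and the
    branch rates k3, k7, k9 are always tied through the target ratios.
    ``timescale`` optionally appends a renewal constraint residual
    ``weight * (X(t) - fraction * X_inf)`` for compartment ``selector``.
    """

    name: str = "custom"
    fixed: dict[str, float] = field(default_factory=dict)
    free: tuple[str, ...] = ()
    shared: dict[str, str] = field(default_factory=dict)
    start: dict[str, float] = field(default_factory=dict)
    target_names: tuple[str, ...] = ("TAC", "AP", "SP", "GPP", "EEC", "GC", "EC")
    timescale: tuple[str, float, float, float] | None = None  # (selector, fraction, t, weight)
    weight_by_sigma: bool = False
    init: InitialCondition = field(default_factory=lambda: presets.DEFAULT_INIT)
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int = 2000
    require_ssr: float | None = 1e-6
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        bad = set(self.free) & set(_TIED)
        if bad:
            raise ValueError(f"tied parameters cannot be free: {sorted(bad)}")

    @property
    def n_free(self) -> int:
        return len(self.free)

    def start_vector(self) -> np.ndarray:
        return np.array([self.start.get(name, 1.0) for name in self.free])


@dataclass
class IdentifiabilityReport:
    """SVD diagnostics of the residual Jacobian at a solution."""

    free_names: tuple[str, ...]
    jacobian: np.ndarray
    singular_values: np.ndarray
    rank: int
    null_space: np.ndarray  # (n_null, n_free) rows are unit directions
    tolerance: float


@dataclass
class FitResult:
    """Converged scenario fit with uncertainties and diagnostics."""

    scenario: str
    params: RateParameters
    free_names: tuple[str, ...]
    free_values: np.ndarray
    ssr: float
    sigma: dict[str, float]
    sigma_flags: dict[str, bool]
    tied_sigma: dict[str, float]
    identifiability: IdentifiabilityReport
    covariance: np.ndarray
    steady: dict[str, float]
    n_evaluations: int
    message: str

    @property
    def rank(self) -> int:
        return self.identifiability.rank


def baseline_config(
    reproduction: bool = False,
    weight_by_sigma: bool = False,
    require_ssr: float | None = 1e-6,
    seed: int = 0,
) -> ScenarioConfig:
    """Baseline scenario: literature rates fixed, 7 free rates, no
    renewal-time constraint.  ``reproduction=True`` pins k2 at its
    published value so the solution is unique."""
    fixed = dict(presets.FIXED_LITERATURE_RATES)
    free = ["k2", "k4", "k5", "k6", "k8", "lambda1", "lambda2"]
    if reproduction:
        fixed["k2"] = presets.BASELINE_PARAMS.k2
        free.remove("k2")
    return ScenarioConfig(
        name="baseline-reproduction" if reproduction else "baseline",
        fixed=fixed,
        free=tuple(free),
        shared={"lambda3": "lambda2", "lambda4": "lambda2"},
        start={},  # literature values exist for no free rate; default 1.0
        target_names=("TAC", "AP", "SP", "GPP", "EEC", "GC", "EC"),
        timescale=None,
        weight_by_sigma=weight_by_sigma,
        require_ssr=require_ssr,
        seed=seed,
    )


def fast_config(
    start: str = "literature",
    weight: float = 1.0,
    require_ssr: float | None = 1e-6,
    seed: int = 0,
) -> ScenarioConfig:
    """Fast scenario: all 15 non-tied rates free plus the 5-day enterocyte
    renewal constraint.  ``start`` is ``"literature"`` (default) or
    ``"published"`` (the printed fast-scenario values)."""
    free = (
        "k1", "k2", "k4", "k5", "k6", "k8",
        "beta", "gamma", "delta", "zeta",
        "lambda1", "lambda2", "lambda3", "lambda4", "lambda5",
    )
    if start == "literature":
        start_values = {
            name: presets.FIXED_LITERATURE_RATES[name]
            for name in free
            if name in presets.FIXED_LITERATURE_RATES
        }
    elif start == "published":
        start_values = {name: getattr(presets.FAST_PARAMS, name) for name in free}
    else:
        raise ValueError(f"unknown start preset {start!r}")
    return ScenarioConfig(
        name="fast",
        fixed={},
        free=free,
        shared={"alpha": "k1"},
        start=start_values,
        target_names=("TAC", "AP", "SP", "GPP", "EEC", "GC", "EC"),
        timescale=("EC", 0.95, 5.0, weight),
        require_ssr=require_ssr,
        seed=seed,
    )


def build_params(
    free_values: Sequence[float],
    config: ScenarioConfig,
    targets: SteadyStateTargets,
) -> RateParameters:
    """Materialize a full rate set from the free vector: fixed values,
    shared copies, then the tied branch rates from the target ratios."""
    values = dict(config.fixed)
    values.update(zip(config.free, map(float, free_values)))
    for dest, src in config.shared.items():
        values[dest] = values[src]
    values.setdefault("alpha", values.get("k1", 0.0))
    for name in _TIED:
        values.setdefault(name, 0.0)
    params = RateParameters.from_dict(values)
    k3, k7, k9 = tied_rates(params, targets)
    if min(k3, k7, k9) < 0:
        raise ValueError("tied rate became negative")
    return params.replace(k3=k3, k7=k7, k9=k9)


def _feasibility_violation(params: RateParameters) -> float:
    comp = composite_rates(params)
    margin = 1e-6
    v = sum(max(0.0, margin - w) for w in comp.as_dict().values())
    for i in range(1, 6):
        v += max(0.0, margin - getattr(params, f"lambda{i}"))
    return v


def residual_vector(
    free_values: Sequence[float],
    config: ScenarioConfig,
    targets: SteadyStateTargets,
) -> np.ndarray:
    """Residuals (cells): model steady states minus targets for the
    configured target set, plus the optional renewal-constraint term.

    When the composite or loss rates admit no steady state, smooth large
    penalty residuals are returned so the optimizer can climb back into
    the feasible region.
    """
    n_res = len(config.target_names) + (1 if config.timescale else 0)
    try:
        params = build_params(free_values, config, targets)
    except (ZeroDivisionError, ValueError):
        return np.full(n_res, 10 * _PENALTY)
    violation = _feasibility_violation(params)
    if violation > 0:
        return np.full(n_res, _PENALTY * (1.0 + violation))
    ss = steady_state(params, config.init)
    res = []
    for name in config.target_names:
        model_value = ss.CBC if name == "CBC0" else getattr(ss, name)
        r = model_value - targets[name]
        if config.weight_by_sigma:
            sigma = targets.sigma(name)
            r /= sigma if sigma > 0 else 1.0
        res.append(r)
    if config.timescale:
        selector, fraction, t_c, weight = config.timescale
        state = closed_form_state(params, config.init, t_c)
        value = state.total if selector == "total" else getattr(state, selector)
        inf_value = ss.total if selector == "total" else getattr(ss, selector)
        res.append(weight * (value - fraction * inf_value))
    return np.array(res)


def _repair_start(
    x0: np.ndarray, config: ScenarioConfig, targets: SteadyStateTargets
) -> np.ndarray:
    """Nudge a start vector into the feasible (positive composite rate)
    region; deterministic, acts only on free rates."""
    values = dict(config.fixed)
    values.update(zip(config.free, x0))
    for dest, src in config.shared.items():
        values[dest] = values[src]

    def get(name: str) -> float:
        return values.get(name, 0.0)

    # evaluate tied k7 roughly for omega_s; k3 is small and left out
    lam2 = get("lambda2") or 1.0
    k7 = get("k6") * (get("lambda3") or lam2) / lam2 * (
        targets["TC"] / targets["EEC"]
    )
    if "k5" in values and get("k5") - get("gamma") < 0.25:
        values["k5"] = get("gamma") + 1.0
    if "k4" in values and get("k4") + get("k6") + k7 - get("delta") < 0.25:
        values["k4"] = get("delta") + 1.0
    if "k8" in values and get("k8") - get("zeta") < 0.25:
        values["k8"] = get("zeta") + 1.0
    if "k2" in values and get("k2") - get("beta") < 0.25:
        values["k2"] = get("beta") + 0.5
    for i in range(1, 6):
        name = f"lambda{i}"
        if name in values and values[name] < 0.01:
            values[name] = 0.1
    return np.array([values.get(name, 1.0) for name in config.free])


def analytic_baseline_start(
    config: ScenarioConfig, targets: SteadyStateTargets, k2_fraction: float = 0.96
) -> np.ndarray:
    """Closed-form interpolant of the baseline constraint system.

    Given the fixed literature rates, the steady-state targets determine
    every free rate once k2 is chosen (the one-dimensional solution
    manifold): omega_d follows from the TAC target, omega_e from AP/TAC,
    lambda1 from EC/AP, omega_s from the k3 tie, and a linear equation in
    lambda2 closes the secretory branch.  Used as the optimizer start; for
    a free k2 the start uses ``k2 = k2_fraction * (omega_d + beta)``.

    Raises ``ValueError`` if the targets admit no positive solution.
    """
    targets.require("TAC", "AP", "SP", "GPP", "EEC", "TC", "GC", "PC", "EC")
    fx = config.fixed
    k1, beta = fx["k1"], fx["beta"]
    gamma, delta, zeta, lam5 = fx["gamma"], fx["delta"], fx["zeta"], fx["lambda5"]
    omega_d = k1 * config.init.CBC0 / targets["TAC"]
    k2 = fx.get("k2", k2_fraction * (omega_d + beta))
    k3 = omega_d + beta - k2
    omega_e = k2 * targets["TAC"] / targets["AP"]
    k5 = omega_e + gamma
    lam1 = k5 * targets["AP"] / targets["EC"]
    omega_s = k3 * omega_e * targets["AP"] / (k2 * targets["SP"])
    r6 = targets["EEC"] / targets["SP"]          # k6 / lambda2
    r7 = targets["TC"] / targets["EEC"]          # k7 / k6 (lambda3 = lambda2)
    rho = targets["GPP"] / targets["SP"]         # k4 / omega_m
    k9 = lam5 * targets["PC"] / targets["GPP"]
    lam2 = (omega_s + delta + rho * (zeta - k9)) / (
        r6 * (1 + r7) + rho * targets["GC"] / targets["GPP"]
    )
    k6 = r6 * lam2
    k4 = omega_s + delta - k6 * (1 + r7)
    k8 = lam2 * targets["GC"] / targets["GPP"]
    values = {"k2": k2, "k4": k4, "k5": k5, "k6": k6, "k8": k8,
              "lambda1": lam1, "lambda2": lam2}
    x0 = np.array([values[name] for name in config.free])
    if np.any(~np.isfinite(x0)) or np.any(x0 <= 0) or min(k3, omega_s) <= 0:
        raise ValueError("targets admit no positive baseline interpolant")
    return x0


def fit_scenario(config: ScenarioConfig, targets: SteadyStateTargets) -> FitResult:
    """Bounded nonlinear least squares for one scenario.

    Non-negativity bounds apply to every free rate.  If the achieved SSR
    exceeds ``config.require_ssr`` the fit restarts from deterministic
    seeded jitters of the start vector; persistent failure raises.
    """
    rng = np.random.default_rng(config.seed)
    x0 = None
    if set(config.free) <= {"k2", "k4", "k5", "k6", "k8", "lambda1", "lambda2"}:
        try:  # baseline-shaped scenario: start from the target algebra
            x0 = analytic_baseline_start(config, targets)
        except (ValueError, KeyError, ZeroDivisionError):
            x0 = None
    if x0 is None:
        x0 = _repair_start(config.start_vector(), config, targets)
    restart_threshold = config.require_ssr if config.require_ssr is not None else 1e-6
    best = None
    for attempt in range(config.restarts + 1):
        sol = least_squares(
            residual_vector,
            x0,
            args=(config, targets),
            bounds=(0.0, np.inf),
            method="trf",
            x_scale="jac",
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[1]:
            best = (sol, ssr)
        if ssr <= restart_threshold:
            break
        jitter = np.exp(rng.normal(0.0, 0.5, size=config.n_free))
        x0 = _repair_start(config.start_vector() * jitter, config, targets)
    sol, ssr = best
    if config.require_ssr is not None and ssr > config.require_ssr:
        raise RuntimeError(
            f"{config.name} fit did not converge: SSR={ssr:.3g} exceeds "
            f"{config.require_ssr:.3g} after {config.restarts + 1} starts"
        )
    if not sol.success:
        raise RuntimeError(f"{config.name} fit failed: {sol.message}")

    params = build_params(sol.x, config, targets)
    ss = steady_state(params, config.init)
    report = identifiability_at(sol.x, config, targets)
    sigma, flags = curvature_uncertainty_at(sol.x, config, targets)
    tied_sig = tied_rate_sigmas(params, sigma, targets, config)
    covariance = _pseudo_covariance(report)
    return FitResult(
        scenario=config.name,
        params=params,
        free_names=config.free,
        free_values=sol.x.copy(),
        ssr=ssr,
        sigma=sigma,
        sigma_flags=flags,
        tied_sigma=tied_sig,
        identifiability=report,
        covariance=covariance,
        steady=ss.as_dict(),
        n_evaluations=int(sol.nfev),
        message=str(sol.message),
    )


def _ssr(free_values: np.ndarray, config: ScenarioConfig, targets: SteadyStateTargets) -> float:
    r = residual_vector(free_values, config, targets)
    return float(np.sum(r * r))


def curvature_uncertainty_at(
    free_values: np.ndarray,
    config: ScenarioConfig,
    targets: SteadyStateTargets,
    step: float = 1e-6,
    relative: bool = False,
) -> tuple[dict[str, float], dict[str, bool]]:
    """One-at-a-time curvature sigmas at an arbitrary point.

    Each free parameter is displaced by +/- step (absolute by default, or
    ``step * max(|value|, 1)`` with ``relative=True``), the SSR increase is
    fitted to a*Delta^2, and sigma = sqrt(1 / (2a)).  Non-positive
    curvature yields sigma = nan and a raised flag.
    """
    base = _ssr(free_values, config, targets)
    sigmas: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for i, name in enumerate(config.free):
        h = step * max(abs(free_values[i]), 1.0) if relative else step
        xp, xm = free_values.copy(), free_values.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        a = (_ssr(xp, config, targets) + _ssr(xm, config, targets) - 2 * base) / (
            2 * h * h
        )
        if a > 0:
            sigmas[name] = math.sqrt(1.0 / (2.0 * a))
            flags[name] = False
        else:
            sigmas[name] = float("nan")
            flags[name] = True
    return sigmas, flags


def curvature_uncertainty(
    fit: FitResult,
    config: ScenarioConfig,
    targets: SteadyStateTargets,
    step: float = 1e-6,
    relative: bool = False,
) -> dict[str, float]:
    """Curvature sigmas of a converged fit (see
    :func:`curvature_uncertainty_at`)."""
    sigmas, _ = curvature_uncertainty_at(
        fit.free_values, config, targets, step=step, relative=relative
    )
    return sigmas


def propagate_tied_uncertainty(
    value: float, factors: Sequence[tuple[float, float]]
) -> float:
    """Quadrature propagation for a product/quotient expression.

    ``factors`` is a sequence of (factor value, factor sigma); the result's
    relative error is the root-sum-square of the factors' relative errors.
    """
    total = 0.0
    for fval, fsig in factors:
        if fval == 0:
            raise ZeroDivisionError("zero factor value in uncertainty propagation")
        total += (fsig / fval) ** 2
    return abs(value) * math.sqrt(total)


def tied_rate_sigmas(
    params: RateParameters,
    free_sigma: Mapping[str, float],
    targets: SteadyStateTargets,
    config: ScenarioConfig,
) -> dict[str, float]:
    """Uncertainties of the tied rates k3, k7, k9 by quadrature of the
    relative errors of every factor in their defining expressions.

    Fitted-rate sigmas come from the curvature method; shared rates
    inherit their source's sigma; fixed literature rates use the published
    sigma; target sigmas come from the calibration (0 where the source
    reports none).
    """
    lit_sigma = {
        "beta": 0.25, "gamma": 0.25, "delta": 0.25, "zeta": 0.25,
        "k1": 0.25, "alpha": 0.25, "lambda5": 0.0,
    }

    def rate_sigma(name: str) -> float:
        if name in free_sigma:
            s = free_sigma[name]
            return 0.0 if math.isnan(s) else s
        if name in config.shared:
            return rate_sigma(config.shared[name])
        return lit_sigma.get(name, 0.0)

    comp = composite_rates(params)
    # omega sigmas: additive expressions, absolute quadrature
    sig_we = math.hypot(rate_sigma("k5"), rate_sigma("gamma"))
    sig_ws = math.sqrt(
        rate_sigma("k4") ** 2 + rate_sigma("k6") ** 2 + rate_sigma("delta") ** 2
    )
    k7_factors = [
        (params.k6, rate_sigma("k6")),
        (params.lambda3, rate_sigma("lambda3")),
        (params.lambda2, rate_sigma("lambda2")),
        (targets["TC"], targets.sigma("TC")),
        (targets["EEC"], targets.sigma("EEC")),
    ]
    sigma_k7 = propagate_tied_uncertainty(params.k7, k7_factors)
    k3_factors = [
        (params.k2, rate_sigma("k2")),
        (comp.omega_s, math.hypot(sig_ws, sigma_k7)),
        (comp.omega_e, sig_we),
        (targets["SP"], targets.sigma("SP")),
        (targets["AP"], targets.sigma("AP")),
    ]
    sigma_k3 = propagate_tied_uncertainty(params.k3, k3_factors)
    k9_factors = [
        (params.k8, rate_sigma("k8")),
        (params.lambda5, rate_sigma("lambda5")),
        (params.lambda4, rate_sigma("lambda4")),
        (targets["PC"], targets.sigma("PC")),
        (targets["GC"], targets.sigma("GC")),
    ]
    sigma_k9 = propagate_tied_uncertainty(params.k9, k9_factors)
    return {"k3": sigma_k3, "k7": sigma_k7, "k9": sigma_k9}


def _numerical_jacobian(
    free_values: np.ndarray,
    config: ScenarioConfig,
    targets: SteadyStateTargets,
    rel_step: float = 1e-7,
) -> np.ndarray:
    n = len(free_values)
    r0 = residual_vector(free_values, config, targets)
    jac = np.empty((len(r0), n))
    for i in range(n):
        h = rel_step * max(abs(free_values[i]), 1e-3)
        xp, xm = free_values.copy(), free_values.copy()
        xp[i] += h
        xm[i] -= h
        jac[:, i] = (
            residual_vector(xp, config, targets)
            - residual_vector(xm, config, targets)
        ) / (2 * h)
    return jac


def identifiability_at(
    free_values: np.ndarray,
    config: ScenarioConfig,
    targets: SteadyStateTargets,
) -> IdentifiabilityReport:
    """Rank and null space of the residual Jacobian at a point.

    Rank is counted at 1e-8 times the largest singular value; the right
    singular vectors of the discarded spectrum span the local flat
    directions of the constraint system.
    """
    jac = _numerical_jacobian(free_values, config, targets)
    u, s, vt = np.linalg.svd(jac, full_matrices=True)
    tol = 1e-8 * (s[0] if len(s) else 1.0)
    rank = int(np.sum(s > tol))
    null = vt[rank:, :]
    return IdentifiabilityReport(
        free_names=config.free,
        jacobian=jac,
        singular_values=s,
        rank=rank,
        null_space=null,
        tolerance=tol,
    )


def identifiability(
    fit: FitResult, config: ScenarioConfig, targets: SteadyStateTargets
) -> IdentifiabilityReport:
    """Identifiability diagnostics at a converged fit."""
    return identifiability_at(fit.free_values, config, targets)


def _pseudo_covariance(report: IdentifiabilityReport) -> np.ndarray:
    """Rank-truncated pseudo-inverse of J^T J — the parameter covariance on
    the identifiable subspace (unit residual variance)."""
    jac = report.jacobian
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    keep = s > report.tolerance
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep] ** 2
    return (vt.T * inv) @ vt


#: Identifiable parameter combinations of the baseline constraint system.
#: Each is pinned by one target ratio (e.g. k2/omega_e = AP/TAC), so they
#: are invariant along the solution manifold even though the individual
#: rates — and the bare composite rates other than omega_d — are not.
IDENTIFIABLE_COMBINATIONS: dict[str, Callable[[RateParameters], float]] = {
    "omega_d": lambda p: composite_rates(p).omega_d,
    "k2_over_omega_e": lambda p: p.k2 / composite_rates(p).omega_e,
    "k3_over_omega_s": lambda p: p.k3 / composite_rates(p).omega_s,
    "k4_over_omega_m": lambda p: p.k4 / composite_rates(p).omega_m,
    "k5_over_lambda1": lambda p: p.k5 / p.lambda1,
    "k6_over_lambda2": lambda p: p.k6 / p.lambda2,
    "k8_over_lambda4": lambda p: p.k8 / p.lambda4,
}


def combination_values(params: RateParameters) -> dict[str, float]:
    """Evaluate the identifiable combinations at a parameter set."""
    return {name: fn(params) for name, fn in IDENTIFIABLE_COMBINATIONS.items()}


def combination_sigmas(
    fit: FitResult, config: ScenarioConfig, targets: SteadyStateTargets
) -> dict[str, float]:
    """Delta-method sigmas of the identifiable combinations.

    Gradients are taken numerically with respect to the free vector (tied
    rates re-evaluated), contracted with the rank-truncated covariance.
    """
    x = fit.free_values
    out: dict[str, float] = {}
    for name, fn in IDENTIFIABLE_COMBINATIONS.items():
        grad = np.empty(len(x))
        for i in range(len(x)):
            h = 1e-7 * max(abs(x[i]), 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (
                fn(build_params(xp, config, targets))
                - fn(build_params(xm, config, targets))
            ) / (2 * h)
        out[name] = float(np.sqrt(grad @ fit.covariance @ grad))
    return out
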