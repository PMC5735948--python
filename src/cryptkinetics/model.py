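"""Time courses, steady states and renewal times of the compartment model.

The scheme is a pure linear cascade: every compartment is fed by exactly
one upstream compartment, so the system

    dCBC/dt = -(k1 - alpha) CBC
    dTAC/dt = -(k2 + k3 - beta) TAC + k1 CBC
    dAP/dt  =  k2 TAC - (k5 - gamma) AP
    dEC/dt  =  k5 AP - lambda1 EC
    dSP/dt  =  k3 TAC - (k4 + k6 + k7 - delta) SP
    dEEC/dt =  k6 SP - lambda2 EEC
    dTC/dt  =  k7 SP - lambda3 TC
    dGPP/dt =  k4 SP - (k8 + k9 - zeta) GPP
    dGC/dt  =  k8 GPP - lambda4 GC
    dPC/dt  =  k9 GPP - lambda5 PC

has a closed-form solution by the integrating-factor method.  For a chain
of distinct clearance rates a_0..a_n (a_0 being the net CBC decay rate,
zero in steady-CBC mode) driven by CBC0 with transfer rates b_1..b_n, the
terminal population is the partial-fraction sum

    X_n(t) = CBC0 * (prod b) * sum_i exp(-a_i t) / prod_{j != i} (a_j - a_i),

which reduces to the familiar per-compartment expressions (e.g.
TAC = (k1/omega_d) CBC0 (1 - e^{-omega_d t})) when a_0 = 0.  Coincident
rates make individual denominators vanish while the sum stays finite: the
sum is (-1)^n times the divided difference of x -> exp(-x t) over the
chain rates, so near-coincident rates (pairwise gap below 1e-3 relative,
where naive partial fractions lose precision to cancellation) are
evaluated exactly through the stable matrix-exponential form of the
divided difference, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import (
    CompositeRates,
    InitialCondition,
    RateParameters,
    composite_rates,
)

__all__ = [
    "COMPARTMENTS",
    "PopulationState",
    "ConfluentRateWarning",
    "ode_rhs",
    "closed_form_state",
    "closed_form_timecourse",
    "integrate_ode",
    "steady_state",
    "renewal_time",
    "write_timecourse_csv",
    "read_timecourse_csv",
]

#: The ten compartments in canonical order (stem cell to Paneth cell).
COMPARTMENTS: tuple[str, ...] = (
    "CBC", "TAC", "AP", "EC", "SP", "EEC", "TC", "GPP", "GC", "PC",
)

# Cascade topology: for each compartment, the transfer rates multiplying
# CBC0 and the names of the clearance rates along its chain (composite
# rates by omega-name, loss rates by lambda-name).  The leading net CBC
# decay rate a0 = k1 - alpha is prepended at evaluation time.
_CHAINS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "CBC": ((), ()),
    "TAC": (("k1",), ("omega_d",)),
    "AP": (("k1", "k2"), ("omega_d", "omega_e")),
    "EC": (("k1", "k2", "k5"), ("omega_d", "omega_e", "lambda1")),
    "SP": (("k1", "k3"), ("omega_d", "omega_s")),
    "EEC": (("k1", "k3", "k6"), ("omega_d", "omega_s", "lambda2")),
    "TC": (("k1", "k3", "k7"), ("omega_d", "omega_s", "lambda3")),
    "GPP": (("k1", "k3", "k4"), ("omega_d", "omega_s", "omega_m")),
    "GC": (("k1", "k3", "k4", "k8"), ("omega_d", "omega_s", "omega_m", "lambda4")),
    "PC": (("k1", "k3", "k4", "k9"), ("omega_d", "omega_s", "omega_m", "lambda5")),
}


class ConfluentRateWarning(UserWarning):
    """Emitted when near-coincident clearance rates force the slower,
    cancellation-free confluent evaluation path."""


@dataclass
class PopulationState:
    """Cell counts per crypt-villus unit at one time point (counts >= 0)."""

    CBC: float = 0.0
    TAC: float = 0.0
    AP: float = 0.0
    EC: float = 0.0
    SP: float = 0.0
    EEC: float = 0.0
    TC: float = 0.0
    GPP: float = 0.0
    GC: float = 0.0
    PC: float = 0.0
    t: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COMPARTMENTS])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPARTMENTS}

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    @classmethod
    def from_array(cls, values: Sequence[float], t: float | None = None) -> "PopulationState":
        return cls(**dict(zip(COMPARTMENTS, map(float, values))), t=t)


def _rate_value(name: str, params: RateParameters, comp: CompositeRates) -> float:
    if name.startswith("omega"):
        return getattr(comp, name)
    return getattr(params, name)


def _chain_terms(
    name: str, params: RateParameters, init: InitialCondition
) -> tuple[float, np.ndarray]:
    """Amplitude and chain clearance rates (leading net CBC decay first)
    for one compartment."""
    comp = composite_rates(params)
    transfers, rate_names = _CHAINS[name]
    a0 = params.k1 - params.alpha
    rates = np.array([a0] + [_rate_value(r, params, comp) for r in rate_names])
    amp = init.CBC0 * float(np.prod([getattr(params, t) for t in transfers]))
    return amp, rates


def _min_relative_gap(rates: np.ndarray) -> float:
    gap = np.inf
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            scale = max(abs(rates[i]), abs(rates[j]), 1e-30)
            gap = min(gap, abs(rates[i] - rates[j]) / scale)
    return gap


def _eval_chain(amp: float, rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate X(t) = amp * sum_i exp(-a_i t) / prod_{j!=i}(a_j - a_i).

    Well-separated rates use the sum directly in double precision.  When
    any pairwise gap falls below 1e-3 relative the sum cancels
    catastrophically (it is a divided difference of exp over clustered
    nodes), so it is evaluated in 60-digit arithmetic instead, with exact
    duplicates spread by 1e-10 relative — a bias far below the working
    precision of the result.
    """
    n = len(rates)
    if n == 1:
        return amp * np.exp(-rates[0] * t)
    if _min_relative_gap(rates) >= 1e-3:
        coeff = np.empty(n)
        for i in range(n):
            others = np.delete(rates, i)
            coeff[i] = 1.0 / np.prod(others - rates[i])
        return amp * (np.exp(-np.outer(t, rates)) @ coeff)
    warnings.warn(
        f"near-coincident clearance rates {np.array2string(rates, precision=6)}; "
        "using the high-precision confluent evaluation",
        ConfluentRateWarning,
        stacklevel=3,
    )
    import mpmath

    sep = 1e-10 * max(np.max(np.abs(rates)), 1.0)
    spread = np.sort(rates.astype(float))
    for i in range(1, n):
        if spread[i] - spread[i - 1] < sep:
            spread[i] = spread[i - 1] + sep
    out = np.empty_like(t, dtype=float)
    with mpmath.workdps(60):
        nodes = [mpmath.mpf(a) for a in spread]
        for k, tk in enumerate(t):
            total = mpmath.mpf(0)
            for i in range(n):
                denom = mpmath.mpf(1)
                for j in range(n):
                    if j != i:
                        denom *= nodes[j] - nodes[i]
                total += mpmath.exp(-nodes[i] * tk) / denom
            out[k] = float(total)
    return amp * out


def closed_form_state(
    params: RateParameters, init: InitialCondition, t: float
) -> PopulationState:
    """Evaluate the analytic solution of the cascade at time ``t`` (days).

    At t = 0 every compartment except CBC is empty; when all composite and
    loss rates are positive the state converges to :func:`steady_state` as
    t grows.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    values = {}
    t_arr = np.array([float(t)])
    for name in COMPARTMENTS:
        amp, rates = _chain_terms(name, params, init)
        val = float(_eval_chain(amp, rates, t_arr)[0])
        # tiny negative round-off near t=0 is clipped, not an error
        values[name] = max(val, 0.0)
    return PopulationState(**values, t=t)


def closed_form_timecourse(
    params: RateParameters, init: InitialCondition, t_grid: Sequence[float]
) -> pd.DataFrame:
    """Analytic trajectories on a time grid, as a tidy frame.

    Columns: ``t``, the ten compartments, and ``total``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be a sorted 1-D array of non-negative days")
    data = {"t": t}
    for name in COMPARTMENTS:
        amp, rates = _chain_terms(name, params, init)
        data[name] = np.clip(_eval_chain(amp, rates, t), 0.0, None)
    frame = pd.DataFrame(data)
    frame["total"] = frame[list(COMPARTMENTS)].sum(axis=1)
    return frame


def ode_rhs(state: PopulationState, params: RateParameters) -> np.ndarray:
    """Right-hand side of the kinetic equations (cells/day, canonical order)."""
    return _rhs_vector(state.as_array(), params)


def _rhs_vector(y: np.ndarray, params: RateParameters) -> np.ndarray:
    p = params
    CBC, TAC, AP, EC, SP, EEC, TC, GPP, GC, PC = y
    return np.array([
        -(p.k1 - p.alpha) * CBC,
        -(p.k2 + p.k3 - p.beta) * TAC + p.k1 * CBC,
        p.k2 * TAC - (p.k5 - p.gamma) * AP,
        p.k5 * AP - p.lambda1 * EC,
        p.k3 * TAC - (p.k4 + p.k6 + p.k7 - p.delta) * SP,
        p.k6 * SP - p.lambda2 * EEC,
        p.k7 * SP - p.lambda3 * TC,
        p.k4 * SP - (p.k8 + p.k9 - p.zeta) * GPP,
        p.k8 * GPP - p.lambda4 * GC,
        p.k9 * GPP - p.lambda5 * PC,
    ])


def integrate_ode(
    params: RateParameters,
    init: InitialCondition,
    t_grid: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Numerical solution of the kinetic ODEs (oracle for the closed forms).

    Starts from the all-empty state except CBC = CBC0 and returns the same
    frame layout as :func:`closed_form_timecourse`.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be a sorted 1-D array of non-negative days")
    y0 = np.zeros(len(COMPARTMENTS))
    y0[0] = init.CBC0
    sol = solve_ivp(
        lambda tt, yy: _rhs_vector(yy, params),
        (0.0, float(t[-1]) if len(t) else 0.0),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    frame = pd.DataFrame({"t": sol.t})
    for i, name in enumerate(COMPARTMENTS):
        frame[name] = sol.y[i]
    frame["total"] = frame[list(COMPARTMENTS)].sum(axis=1)
    return frame


def steady_state(params: RateParameters, init: InitialCondition) -> PopulationState:
    """Long-time limit of every compartment (requires a finite steady state).

    Uses the chained forms: TAC = (k1/omega_d) CBC0, AP = (k2/omega_e) TAC,
    EC = (k5/lambda1) AP, SP = (k3/omega_s) TAC, EEC = (k6/lambda2) SP,
    TC = (k7/lambda3) SP, GPP = (k4/omega_m) SP, GC = (k8/lambda4) GPP,
    PC = (k9/lambda5) GPP.
    """
    comp = composite_rates(params)
    if not comp.all_positive:
        raise ValueError(
            f"no finite steady state: non-positive composite rate(s) {comp.nonpositive}"
        )
    lambdas = {f"lambda{i}": getattr(params, f"lambda{i}") for i in range(1, 6)}
    bad = [k for k, v in lambdas.items() if v <= 0]
    if bad:
        raise ValueError(f"no finite steady state: non-positive loss rate(s) {bad}")
    TAC = params.k1 / comp.omega_d * init.CBC0
    AP = params.k2 / comp.omega_e * TAC
    EC = params.k5 / params.lambda1 * AP
    SP = params.k3 / comp.omega_s * TAC
    EEC = params.k6 / params.lambda2 * SP
    TC = params.k7 / params.lambda3 * SP
    GPP = params.k4 / comp.omega_m * SP
    GC = params.k8 / params.lambda4 * GPP
    PC = params.k9 / params.lambda5 * GPP
    return PopulationState(
        CBC=init.CBC0, TAC=TAC, AP=AP, EC=EC, SP=SP,
        EEC=EEC, TC=TC, GPP=GPP, GC=GC, PC=PC, t=np.inf,
    )


def renewal_time(
    params: RateParameters,
    init: InitialCondition,
    selector: str = "total",
    fraction: float = 0.95,
    horizon: float = 10_000.0,
    tol: float = 1e-3,
) -> float:
    """Smallest t (days) at which a population reaches ``fraction`` of its
    steady-state value.

    ``selector`` is one of the ten compartment names or ``"total"`` (the sum
    over all compartments).  The crossing is bracketed on [0, horizon] and
    located by bisection to ``tol`` days.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if selector != "total" and selector not in COMPARTMENTS:
        raise KeyError(f"unknown selector {selector!r}")
    ss = steady_state(params, init)
    target_inf = ss.total if selector == "total" else getattr(ss, selector)
    if not np.isfinite(target_inf) or target_inf <= 0:
        raise ValueError(f"population {selector!r} has no positive finite steady state")
    threshold = fraction * target_inf

    def value(t: float) -> float:
        state = closed_form_state(params, init, t)
        return (state.total if selector == "total" else getattr(state, selector))

    if value(horizon) < threshold:
        raise RuntimeError(
            f"{selector!r} does not reach {fraction:.0%} of steady state "
            f"within {horizon} days"
        )
    lo, hi = 0.0, horizon
    # shrink the bracket first so bisection finds the *first* crossing of a
    # monotone trajectory quickly
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if value(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def write_timecourse_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a time-course frame with the documented fixed column order."""
    cols = ["t", *COMPARTMENTS, "total"]
    frame.loc[:, cols].to_csv(path, index=False)


def read_timecourse_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["t", *COMPARTMENTS, "total"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"time-course CSV missing column(s) {missing}")
    return frame[expected]
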