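"""Local sensitivity analysis of the steady-state cell populations.

The derivative matrix S has one row per output (the nine non-CBC
steady-state populations) and one column per input (the 19 rate
constants): S_ij = dP_i/dr_j, evaluated by central differences on the
steady-state expressions.  Tied rates (k3, k7, k9) are perturbed as
independent inputs with their own uncertainties, mirroring how they are
reported alongside the fitted rates.

The variance matrix V_ij = S_ij^2 * sigma_rj^2 weights each sensitivity
by the squared input uncertainty; rank-ordering a row of V identifies the
inputs that most influence that population.  Note V as defined carries
cells^2; it is computed literally and not re-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import COMPARTMENTS, steady_state
from .params import InitialCondition, RateParameters, RATE_NAMES

__all__ = [
    "OUTPUTS",
    "SensitivityReport",
    "sensitivity_matrix",
    "variance_matrix",
    "rank_inputs",
    "sensitivity_report",
]

#: Model outputs: every steady-state population except the constant CBC.
OUTPUTS: tuple[str, ...] = tuple(c for c in COMPARTMENTS if c != "CBC")


@dataclass
class SensitivityReport:
    """S, V and per-output input rankings for one parameter set."""

    S: pd.DataFrame              # rows = outputs, columns = the 19 rates
    V: pd.DataFrame
    sigma_r: dict[str, float]
    rankings: dict[str, tuple[str, ...]]


def sensitivity_matrix(
    params: RateParameters,
    init: InitialCondition,
    step: float = 1e-6,
) -> pd.DataFrame:
    """Central-difference derivative matrix S_ij = dP_i/dr_j.

    Each rate r_j is perturbed alone by ``step * max(|r_j|, 1)``; a
    perturbation that destroys the steady state raises.
    """
    steady_state(params, init)  # validate existence up front
    S = pd.DataFrame(0.0, index=list(OUTPUTS), columns=list(RATE_NAMES))
    for name in RATE_NAMES:
        value = getattr(params, name)
        h = step * max(abs(value), 1.0)
        if value - h >= 0:
            lo, hi, denom = value - h, value + h, 2 * h
        else:  # forward difference keeps near-zero rates non-negative
            lo, hi, denom = value, value + h, h
        try:
            ss_hi = steady_state(params.replace(**{name: hi}), init)
            ss_lo = steady_state(params.replace(**{name: lo}), init)
        except ValueError as err:
            raise ValueError(
                f"perturbing {name} by {h:g} destroys the steady state"
            ) from err
        diff = (ss_hi.as_array() - ss_lo.as_array()) / denom
        for i, out in enumerate(COMPARTMENTS):
            if out in S.index:
                S.loc[out, name] = diff[i]
    return S


def variance_matrix(S: pd.DataFrame, sigma_r: Mapping[str, float]) -> pd.DataFrame:
    """V_ij = S_ij^2 * sigma_rj^2 (element-wise)."""
    missing = [c for c in S.columns if c not in sigma_r]
    if missing:
        raise ValueError(f"missing sigma for input(s) {missing}")
    sig = np.array([sigma_r[c] for c in S.columns])
    return (S**2) * sig**2


def rank_inputs(V: pd.DataFrame, output: str) -> tuple[str, ...]:
    """Inputs of one output row sorted by descending V_ij.

    Ties break by the canonical rate order (k1..k9, alpha..zeta,
    lambda1..lambda5).
    """
    if output not in V.index:
        raise KeyError(f"unknown output {output!r}")
    row = V.loc[output]
    order = {name: i for i, name in enumerate(RATE_NAMES)}
    return tuple(sorted(row.index, key=lambda n: (-row[n], order[n])))


def sensitivity_report(
    params: RateParameters,
    init: InitialCondition,
    sigma_r: Mapping[str, float],
    step: float = 1e-6,
) -> SensitivityReport:
    """Full local sensitivity analysis at one parameter set."""
    S = sensitivity_matrix(params, init, step=step)
    V = variance_matrix(S, sigma_r)
    rankings = {out: rank_inputs(V, out) for out in OUTPUTS}
    return SensitivityReport(S=S, V=V, sigma_r=dict(sigma_r), rankings=rankings)
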