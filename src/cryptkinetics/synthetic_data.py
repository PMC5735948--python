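"""Synthetic calibration targets and time courses from a known truth.

Real inputs to this pipeline are literature steady-state cell counts with
reported uncertainties.  The generator emulates exactly that: it takes a
known ("true") rate set, evaluates its steady states or closed-form
trajectories, and perturbs them with a declared noise model, recording the
truth alongside so that parameter-recovery experiments can score
themselves.  Noise kinds:

* ``none`` — targets equal the model values exactly;
* ``multiplicative-gaussian`` — value * (1 + cv * z), reported sigma
  cv * value;
* ``poisson-count`` — Poisson draws around the value, reported sigma
  sqrt(value).

Draws that land non-positive are redrawn (at most 100 attempts) rather
than truncated, keeping targets physical without biasing the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import SteadyStateTargets
from .model import COMPARTMENTS, closed_form_timecourse, steady_state
from .params import InitialCondition, RateParameters

__all__ = ["NoiseModel", "SyntheticTargets", "generate_targets", "generate_timecourse"]

_KINDS = ("none", "multiplicative-gaussian", "poisson-count")
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise specification; identical seeds reproduce draws."""

    kind: str = "none"
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"noise kind must be one of {_KINDS}, got {self.kind!r}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")


@dataclass
class SyntheticTargets:
    """Noisy targets plus the generating truth (the recovery oracle)."""

    targets: SteadyStateTargets
    true_params: RateParameters
    true_values: dict[str, float]
    noise: NoiseModel


def _perturb(value: float, noise: NoiseModel, rng: np.random.Generator) -> float:
    if noise.kind == "none":
        return value
    for _ in range(_MAX_REDRAWS):
        if noise.kind == "multiplicative-gaussian":
            draw = value * (1.0 + noise.cv * rng.standard_normal())
        else:  # poisson-count
            draw = float(rng.poisson(value))
        if draw > 0:
            return draw
    raise RuntimeError(
        f"could not draw a positive value around {value} after {_MAX_REDRAWS} attempts"
    )


def generate_targets(
    true_params: RateParameters,
    init: InitialCondition,
    noise: NoiseModel = NoiseModel(),
) -> SyntheticTargets:
    """Steady-state targets from a known rate set, perturbed per the noise
    model; reported sigma is cv*value (gaussian), sqrt(value) (poisson) or
    0 (none)."""
    ss = steady_state(true_params, init)
    rng = np.random.default_rng(noise.seed)
    values: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    truth: dict[str, float] = {}
    for comp in COMPARTMENTS:
        name = "CBC0" if comp == "CBC" else comp
        true_value = getattr(ss, comp)
        truth[name] = true_value
        values[name] = _perturb(true_value, noise, rng)
        if noise.kind == "multiplicative-gaussian":
            sigmas[name] = noise.cv * true_value
        elif noise.kind == "poisson-count":
            sigmas[name] = float(np.sqrt(true_value))
        else:
            sigmas[name] = 0.0
    targets = SteadyStateTargets(values=values, sigmas=sigmas, N=ss.total)
    return SyntheticTargets(
        targets=targets, true_params=true_params, true_values=truth, noise=noise
    )


def generate_timecourse(
    true_params: RateParameters,
    init: InitialCondition,
    t_grid: Sequence[float],
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Closed-form trajectories sampled on ``t_grid`` with per-point noise,
    in the standard time-course frame layout (t, compartments, total)."""
    frame = closed_form_timecourse(true_params, init, t_grid)
    if noise.kind == "none":
        return frame
    rng = np.random.default_rng(noise.seed)
    noisy = frame.copy()
    for comp in COMPARTMENTS:
        noisy[comp] = [
            _perturb(v, noise, rng) if v > 0 else 0.0 for v in frame[comp]
        ]
    noisy["total"] = noisy[list(COMPARTMENTS)].sum(axis=1)
    return noisy
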