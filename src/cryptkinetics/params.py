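"""Kinetic rate parameterization of the crypt-villus compartmental scheme.

The model tracks ten epithelial cell compartments per crypt-villus unit
(CVU): the crypt-based columnar stem cell (CBC), the transit-amplifying
cell (TAC), absorptive and secretory progenitors (AP, SP), the
goblet/Paneth progenitor (GPP), and the five terminally differentiated
types (EC, EEC, TC, GC, PC).  Nineteen first-order rate constants (all in
day^-1) govern the flows between compartments:

* ``k1``-``k9`` -- differentiation rates along the lineage tree,
* ``alpha``-``zeta`` -- proliferation rates of the dividing compartments,
* ``lambda1``-``lambda5`` -- loss rates of the differentiated types.

Each proliferating compartment empties at a *composite* net clearance rate
(outgoing differentiation minus own proliferation); all four composite
rates must be positive for a finite steady state to exist.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "RATE_NAMES",
    "RateParameters",
    "CompositeRates",
    "InitialCondition",
    "composite_rates",
    "read_parameter_config",
    "write_parameter_config",
]

#: Canonical ordering of the 19 rate constants; used for vectors, matrices
#: and deterministic tie-breaking everywhere in the package.
RATE_NAMES: tuple[str, ...] = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
    "alpha", "beta", "gamma", "delta", "zeta",
    "lambda1", "lambda2", "lambda3", "lambda4", "lambda5",
)


@dataclass
class RateParameters:
    """The 19 kinetic rate constants of the scheme, all in day^-1.

    Rates must be non-negative.  In steady-state mode (the default for
    calibrated runs) the stem-cell compartment is constant, which requires
    ``k1 == alpha`` exactly; :meth:`validate` enforces this when
    ``steady_cbc=True``.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    k7: float = 0.0
    k8: float = 0.0
    k9: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0
    zeta: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    lambda4: float = 0.0
    lambda5: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = float(getattr(self, name))
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")
            setattr(self, name, value)

    def validate(self, steady_cbc: bool = True) -> None:
        """Raise ``ValueError`` on an invalid parameter set."""
        if steady_cbc and self.k1 != self.alpha:
            raise ValueError(
                "steady-state CBC mode requires k1 == alpha "
                f"(got k1={self.k1}, alpha={self.alpha})"
            )

    @property
    def steady_cbc(self) -> bool:
        """True when the stem-cell compartment is constant (k1 == alpha)."""
        return self.k1 == self.alpha

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "RateParameters":
        unknown = set(values) - set(RATE_NAMES)
        if unknown:
            raise KeyError(f"unknown rate name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})

    def replace(self, **changes: float) -> "RateParameters":
        return dataclasses.replace(self, **changes)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())


@dataclass(frozen=True)
class CompositeRates:
    """Net clearance rates of the four proliferating compartments.

    ``omega_d`` (TAC), ``omega_e`` (AP), ``omega_s`` (SP) and ``omega_m``
    (GPP) are the sums of outgoing differentiation rates minus the
    compartment's own proliferation rate.  Any non-positive value means the
    compartment grows without bound and no finite steady state exists;
    :attr:`nonpositive` names the offenders (a flag, not an error, since
    transient analysis may still be meaningful).
    """

    omega_d: float
    omega_e: float
    omega_s: float
    omega_m: float

    @property
    def nonpositive(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("omega_d", "omega_e", "omega_s", "omega_m")
            if getattr(self, name) <= 0
        )

    @property
    def all_positive(self) -> bool:
        return not self.nonpositive

    def as_dict(self) -> dict[str, float]:
        return {
            "omega_d": self.omega_d,
            "omega_e": self.omega_e,
            "omega_s": self.omega_s,
            "omega_m": self.omega_m,
        }


@dataclass(frozen=True)
class InitialCondition:
    """Initial stem-cell count per crypt-villus unit.

    All other compartments start empty; CBC0 > 0 is required for any
    nontrivial dynamics.
    """

    CBC0: float = 10.0

    def __post_init__(self) -> None:
        if self.CBC0 <= 0:
            raise ValueError(f"CBC0 must be > 0, got {self.CBC0}")


def composite_rates(params: RateParameters) -> CompositeRates:
    """Compute the four composite clearance rates from a parameter set.

    omega_d = k2 + k3 - beta          (transit-amplifying cells)
    omega_e = k5 - gamma              (absorptive progenitors)
    omega_s = k4 + k6 + k7 - delta    (secretory progenitors)
    omega_m = k8 + k9 - zeta          (goblet/Paneth progenitors)
    """
    return CompositeRates(
        omega_d=params.k2 + params.k3 - params.beta,
        omega_e=params.k5 - params.gamma,
        omega_s=params.k4 + params.k6 + params.k7 - params.delta,
        omega_m=params.k8 + params.k9 - params.zeta,
    )


def read_parameter_config(path: str | Path) -> tuple[RateParameters, InitialCondition]:
    """Read a flat key-value parameter file (YAML mapping).

    Keys are exactly the 19 rate names plus ``CBC0``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter config {path} must be a flat mapping")
    cbc0 = float(raw.pop("CBC0", 10.0))
    return RateParameters.from_dict(raw), InitialCondition(CBC0=cbc0)


def write_parameter_config(
    path: str | Path, params: RateParameters, init: InitialCondition
) -> None:
    """Write parameters and CBC0 as a flat YAML mapping."""
    payload = {name: float(val) for name, val in params}
    payload["CBC0"] = float(init.CBC0)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
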