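"""Steady-state calibration targets for a crypt-villus unit (CVU).

Literature reports cell abundances either per crypt (multiplied by the
number of crypts feeding a villus, here 2) or as fractions of the total
CVU cell count N.  Three progenitor compartments — absorptive progenitors
(AP), secretory progenitors (SP) and goblet/Paneth progenitors (GPP) —
have no measured abundance and are estimated by assuming each progenitor
pool is proportional (constant phi) to the steady-state sum of its
terminal progeny:

    f_GPP = phi (GC + PC) / N          =>  phi = f_GPP N / (GC + PC)
    GPP   = phi (GC + PC)
    AP    = phi EC
    SP    = phi [EEC + TC + (1 + phi)(GC + PC)]

The enterocyte count then follows from cell-number conservation,
EC = (N - sum of everything else), which with AP = phi EC closes to

    EC = [N - (CBC0 + TAC + SP + GPP + EEC + TC + GC + PC)] / (1 + phi).

Finally, each branch point of the lineage tree lets the higher-subscript
differentiation rate be expressed through the lower one and the target
abundance ratio of the two branches:

    k3 = k2 (omega_s/omega_e) (SP/AP)
    k7 = k6 (lambda3/lambda2) (TC/EEC)
    k9 = k8 (lambda5/lambda4) (PC/GC)

(k7 must be evaluated before k3 because omega_s contains k7.)
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import presets
from .params import RateParameters, composite_rates

__all__ = [
    "CVUComposition",
    "SteadyStateTargets",
    "TARGET_COMPARTMENTS",
    "assemble_cvu_targets",
    "compute_phi",
    "estimate_progenitors",
    "enterocyte_target",
    "tied_rates",
    "calibrate_targets",
    "read_literature_config",
]

#: Compartments carrying a calibrated steady-state target, in canonical
#: order.  "CBC0" plays the role of the (constant) CBC compartment.
TARGET_COMPARTMENTS: tuple[str, ...] = (
    "CBC0", "TAC", "AP", "EC", "SP", "EEC", "TC", "GPP", "GC", "PC",
)


@dataclass(frozen=True)
class CVUComposition:
    """Cell bookkeeping of one crypt-villus unit."""

    N_c: float = presets.N_CRYPT_CELLS_PER_CRYPT * presets.CRYPTS_PER_VILLUS
    N_v: float = presets.N_VILLUS_CELLS
    crypts_per_villus: int = presets.CRYPTS_PER_VILLUS

    def __post_init__(self) -> None:
        if self.N_c <= 0 or self.N_v <= 0 or self.crypts_per_villus <= 0:
            raise ValueError("CVU composition values must be positive")

    @property
    def N(self) -> float:
        """Total cells per crypt-villus unit."""
        return self.N_c + self.N_v


@dataclass
class SteadyStateTargets:
    """Calibrated long-time cell counts per CVU with uncertainties.

    ``values`` maps target names (:data:`TARGET_COMPARTMENTS`) to counts;
    ``sigmas`` to absolute uncertainties (0 when the source reports none).
    ``phi`` is the progenitor proportionality constant and the ``f_*``
    fields the dimensionless abundance fractions it implies.
    """

    values: dict[str, float] = field(default_factory=dict)
    sigmas: dict[str, float] = field(default_factory=dict)
    N: float = 4000.0
    phi: float | None = None
    f_GPP: float | None = None
    f_AP: float | None = None
    f_SP: float | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def sigma(self, name: str) -> float:
        return self.sigmas.get(name, 0.0)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.values]
        if missing:
            raise KeyError(f"missing steady-state target(s): {missing}")

    @property
    def total(self) -> float:
        return sum(self.values[n] for n in TARGET_COMPARTMENTS if n in self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": n, "value": self.values[n], "sigma": self.sigma(n)}
            for n in TARGET_COMPARTMENTS
            if n in self.values
        ]
        return pd.DataFrame(rows)

    def replace(self, **changes) -> "SteadyStateTargets":
        return dataclasses.replace(self, **changes)


def assemble_cvu_targets(
    literature: Mapping[str, tuple[float, float | None, str]] | None = None,
    comp: CVUComposition | None = None,
) -> SteadyStateTargets:
    """Scale literature abundances onto the per-CVU basis.

    Each entry is ``(value, uncertainty, basis)`` where basis is
    ``"per_crypt"`` (multiplied by crypts per villus), ``"fraction"``
    (multiplied by the CVU total N) or ``"per_cvu"`` (used as is).
    Uncertainties scale identically; progenitor targets are left unfilled.
    """
    literature = dict(presets.LITERATURE_COUNTS if literature is None else literature)
    comp = comp or CVUComposition()
    required = ("CBC0", "TAC", "EEC", "TC", "GC", "PC")
    missing = [n for n in required if n not in literature]
    if missing:
        raise KeyError(f"missing literature input(s): {missing}")
    values: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    for name, (value, sigma, basis) in literature.items():
        if basis == "per_crypt":
            factor = float(comp.crypts_per_villus)
        elif basis == "fraction":
            factor = comp.N
        elif basis == "per_cvu":
            factor = 1.0
        else:
            raise ValueError(f"unknown basis {basis!r} for {name}")
        values[name] = value * factor
        sigmas[name] = (sigma or 0.0) * factor
    return SteadyStateTargets(values=values, sigmas=sigmas, N=comp.N)


def compute_phi(f_GPP: float, GC_inf: float, PC_inf: float, N: float) -> float:
    """Progenitor proportionality constant phi = f_GPP * N / (GC + PC)."""
    denom = GC_inf + PC_inf
    if denom <= 0:
        raise ZeroDivisionError("GC_inf + PC_inf must be > 0 to compute phi")
    return f_GPP * N / denom


def estimate_progenitors(
    phi: float, targets: SteadyStateTargets, f_GPP: float | None = None
) -> SteadyStateTargets:
    """Fill the unobserved progenitor targets GPP, SP (and AP if EC known).

    Uncertainties propagate through the proportionality relations with phi
    treated as exact.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    targets.require("EEC", "TC", "GC", "PC")
    v, s = dict(targets.values), dict(targets.sigmas)
    gcpc = v["GC"] + v["PC"]
    s_gcpc = math.hypot(targets.sigma("GC"), targets.sigma("PC"))
    v["GPP"] = phi * gcpc
    s["GPP"] = phi * s_gcpc
    v["SP"] = phi * (v["EEC"] + v["TC"] + (1 + phi) * gcpc)
    s["SP"] = phi * math.sqrt(
        targets.sigma("EEC") ** 2
        + targets.sigma("TC") ** 2
        + (1 + phi) ** 2 * s_gcpc**2
    )
    if "EC" in v:
        v["AP"] = phi * v["EC"]
        s["AP"] = phi * targets.sigma("EC")
    return targets.replace(
        values=v, sigmas=s, phi=phi,
        f_GPP=f_GPP if f_GPP is not None else v["GPP"] / targets.N,
        f_SP=v["SP"] / targets.N,
        f_AP=(v.get("AP", 0.0) / targets.N) if "AP" in v else None,
    )


def enterocyte_target(
    phi: float, targets: SteadyStateTargets, N: float | None = None
) -> SteadyStateTargets:
    """Close the calibration with the conservation-derived enterocyte count.

    EC = [N - (CBC0 + TAC + SP + GPP + EEC + TC + GC + PC)] / (1 + phi),
    after which AP = phi * EC and the ten targets sum exactly to N.
    """
    N = targets.N if N is None else N
    others = ("CBC0", "TAC", "SP", "GPP", "EEC", "TC", "GC", "PC")
    targets.require(*others)
    residual = N - sum(targets[n] for n in others)
    ec = residual / (1 + phi)
    if ec <= 0:
        raise ValueError(f"enterocyte target is non-positive ({ec:.3f})")
    v, s = dict(targets.values), dict(targets.sigmas)
    v["EC"] = ec
    s["EC"] = math.sqrt(sum(targets.sigma(n) ** 2 for n in others)) / (1 + phi)
    v["AP"] = phi * ec
    s["AP"] = phi * s["EC"]
    return targets.replace(values=v, sigmas=s, phi=phi, f_AP=v["AP"] / targets.N)


def tied_rates(
    params: RateParameters, targets: SteadyStateTargets
) -> tuple[float, float, float]:
    """Branch-ratio constraints (k3, k7, k9) from free rates and targets.

    k7 depends only on k6 and the loss rates, so it is evaluated first;
    omega_s (which contains k7) then enters k3.
    """
    targets.require("AP", "SP", "EEC", "TC", "GC", "PC")
    for name, value in (
        ("lambda2", params.lambda2),
        ("lambda4", params.lambda4),
        ("EEC target", targets["EEC"]),
        ("GC target", targets["GC"]),
        ("AP target", targets["AP"]),
    ):
        if value == 0:
            raise ZeroDivisionError(f"tied rates undefined: {name} is zero")
    k7 = params.k6 * (params.lambda3 / params.lambda2) * (targets["TC"] / targets["EEC"])
    omega_e = params.k5 - params.gamma
    if omega_e == 0:
        raise ZeroDivisionError("tied rates undefined: omega_e is zero")
    omega_s = params.k4 + params.k6 + k7 - params.delta
    k3 = params.k2 * (omega_s / omega_e) * (targets["SP"] / targets["AP"])
    k9 = params.k8 * (params.lambda5 / params.lambda4) * (targets["PC"] / targets["GC"])
    return k3, k7, k9


def calibrate_targets(
    literature: Mapping[str, tuple[float, float | None, str]] | None = None,
    comp: CVUComposition | None = None,
    f_GPP: float = presets.F_GPP,
    f_GPP_sigma: float = presets.F_GPP_SIGMA,
) -> SteadyStateTargets:
    """Full calibration: scale literature counts, estimate progenitors,
    close with the enterocyte conservation target."""
    targets = assemble_cvu_targets(literature, comp)
    phi = compute_phi(f_GPP, targets["GC"], targets["PC"], targets.N)
    targets = estimate_progenitors(phi, targets, f_GPP=f_GPP)
    # GPP uncertainty is better taken from the assumed abundance fraction
    # (1 +/- 0.5% of N) than from GC/PC propagation
    if f_GPP_sigma:
        targets.sigmas["GPP"] = f_GPP_sigma * targets.N
    return enterocyte_target(phi, targets)


def read_literature_config(path: str | Path) -> SteadyStateTargets:
    """Read a literature-abundance config and run the full calibration.

    Schema (YAML)::

        composition: {N_c: 500, N_v: 3500, crypts_per_villus: 2}
        f_GPP: {value: 0.01, uncertainty: 0.005}
        counts:
          CBC0: {value: 5, uncertainty: 1, basis: per_crypt, source: "..."}
          ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    comp_raw = raw.get("composition", {})
    comp = CVUComposition(
        N_c=float(comp_raw.get("N_c", 500.0)),
        N_v=float(comp_raw.get("N_v", 3500.0)),
        crypts_per_villus=int(comp_raw.get("crypts_per_villus", 2)),
    )
    counts = {}
    for name, entry in raw.get("counts", {}).items():
        counts[name] = (
            float(entry["value"]),
            None if entry.get("uncertainty") is None else float(entry["uncertainty"]),
            entry.get("basis", "per_cvu"),
        )
    fg = raw.get("f_GPP", {})
    return calibrate_targets(
        literature=counts or None,
        comp=comp,
        f_GPP=float(fg.get("value", presets.F_GPP)),
        f_GPP_sigma=float(fg.get("uncertainty", presets.F_GPP_SIGMA)),
    )
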