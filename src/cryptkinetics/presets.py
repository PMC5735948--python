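"""Published parameter sets and literature inputs for murine ileum.

These are data, not code: literature cell counts per crypt or as fractions
of the crypt-villus unit (CVU) total, the fixed literature rates, and the
two published fitted rate sets ("baseline" and "fast") together with
their printed uncertainties.  They are used as calibration inputs, as
fit starting points in reproduction mode, and as the uncertainty vectors
for the sensitivity analysis.
"""

from __future__ import annotations

from .params import InitialCondition, RateParameters

__all__ = [
    "CRYPTS_PER_VILLUS",
    "N_CRYPT_CELLS_PER_CRYPT",
    "N_VILLUS_CELLS",
    "LITERATURE_COUNTS",
    "F_GPP",
    "F_GPP_SIGMA",
    "FIXED_LITERATURE_RATES",
    "BASELINE_PARAMS",
    "BASELINE_SIGMAS",
    "FAST_PARAMS",
    "FAST_SIGMAS",
    "DEFAULT_INIT",
]

#: Hexagonal packing of crypts around villi in ileum: each villus is fed,
#: on average, by two complete crypts.
CRYPTS_PER_VILLUS = 2

N_CRYPT_CELLS_PER_CRYPT = 250.0   # cells per crypt
N_VILLUS_CELLS = 3500.0           # cells per villus

#: Literature abundances: (value, uncertainty, basis).  basis "per_crypt"
#: values are multiplied by CRYPTS_PER_VILLUS; basis "fraction" values by
#: the CVU total N.  Uncertainties scale the same way; None means the
#: source reports no error estimate.
LITERATURE_COUNTS: dict[str, tuple[float, float | None, str]] = {
    "CBC0": (5.0, 1.0, "per_crypt"),        # Lgr5+ stem cells
    "TAC": (155.0, 5.0, "per_crypt"),       # rapidly dividing crypt cells
    "EEC": (0.01, None, "fraction"),        # enteroendocrine cells
    "TC": (0.004, None, "fraction"),        # tuft cells
    "GC": (0.085, 0.015, "fraction"),       # goblet cells
    "PC": (40.0, 10.0, "per_crypt"),        # Paneth cells
}

#: Goblet/Paneth progenitor ("intermediate cell") abundance as a fraction
#: of the CVU total, estimated from published immunofluorescence imagery.
F_GPP = 0.01
F_GPP_SIGMA = 0.005

#: Rates fixed at literature values in the baseline scenario (day^-1).
FIXED_LITERATURE_RATES: dict[str, float] = {
    "k1": 1.0,          # CBC cycling rate; steady CBC forces alpha = k1
    "alpha": 1.0,
    "beta": 1.75,       # TAC proliferation; assumed shared by progenitors
    "gamma": 1.75,
    "delta": 1.75,
    "zeta": 1.75,
    "lambda5": 1.0 / 21.0,  # Paneth cell loss, once per three weeks
}

DEFAULT_INIT = InitialCondition(CBC0=10.0)

#: Published baseline-scenario rates (fitted + constrained), day^-1.
BASELINE_PARAMS = RateParameters(
    k1=1.0, alpha=1.0,
    k2=1.714495, k3=0.068, k4=1.67958, k5=3.7112,
    k6=0.3565, k7=0.14, k8=3.712, k9=0.095,
    beta=1.75, gamma=1.75, delta=1.75, zeta=1.75,
    lambda1=0.35364, lambda2=0.43673, lambda3=0.43673,
    lambda4=0.43673, lambda5=1.0 / 21.0,
)

#: Published baseline uncertainties (day^-1); lambda5 has no printed error.
BASELINE_SIGMAS: dict[str, float] = {
    "k1": 0.25, "alpha": 0.25,            # assumed 25%
    "k2": 0.000008, "k3": 0.06, "k4": 0.00005, "k5": 0.0009,
    "k6": 0.0002, "k7": 0.10, "k8": 0.008, "k9": 0.045,
    "beta": 0.25, "gamma": 0.25, "delta": 0.25, "zeta": 0.25,
    "lambda1": 0.00007, "lambda2": 0.00005, "lambda3": 0.00005,
    "lambda4": 0.00005, "lambda5": 0.0,
}

#: Published fast-scenario rates (all parameters freed; tied rates from the
#: branching identities), day^-1.
FAST_PARAMS = RateParameters(
    k1=24.025, alpha=24.025,
    k2=6.4369, k3=0.125, k4=0.798, k5=14.875,
    k6=0.1050, k7=0.052, k8=1.326, k9=0.096,
    beta=5.7868, gamma=7.512, delta=0.096, zeta=0.523,
    lambda1=1.4154, lambda2=0.1182, lambda3=0.148,
    lambda4=0.1560, lambda5=0.0479,
)

FAST_SIGMAS: dict[str, float] = {
    "k1": 0.006, "alpha": 0.006,
    "k2": 0.0002, "k3": 0.108, "k4": 0.001, "k5": 0.004,
    "k6": 0.0002, "k7": 0.037, "k8": 0.004, "k9": 0.041,
    "beta": 0.0002, "gamma": 0.002, "delta": 0.001, "zeta": 0.002,
    "lambda1": 0.0004, "lambda2": 0.0002, "lambda3": 0.004,
    "lambda4": 0.0004, "lambda5": 0.0009,
}
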