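# Methods

## Model

Ten cell compartments of the murine ileal crypt-villus unit (CVU) — CBC,
TAC, AP, EC, SP, EEC, TC, GPP, GC, PC — evolve by first-order mass-action
kinetics. Differentiation rates k1–k9 move cells down the lineage tree,
proliferation rates α, β, γ, δ, ζ act within the five dividing
compartments, and loss rates λ1–λ5 remove the five terminally
differentiated types. All rates are in day⁻¹; counts are real-valued cells
per CVU (a deterministic mean-field description, not a birth–death
process). Time is in days throughout.

A constant stem-cell pool requires k1 = α exactly; this steady-CBC mode is
the default and the only mode used for calibrated runs. A non-steady mode
(k1 ≠ α, exponentially growing or decaying CBC) is supported for synthetic
experiments only.

Assumptions inherited from the calibration literature: every villus is fed
on average by 2 crypts (hexagonal ileal packing), so per-crypt counts are
doubled; all dividing progenitors proliferate at the TAC rate
(β = γ = δ = ζ = 1.75/day); the secretory loss rates are shared
(λ2 = λ3 = λ4) except the Paneth rate λ5 = 1/21/day; k1 = α = 1/day.

## Closed-form solution

The scheme is a pure cascade — each compartment has exactly one upstream
source — so each population is the inverse Laplace transform of
`CBC0·(∏ transfer rates) / (s·∏(s + a_j))`, a partial-fraction sum of
exponentials over its chain's clearance rates a_j (the composite rates
ω_d, ω_e, ω_s, ω_m and the λ's, plus the net CBC decay rate, zero in
steady mode). This evaluates the textbook per-compartment expressions
(e.g. `TAC = (k1/ω_d)·CBC0·(1 − e^{−ω_d t})`) for all chains uniformly.

Numerics of coincident rates: the partial-fraction coefficients diverge as
chain rates approach each other although the sum (a divided difference of
x ↦ e^{−xt}) stays finite. When any pairwise gap falls below 1e-3 relative
the sum is evaluated in 60-digit arithmetic (mpmath), with exact
duplicates spread by 1e-10 relative — a bias orders of magnitude below the
1e-6 agreement the tests demand. A simple float-precision perturbation was
rejected because it loses ~1e-1 relative accuracy under triple
confluence, and a matrix-exponential (bidiagonal expm) route proved
inaccurate for nearly- but not exactly-coincident nodes. A
`ConfluentRateWarning` flags the slow path.

The numerical ODE integrator (`integrate_ode`, LSODA, default rtol 1e-9)
exists purely as an independent oracle for the closed forms and is
property-tested against them over random valid rate sets.

Renewal times locate the first crossing of a fraction of the steady state
by bisection on the closed form, to 1e-3 day (configurable), within a
10,000-day horizon. All trajectories here are monotone, so bisection finds
the unique crossing; the choice of bisection is a design decision — any
bracketing root finder gives the same answer to tolerance.

## Calibration

Literature abundances arrive either per crypt (×2) or as fractions of the
N = 4000-cell CVU. Unobserved progenitor pools are estimated by assuming
each progenitor is proportional, with a single constant φ, to the
steady-state sum of its terminal progeny. φ is fixed by the assumed
goblet/Paneth-progenitor abundance f_GPP = 1 ± 0.5% of N:
φ = f_GPP·N/(GC∞+PC∞) = 0.0952. Then GPP∞ = φ(GC∞+PC∞) = 40,
SP∞ = φ[EEC∞+TC∞+(1+φ)(GC∞+PC∞)] ≈ 49.14, AP∞ = φ·EC∞, and the
enterocyte count closes by conservation,
EC∞ = [N − (CBC0+TAC∞+SP∞+GPP∞+EEC∞+TC∞+GC∞+PC∞)]/(1+φ) = 2844,
after which the ten targets sum to N exactly. φ computed from the baseline
targets is reused everywhere; it is treated as exact in uncertainty
propagation (its own ±50% assumption dominates the GPP target error, which
is therefore taken as f_GPP_sigma·N = 20 cells rather than propagated from
GC/PC).

Branch-point ties express the higher-subscripted rate of each branching
through the lower one and the target abundance ratio:
k3 = k2(ω_s/ω_e)(SP∞/AP∞), k7 = k6(λ3/λ2)(TC∞/EEC∞),
k9 = k8(λ5/λ4)(PC∞/GC∞). k7 is evaluated before k3 because ω_s contains
k7 (the evaluation order is forced by the dependency, though not spelled
out in the source tables). A useful collapse: combining the k9 tie with
the goblet steady state gives k9 = λ5·PC∞/GPP∞ = 2/21 ≈ 0.0952
independent of k8; the tests assert it.

## Fitting

Baseline scenario: free rates {k2, k4, k5, k6, k8, λ1, λ2}, seven
steady-state targets {TAC, AP, SP, GPP, EEC, GC, EC} (TC and PC are
satisfied identically through the ties). Fast scenario: all 15 non-tied
rates free, plus one residual `EC(5 d) − 0.95·EC∞` (weight 1 by default —
the mechanism by which the original analysis imposed this constraint is
not documented, and a weighted residual is the least-intrusive choice).
Residuals are unweighted cell counts by default; an option weights them by
target σ for statistically calibrated synthetic-recovery experiments.

Optimizer: scipy `least_squares` (TRF) with non-negativity bounds on every
rate and Jacobian column scaling (without which the fast scenario stalls
from literature starts). Infeasible regions (any composite or loss rate
≤ 0, where no steady state exists) return large smooth penalty residuals
so the optimizer can recover. Baseline-shaped scenarios start from the
closed-form interpolant of the target algebra: the targets determine every
free rate once k2 is chosen, via ω_d = k1·CBC0/TAC∞, ω_e = k2·TAC∞/AP∞,
λ1 = k5·AP∞/EC∞, a linear equation in λ2 closing the secretory branch,
and k2 = 0.96(ω_d+β) as a neutral point on the manifold. This replaces a
naive all-ones start, which left noisy synthetic fits in distant local
minima. The fast scenario starts from literature values with a
feasibility repair; deterministic seeded restarts (log-normal jitter) run
until the SSR threshold (1e-6 cells²) is met.

Identifiability: the baseline system has seven free rates but a rank-6
residual Jacobian — the k3 tie makes the SP residual dependent on the AP
one — so a one-dimensional solution manifold exists and individual fitted
values are solver-dependent. The identifiable quantities are the
target-ratio combinations ω_d, k2/ω_e, k3/ω_s, k4/ω_m, k5/λ1, k6/λ2,
k8/λ4 (six independent; the k3 tie links the second and third). Note the
bare composite rates ω_e, ω_s, ω_m are *not* invariant along the flat
direction, only their ratios to the feeding rate are. Rank is counted at
1e-8 × the largest singular value; the discarded right singular vectors
are reported as the flat directions. Reproduction mode pins k2 at its
published value, making the solution unique so the published constrained
rates (k3 = 0.068, k7 = 0.14, k9 = 0.095) can be checked at printed
precision. The fast scenario is underdetermined (15 free rates, 8
constraints); its published values are one valid solution, not ground
truth, and are treated as such.

Uncertainties: one-at-a-time curvature — each fitted value is displaced by
±1e-6 day⁻¹ (absolute, as in the source procedure; a relative-step option
exists because absolute steps misbehave for rates ≫ 1), the SSR increase
is fitted to aΔ², and σ = √(1/(2a)); non-positive curvature is flagged
rather than raised. These are conditional (others-held-fixed) sigmas under
an implicit unit data variance — they quantify the sharpness of the SSR
bowl, not calibrated confidence intervals. Tied-rate sigmas propagate by
quadrature of the relative errors of every factor in the defining
expression; the σ values for the EEC∞ and TC∞ targets are not documented
and default to 0 (configurable), so the package's σ_k7 is smaller than the
published 0.10. For statistically calibrated statements (the synthetic
recovery tests) the package instead uses σ-weighted residuals and the
delta method on the rank-truncated pseudo-inverse of JᵀJ.

## Sensitivity analysis

S_ij = ∂P_i/∂r_j over the nine non-CBC steady-state populations and all
19 rates, by central differences on the steady-state expressions with
step 1e-6·max(|r_j|, 1) (one-sided at zero to preserve non-negativity);
a symbolic-differentiation oracle (sympy) checks S to 1e-6 relative in the
tests. Tied rates are perturbed as independent inputs with their own σ —
matching how they are tabulated with their own uncertainties — rather than
chain-ruled through the ties. V_ij = S_ij²σ_j² uses the published σ
vectors of each scenario; as defined V carries cells², and no
re-normalisation is applied (the source calls V dimensionless without
giving one). Rankings sort each output's row of V descending, ties broken
by the canonical rate order. The reproduced findings: baseline rankings
put β first and k3 second for every output; fast rankings put k3 first for
every output.

## Synthetic data

The generator emulates exactly the pipeline's real inputs: steady-state
targets with reported uncertainties, and time-course observations.
Defaults: truth = the published baseline rate set with CBC0 = 10 (so
synthetic experiments live in the calibrated regime); multiplicative
Gaussian noise at a declared CV with reported σ = cv·value, or Poisson
counts with σ = √value; non-positive draws are redrawn (≤100 attempts)
rather than truncated, avoiding silent bias. Identical seeds reproduce
draws exactly.

What passing synthetic tests do and do not show: the generator draws
independent noise per compartment around exact steady states — it does not
emulate histology section counting, staining efficiency, correlated
errors between cell types, or biological variation of the rate constants
themselves. Recovery results therefore demonstrate the estimator's
correctness and calibration under its own noise model, not robustness to
real measurement processes.

## Scenario runs and problem sizes

`run_scenario` writes all artifacts with fixed column orders and a
manifest; two runs with the same config and seed are byte-identical. The
default time-course grid is 0–100 days at 0.1-day steps. The test suite's
Monte-Carlo sizes — 100-seed generator checks, 100 noisy-recovery
replicates, ~20 hypothesis examples for the ODE-oracle property — were
chosen as the smallest sizes at which the asserted statistics are stable.

## Known limitations

- No spatial structure, migration, lattice or agent-based dynamics; no
  stochastic birth–death simulation — deliberately outside scope.
- The mean-field first-order model cannot reproduce the observed ~5-day
  epithelial renewal with measured rates; that failure is the headline
  scientific result, not a software defect.
- Published fast-scenario values are reproduced only as one point of an
  underdetermined family; exact per-parameter agreement with the printed
  tables is neither expected nor asserted.
- Curvature sigmas are conditional and scale-free (see above); treat them
  as diagnostics, not confidence intervals.
- Two printed source values are not exactly consistent with their own
  defining equations (a fast-scenario EC∞ of 2848 vs the 2844 that
  conservation yields; a fast k3 of 0.125 vs ~0.136 from the tie with the
  printed free rates). The package reproduces the equations and notes the
  discrepancies rather than special-casing the printed numbers.
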