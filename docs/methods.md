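# Methods

## Model

The population is clonal with two discrete phenotypes: drug-sensitive (A)
and drug-tolerant (B). Cells are structured by chronological age *a*
(ageing velocity 1), a cipher for the decay of intracellular signalling
factors. A parent of age *a* passes its phenotype to both daughters with
probability β_ii(a) = P*_ii + (Pmax_ii − P*_ii)e^(−σ_i a); the complement
switches. Phenotypes are fixed at birth; division (rate R_i) removes the
mother and injects two age-zero daughters through the renewal boundary
condition; death is a constant per-capita rate d_i, with the sensitive rate
elevated by drug through the saturable (Emax) law
d_A(t) = d_A + (d_Amax − d_A)·C/(C + C_half).

Growth laws: `malthusian` (R_i = r_i), `logistic`
(R_i = r_i·max(0, 1 − N/K), clamped at zero so event-handling overshoot
cannot produce negative rates), and the Allee variants, which multiply the
tolerant base rate by the cooperation factor

    f_n(θ) = (r_B + r_A θ^n) / (r_B (1 + θ^n)),       θ = B̄/Ā.

f_n rises from 1 (no tolerant cells) to r_A/r_B, so the boosted tolerant
rate r_B f_n interpolates between r_B and r_A. This Hill form is the unique
one under which both threshold identities below hold exactly; at Ā = 0 the
ratio is taken as +∞ and the saturated rate used, so trajectories that
drive sensitives extinct remain integrable.

Two thresholds follow in closed form (tested on randomized draws):
θ* = (−λ_B/λ_A)^(1/n) separates λ_B(θ) = r_B f_n(θ) − d_B < 0 from > 0
(exactly when d_A = d_B), and ϑ*_ε = [(εr_A − r_B)/(r_A(1 − ε))]^(1/n)
bounds the cooperation gain below a fraction ε ∈ (r_B/r_A, 1) of r_A.

## Exact ODE reduction and the transport solver

Because β_ii is a shifted exponential, integrating the transport equations
over age closes on five ODEs for (Ā, B̄, N_AA, N_BB, C), where
N_ii = ∫β_ii(a)·density da is the retention moment, sandwiched between
P*_ii·pop and Pmax_ii·pop. The reduction is exact; the `pde` module solves
the transport system directly as an independent cross-check. Its scheme is
aligned with characteristics (Δt = Δa, exact shift), applies the pointwise
survival factor, and fills the age-zero cell from the renewal integrals
(trapezoidal rule) *implicitly* — the newborn cell's own quadrature weight
enters a 2×2 linear solve — which removes the one-step boundary lag and
makes the observed convergence second order in Δa (≈0.05% disagreement with
the ODE solution at Δa = 0.25 h over 200 h). The age grid is truncated at
20 e-folding lengths of the slowest stable profile, whose decay rate is
λ_P + d_i + r_i (not d_i + r_i: for shrinking populations the profile is
much flatter), floored at 1e−3 h⁻¹.

Time units are hours everywhere internally; day-based quantities are
converted at the interfaces. Doses are carried in units of C_half·Vol, the
only combination entering the pharmacodynamics; the infusion duration
T_admin defaults to 1 h. PK trajectories use the piecewise closed form of
the linear clearance ODE (superposition over administrations), so dosing
never requires solver event detection; the reduced system is integrated
with LSODA at rtol 1e−8 with dose/infusion edges as hard breakpoints.

## Fitness analytics

In the Malthusian regime the reduced system is linear. In the pool
coordinates (N_AA, Ā − N_AA, N_BB, B̄ − N_BB) the generator is Metzler, so
the Malthusian parameter λ_P is its real dominant eigenvalue with a
nonnegative eigenvector (power iteration is the fallback for reducible,
no-switching cases). The next-generation split J = F + V, with F holding
every birth term (the 2R_i fluxes and their Pmax-weighted images in the
retention pools), gives R0 = ρ(F(−V)⁻¹) and the classic sign relation
sign(λ_P) = sign(R0 − 1), verified on 1000 random draws. For Allee modes
the nonlinear eigenproblem (generator evaluated at f_n(θ), eigenvector
ratio equal to θ) can be bistable; the solver returns the *smallest* fixed
point — the state reached when a population is expanded from a
sensitive-dominated seed — by a bracketing scan and Brent refinement.

Under periodic dosing the generator is time-periodic through d_A(C_ss(t)),
with C_ss the periodic steady-state concentration. The per-period growth
factor ρ is the dominant Floquet multiplier of the 4×4 fundamental system,
integrated once per period at rtol 1e−10; the tumour decays iff ρ < 1, an
operational treated reproduction-number criterion. The minimal
growth-reversing dose is found by bisection on ρ(dose) = 1 (relative
tolerance 1e−6); a companion helper reports λ_A − λ_A*, the drug-reversible
part of the sensitive growth rate that scales the analytic minimal dose.

## Treatment scheduling

`run_periodic` doses unconditionally; `run_informed` doses at times nT only
while θ < θ* (strict inequality; θ = ∞ when sensitives are extinct skips
and is flagged). Decision times are exactly nT from the window start with θ
evaluated just before dosing. `select_period` scans T = 1…7 days, assigns
each period the Floquet-minimal dose inflated by a safety factor (default
2.0) and capped at D_MTD·T/7 so the cumulative dose never exceeds the
weekly maximally tolerated schedule (D_MTD defaults to 1.5× the minimal
weekly-effective dose), and returns the largest T with sustained decay and
no established resistance. The safety factor exists because the exact
ρ = 1 dose only stalls growth, and cooperation at the realized θ (≈0.5 in
the docetaxel-style runs) slows decay further; the analytic sufficient-
condition dose it stands in for is likewise conservative. Operational
definitions (the underlying sources give none numerically): *sustained
decay* = N(window end) < N(treatment start) and negative log-slope over the
final 30 days; *resistance established* = over the final 20% of the dosing
window, median θ > θ* and nonnegative log-N slope while dosing continues.
Burden is the trapezoidal time-average of N/K over the window.

## Fitting and the synthetic assay generator

The generator emulates spheroid growth assays: counts on days 1, 3, 5, 7
(design configurable), untreated or bathed in a constant lethal drug from
72 h (modelled as a step of d_A to d_Amax — the bath saturates the effect,
so no PK enters the fit), with mean-preserving multiplicative lognormal
noise at CV 10% by default. Plating composition is the stable
exponential-growth eigenvector by default ("eigen"); a sorted
pure-sensitive plating ("sensitive") is available and, when used, the
series starts at t = 0. The generator and the fitting forward model share
one code path, so noiseless data is refit to machine precision.

Fitting conventions: P*_AA = 0, Pmax_AA = 0.95, σ_A = σ_B = 1e−2 h⁻¹,
d_A = d_B, and r_B ≤ r_A enforced by fitting the ratio r_B/r_A (the
retention pair is fitted as p_min plus a gap fraction). The objective is
the raw squared count error summed jointly over untreated and treated
series; optimization is bounded trust-region least squares from
Latin-hypercube multistarts (15 by default), with division/death rates
capped at 0.2 h⁻¹ on biological-plausibility grounds. Cross-drug refits
freeze the growth parameters and re-estimate only (d_Amax, P*_BB,
Pmax_BB). `classify_strategy` compares strategy-pinned fits under the
lognormal likelihood (squared log-count error) with a one-sided margin
favouring switch on ties (see below).

### Identifiability of the printed assay design

Three structural findings, each reproduced by the test suite:

1. With eigen plating the untreated series is an exact single exponential
   (the population starts on the eigenvector), leaving an exact ridge in
   (r_A, r_B, d, d_Amax): fits reach zero residual with λ_A off by >20%.
   Only composites (λ_P, fall rate, rebound rate, amplitudes) are
   identified. The recovery study therefore treats the shared death rate
   as known — it is measurable independently by a viability assay — and
   the switching strategy as given; under those conditions the median λ_A
   error at 10% noise (triplicate wells, 20 replicates) is ≈2–5%. λ_A*
   remains saturation-limited (the bath drives sensitives essentially
   extinct between two observation days, so the data only bound the kill
   rate from below) with median errors ≈30%.
2. Untreated-only data cannot distinguish the switch from the stay
   retention strategy (objective gap ≈1e−13), while parameter sets that
   explain the untreated data equally well under the two strategies make
   treated predictions differing by ~100% at day 7 — treatment response
   carries the strategy information.
3. A forced binary switch-vs-stay classification from total counts at 10%
   noise is nonetheless weakly powered: the stay parameterization can
   reproduce every switch-generated N(t) curve exactly (the converse is
   blocked by the r_B ≤ r_A bound), so wrong-strategy refits reach the
   optimizer floor and classification of switch truths is decided by
   noise. The margin rule keeps switch truths correct but stay truths are
   still mimicked in roughly half the replicates; the standing study
   reports ≈55–75% accuracy, and the corresponding validation test is
   expected to fail until richer observables (e.g. sorted subpopulation
   counts or post-washout resensitisation) are added to the design.

## Scenario parameter sets

All named scenarios are synthetic stand-ins chosen once to lie in the
regimes the analyses assume; none are fitted to data. The generic set
(`switch`/`stay`/`symmetric`; r_A = 0.035, r_B = 0.018, d_A = d_B = 0.02,
d_Amax = 0.08 h⁻¹, K = 1e6, n = 2, dose 50 every 21 days between days 50
and 275, drug half-life 6 h) uses equal death rates with the tolerance
cost entirely on r_B: at a cooperation-saturated tolerant-dominated state
both phenotypes then have equal base fitness and the switching-leak
asymmetry alone decides which composition is stable — the mechanism that
makes resistance transient for the switch strategy and permanent for the
stay strategy. The docetaxel-style sets (`wt_like`: r_A = 0.07,
r_B = 0.005, d = 0.04, d_Amax = 0.15; `m1_like`: r_A = 0.08, r_B = 0.004,
d = 0.045, d_Amax = 0.20; retention (0.2, 0.8); n = 1; half-life 11 h) are
high-turnover sets satisfying |λ_B| > λ_A, so θ* > 1 exceeds the stable
ratio and the adaptive gate starts open, as the scheduling analysis
requires. The fitting-study truth is a separate Malthusian set
(r_A = 0.05, r_B = 0.03, d = 0.015, d_Amax = 0.12) whose tolerant pool
persists (λ_B > 0) so the bath produces the fall-then-rebound response.

What passing tests show — and do not show — about real data: the
generator reproduces the deterministic mean structure and multiplicative
count noise of the emulated assays, but not well-to-well growth-rate
variability, counting saturation, spheroid geometry or measurement
drop-out; recovery results are therefore best-case statements about the
design, not about any particular instrument.

## Study sizes and numerical conventions

Validation studies run at frozen sizes: 1000 draws for the algebraic
identities, 5 draws for the transport cross-check (200 h, Δa = 0.25 h), 20
replicates for the fitting studies, 15 draws for dose monotonicity;
therapy comparisons use a 100-day treatment window from day 50 at
n0 = 1e5 cells, K = 1e6. Integrator tolerances: rtol 1e−8 (trajectories),
1e−10 (monodromy); absolute tolerances scaled to the initial population.
Eigen ties are broken by largest real part, then largest modulus.
Negative-value clipping is applied to reported states only, never fed back
into the integrator.

Known limitations: no stochastic (finite-population) simulation, so
extinction is asymptotic rather than actual; single drug, no toxicity
model; the treated reproduction criterion ignores cooperation (hence the
scheduler's safety factor); and the classification limits described above.
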