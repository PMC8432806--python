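"""Direct solver for the age-structured transport model.

Serves as an independent cross-check of the reduced ODE system (the
reduction is exact, so any disagreement is discretization error) and
exposes the age densities themselves, e.g. the stable age distribution.

The scheme follows characteristics: cells age at unit velocity, so with
time step equal to the age step (dt = da) the advection is an exact shift
of the density array, followed by the pointwise survival factor
exp(-[d_i(+drug) + R_i] dt) and the renewal boundary fill at age zero,

    A(t, 0) = 2 int [R_A beta_AA A + R_B (1 - beta_BB) B] da,
    B(t, 0) = 2 int [R_A (1 - beta_AA) A + R_B beta_BB B] da,

evaluated by the trapezoidal rule.  First order in da.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import ModelParams, reproduction_rate, switching_probability
from .pkpd import PKParams, DoseSchedule, concentration, treated_death_rate

__all__ = ["AgeDensity", "default_a_max", "stable_profile_density", "pde_step",
           "simulate_pde", "age_profile"]


@dataclass
class AgeDensity:
    """Per-phenotype cell density (cells per unit age) on a uniform age grid."""

    ages: np.ndarray
    density_A: np.ndarray
    density_B: np.ndarray

    @property
    def da(self) -> float:
        return float(self.ages[1] - self.ages[0])

    @property
    def abar(self) -> float:
        return float(np.trapezoid(self.density_A, self.ages))

    @property
    def bbar(self) -> float:
        return float(np.trapezoid(self.density_B, self.ages))

    def copy(self) -> "AgeDensity":
        return AgeDensity(self.ages, self.density_A.copy(), self.density_B.copy())


def default_a_max(params: ModelParams) -> float:
    """Age-grid truncation: ~20 e-folding lengths of the slowest stable
    age profile.  The profile of phenotype i decays at lambda_P + d_i +
    r_i, which for a shrinking population is much slower than the naive
    residence rate d_i + r_i."""
    from .fitness import malthusian_parameter

    lam_p = malthusian_parameter(params)
    mu = min(lam_p + params.d_A + params.r_A, lam_p + params.d_B + params.r_B)
    mu = max(mu, 1e-3)  # cap the grid for pathological near-flat profiles
    return 20.0 / mu


def stable_profile_density(params: ModelParams, n0: float, da: float = 0.25,
                           a_max: Optional[float] = None) -> AgeDensity:
    """Initial densities of a population in steady exponential growth.

    Along characteristics the stable age profile of phenotype i decays as
    exp(-(lambda_P + d_i + r_i) a); each profile is normalized so the age
    integrals reproduce the eigen-mode split of n0.
    """
    from .fitness import malthusian_parameter
    from .ode import initial_state

    if a_max is None:
        a_max = default_a_max(params)
    ages = np.arange(0.0, a_max + 0.5 * da, da)
    lam_p = malthusian_parameter(params)
    y0 = initial_state(params, n0)
    prof_A = np.exp(-(lam_p + params.d_A + params.r_A) * ages)
    prof_B = np.exp(-(lam_p + params.d_B + params.r_B) * ages)
    dens_A = y0.abar * prof_A / np.trapezoid(prof_A, ages)
    dens_B = y0.bbar * prof_B / np.trapezoid(prof_B, ages) if y0.bbar > 0 else 0.0 * ages
    return AgeDensity(ages, dens_A, dens_B)


def pde_step(density: AgeDensity, dt: float, params: ModelParams,
             delta_A: Optional[float] = None) -> AgeDensity:
    """Advance the densities by one characteristics-aligned step.

    Requires dt == da (unit ageing velocity); `delta_A` is the (possibly
    drug-elevated) sensitive death rate over the step.
    """
    if abs(dt - density.da) > 1e-12 * max(dt, density.da):
        raise ValueError("characteristics scheme requires dt == da")
    ages, A, B = density.ages, density.density_A, density.density_B
    abar, bbar = density.abar, density.bbar
    R_A = reproduction_rate("A", abar, bbar, params)
    R_B = reproduction_rate("B", abar, bbar, params)
    dA = params.d_A if delta_A is None else delta_A

    beta_AA = switching_probability(params.strategy_A, ages)
    beta_BB = switching_probability(params.strategy_B, ages)

    surv_A = np.exp(-(dA + R_A) * dt)
    surv_B = np.exp(-(params.d_B + R_B) * dt)
    new_A = np.empty_like(A)
    new_B = np.empty_like(B)
    new_A[1:] = A[:-1] * surv_A
    new_B[1:] = B[:-1] * surv_B
    new_A[0] = 0.0
    new_B[0] = 0.0

    # Renewal boundary at the new time level, solved implicitly: the
    # age-zero cell itself carries trapezoid weight da/2 in the integral,
    # giving a 2x2 linear system for (A0, B0).
    da = density.da
    s_A = 2.0 * np.trapezoid(R_A * beta_AA * new_A + R_B * (1.0 - beta_BB) * new_B, ages)
    s_B = 2.0 * np.trapezoid(R_A * (1.0 - beta_AA) * new_A + R_B * beta_BB * new_B, ages)
    baa0, bbb0 = beta_AA[0], beta_BB[0]
    m = np.array([[1.0 - da * R_A * baa0, -da * R_B * (1.0 - bbb0)],
                  [-da * R_A * (1.0 - baa0), 1.0 - da * R_B * bbb0]])
    new_A[0], new_B[0] = np.linalg.solve(m, [s_A, s_B])
    return AgeDensity(ages, new_A, new_B)


def simulate_pde(params: ModelParams, pk: Optional[PKParams] = None,
                 schedule: Optional[DoseSchedule] = None,
                 t_span: Sequence[float] = (0.0, 200.0), n0: float = 1e4,
                 da: float = 0.25, a_max: Optional[float] = None,
                 density0: Optional[AgeDensity] = None,
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, AgeDensity]:
    """March the transport model over `t_span` (hours).

    Returns (times, Abar(t), Bbar(t), final AgeDensity).  The drug
    concentration along the way comes from the closed-form PK solution.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    n_steps = int(round((t1 - t0) / da))
    times = t0 + da * np.arange(n_steps + 1)
    dens = density0.copy() if density0 is not None else stable_profile_density(
        params, n0, da=da, a_max=a_max)
    if pk is not None and schedule is not None and schedule.times:
        c_t = concentration(pk, schedule, times)
    else:
        c_t = np.zeros_like(times)

    abars = np.empty(n_steps + 1)
    bbars = np.empty(n_steps + 1)
    abars[0], bbars[0] = dens.abar, dens.bbar
    for k in range(n_steps):
        delta = (treated_death_rate(params.d_A, params.d_A_max, c_t[k], pk.c_half)
                 if pk is not None else None)
        dens = pde_step(dens, da, params, delta_A=delta)
        abars[k + 1], bbars[k + 1] = dens.abar, dens.bbar
    return times, abars, bbars, dens


def age_profile(density: AgeDensity) -> dict:
    """Per-phenotype age densities normalized to unit mass.

    At stationarity in the Malthusian regime the log-profile is affine in
    age with slope -(lambda_P + d_i + r_i).
    """
    out = {"ages": density.ages.copy()}
    for key, dens in (("A", density.density_A), ("B", density.density_B)):
        tot = np.trapezoid(dens, density.ages)
        out[f"profile_{key}"] = dens / tot if tot > 0 else dens * 0.0
    return out
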