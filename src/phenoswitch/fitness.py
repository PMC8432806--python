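"""Population-fitness analytics for the switching model.

In the unlimited-resource (Malthusian) regime the reduced model is linear
in (Abar, Bbar, N_AA, N_BB).  In the transformed coordinates
(N_AA, Abar - N_AA, N_BB, Bbar - N_BB) — the retaining and switching
sub-pools of each phenotype — the generator is Metzler (nonnegative
off-diagonal), so the dominant eigenvalue, the Malthusian parameter
lambda_P, is real with a nonnegative eigenvector, and the next-generation
split J = F + V (F collecting every birth term, the entries carrying the
factor 2 R_i) yields a basic reproduction number R0 = rho(F (-V)^{-1})
obeying the classic sign relation sign(lambda_P) = sign(R0 - 1).

Under periodic dosing the generator becomes time-periodic; its Floquet
(monodromy) multiplier rho over one period plays the role of a treated
per-period reproduction number: the tumour decays iff rho < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model import ModelParams, cooperation_factor
from .pkpd import PKParams, periodic_steady_concentration, treated_death_rate

__all__ = [
    "linear_generator",
    "malthusian_parameter",
    "malthusian_parameter_allee",
    "basic_reproduction_number",
    "stable_structure",
    "sensitive_fraction_stable",
    "sensitive_fraction_limited",
    "treated_period_multiplier",
    "min_effective_dose",
    "dose_scale_reference",
    "DoseResult",
    "fitness_report",
]

# Transform from pool coordinates u = (N_AA, Abar-N_AA, N_BB, Bbar-N_BB)
# back to (Abar, Bbar, N_AA, N_BB).
_FROM_POOLS = np.array([
    [1.0, 1.0, 0.0, 0.0],
    [0.0, 0.0, 1.0, 1.0],
    [1.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 1.0, 0.0],
])


def _generator_pools(params: ModelParams, delta_A: Optional[float] = None,
                     f_B: float = 1.0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Metzler generator J, birth part F and remainder V = J - F in the
    retaining/switching pool coordinates, at fixed sensitive death rate
    `delta_A` (default untreated d_A) and tolerant-rate multiplier f_B."""
    sA, sB = params.strategy_A, params.strategy_B
    RA, RB = params.r_A, params.r_B * f_B
    dA = params.d_A if delta_A is None else delta_A
    dB = params.d_B
    F = np.array([
        [2 * RA * sA.p_max, 0.0, 0.0, 2 * RB * sA.p_max],
        [2 * RA * (1 - sA.p_max), 0.0, 0.0, 2 * RB * (1 - sA.p_max)],
        [0.0, 2 * RA * sB.p_max, 2 * RB * sB.p_max, 0.0],
        [0.0, 2 * RA * (1 - sB.p_max), 2 * RB * (1 - sB.p_max), 0.0],
    ])
    V = np.array([
        [-(RA + dA) - sA.sigma * (1 - sA.p_min), sA.sigma * sA.p_min, 0.0, 0.0],
        [sA.sigma * (1 - sA.p_min), -(RA + dA) - sA.sigma * sA.p_min, 0.0, 0.0],
        [0.0, 0.0, -(RB + dB) - sB.sigma * (1 - sB.p_min), sB.sigma * sB.p_min],
        [0.0, 0.0, sB.sigma * (1 - sB.p_min), -(RB + dB) - sB.sigma * sB.p_min],
    ])
    return F + V, F, V


def linear_generator(params: ModelParams, delta_A: Optional[float] = None,
                     f_B: float = 1.0) -> np.ndarray:
    """4x4 rate matrix of the linearized model over (Abar, Bbar, N_AA, N_BB)."""
    J_u, _, _ = _generator_pools(params, delta_A, f_B)
    T = _FROM_POOLS
    return T @ J_u @ np.linalg.inv(T)


def _dominant_eig(J_u: np.ndarray) -> Tuple[float, np.ndarray]:
    """Dominant (Perron) eigenvalue and nonnegative eigenvector of a
    Metzler matrix; falls back to power iteration on reducible cases."""
    vals, vecs = np.linalg.eig(J_u)
    order = np.lexsort((-np.abs(vals), -vals.real))
    lam = vals[order[0]]
    v = vecs[:, order[0]].real
    if v.sum() < 0:
        v = -v
    if np.min(v) < -1e-8 * max(np.max(np.abs(v)), 1e-300):
        # Reducible generator: Perron vector via power iteration on the
        # nonnegative shift J_u + s I.
        s = float(np.max(-np.diag(J_u))) + 1.0
        M = J_u + s * np.eye(4)
        v = np.full(4, 0.25)
        for _ in range(200000):
            w = M @ v
            nrm = np.linalg.norm(w)
            if nrm == 0:
                break
            w /= nrm
            if np.linalg.norm(w - v) < 1e-14:
                v = w
                break
            v = w
        lam = float(v @ (J_u @ v) / (v @ v))
    v = np.clip(v, 0.0, None)
    return float(np.real(lam)), v


def malthusian_parameter(params: ModelParams) -> float:
    """Intrinsic exponential growth rate lambda_P of the mixed population.

    Dominant eigenvalue of the untreated linear generator; real by the
    Metzler structure.  For a plastic population it lies strictly between
    lambda_B and lambda_A; with no switching (both strategies (1, 1)) it is
    max(lambda_A, lambda_B).
    """
    lam, _ = _dominant_eig(_generator_pools(params)[0])
    return lam


def stable_structure(params: ModelParams) -> np.ndarray:
    """Stable exponential-growth composition (Abar, Bbar, N_AA, N_BB)
    normalized to Abar + Bbar = 1.

    For Allee growth modes the self-consistent cooperation-adjusted
    eigenproblem is solved first.
    """
    if params.growth.is_allee:
        _, theta_hat = malthusian_parameter_allee(params)
        f_B = cooperation_factor(theta_hat, params.growth.n, params.r_A, params.r_B)
    else:
        f_B = 1.0
    _, u = _dominant_eig(_generator_pools(params, f_B=f_B)[0])
    y = _FROM_POOLS @ u
    tot = y[0] + y[1]
    if tot <= 0:
        raise RuntimeError("degenerate dominant eigenvector")
    return y / tot


def malthusian_parameter_allee(params: ModelParams, tol: float = 1e-10,
                               theta_max: float = 1e9) -> Tuple[float, float]:
    """Growth rate and self-consistent ratio theta of cooperation-boosted
    exponential growth.

    The generator evaluated with the tolerant rate scaled by f_n(theta)
    has a dominant eigenvector whose Bbar/Abar ratio g(theta) must equal
    theta.  Cooperation can make the problem bistable (a sensitive- and a
    tolerant-dominated branch); the smallest fixed point is returned — the
    state a population reaches when expanded from a sensitive-dominated
    seed — located by a bracketing scan and Brent refinement.  If g stays
    above theta everywhere the population is tolerant-dominated and the
    saturated (f_n -> r_A/r_B) generator applies.
    """
    from scipy.optimize import brentq

    if not params.growth.is_allee:
        raise ValueError("requires an Allee growth mode")
    n = params.growth.n

    def ratio(theta: float) -> float:
        f_B = cooperation_factor(theta, n, params.r_A, params.r_B)
        _, u = _dominant_eig(_generator_pools(params, f_B=f_B)[0])
        y = _FROM_POOLS @ u
        return 1e12 if y[0] <= 0 else min(y[1] / y[0], 1e12)

    def excess(theta: float) -> float:
        return ratio(theta) - theta

    if excess(0.0) <= 0.0:
        theta_hat = 0.0
    else:
        grid = np.concatenate([[0.0], np.geomspace(1e-6, theta_max, 200)])
        theta_hat = None
        for a, b in zip(grid[:-1], grid[1:]):
            if excess(b) <= 0.0:
                theta_hat = brentq(excess, a, b, xtol=tol)
                break
    if theta_hat is None:
        # no crossing: tolerant-dominated, cooperation saturated
        theta_hat = math.inf
        f_B = params.r_A / params.r_B
    else:
        f_B = cooperation_factor(theta_hat, n, params.r_A, params.r_B)
    lam, _ = _dominant_eig(_generator_pools(params, f_B=f_B)[0])
    return lam, theta_hat


def basic_reproduction_number(params: ModelParams) -> float:
    """Expected offspring per cell, R0 = rho(F (-V)^{-1}).

    F collects every birth flux (the 2 R_i terms, including their
    p_max-weighted images in the retention pools) and V the remaining
    transition/loss terms.  sign(lambda_P) = sign(R0 - 1).
    """
    _, F, V = _generator_pools(params)
    if min(params.r_A + params.d_A, params.r_B + params.d_B) <= 0:
        raise ValueError("R0 requires positive loss rates (r_i + d_i > 0)")
    ngm = F @ np.linalg.inv(-V)
    vals = np.linalg.eigvals(ngm)
    return float(np.max(np.abs(vals)))


def sensitive_fraction_stable(params: ModelParams) -> float:
    """Sensitive share Abar/(Abar+Bbar) of the stable age distribution."""
    y = stable_structure(params)
    return float(y[0])


def sensitive_fraction_limited(params: ModelParams, horizon_days: float = 500.0,
                               n0: float = 1e3, **sim_kw) -> float:
    """Sensitive share at the horizon of a resource-limited simulation."""
    if not params.growth.is_logistic:
        raise ValueError("requires a logistic growth mode")
    from .ode import simulate

    traj = simulate(params, t_span=(0.0, horizon_days * 24.0), n0=n0, **sim_kw)
    final = traj.final_state()
    return float(final.abar / (final.abar + final.bbar))


def treated_period_multiplier(params: ModelParams, pk: PKParams, dose: float,
                              period: float, rtol: float = 1e-10) -> float:
    """Floquet multiplier rho of the linear model under periodic dosing.

    Integrates the 4x4 fundamental system over one period (hours) of the
    periodic steady-state drug concentration; the tumour decays in the
    periodic environment iff rho < 1 — an operational treated R0* < 1
    criterion.
    """
    if period <= 0:
        raise ValueError("period must be > 0")

    def fundamental_rhs(t, phi_flat):
        c = periodic_steady_concentration(pk, dose, period, t % period)
        delta = treated_death_rate(params.d_A, params.d_A_max, c, pk.c_half)
        J_u, _, _ = _generator_pools(params, delta_A=delta)
        return (J_u @ phi_flat.reshape(4, 4)).ravel()

    phi = np.eye(4).ravel()
    # The concentration profile has a kink at the end of the infusion.
    edges = [0.0, min(pk.t_admin, period), period]
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        sol = solve_ivp(fundamental_rhs, (a, b), phi, method="LSODA",
                        rtol=rtol, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"monodromy integration failed: {sol.message}")
        phi = sol.y[:, -1]
    vals = np.linalg.eigvals(phi.reshape(4, 4))
    return float(np.max(np.abs(vals)))


def dose_scale_reference(params: ModelParams) -> float:
    """Companion quantity lambda_A - lambda_A*: the drug-reversible part of
    the sensitive growth rate, the numerator of the closed-form minimal
    dose."""
    return params.lambda_A - params.lambda_A_star


@dataclass(frozen=True)
class DoseResult:
    """Outcome of the minimal-dose search."""

    dose: float
    feasible: bool
    capped: bool
    rho: float
    period: float


def min_effective_dose(params: ModelParams, pk: PKParams, period: float,
                       cap: float = 1e4, rel_tol: float = 1e-6) -> DoseResult:
    """Smallest per-period dose driving the Floquet multiplier to 1.

    Bisection on rho(dose) = 1 to relative tolerance `rel_tol`; returns the
    cap (flagged) if even the capped dose cannot reverse growth, and dose 0
    if the untreated population already decays.  `period` in hours, dose in
    c_half*vol units.
    """
    rho0 = treated_period_multiplier(params, pk, 0.0, period)
    if rho0 <= 1.0:
        return DoseResult(0.0, True, False, rho0, period)
    rho_cap = treated_period_multiplier(params, pk, cap, period)
    if rho_cap >= 1.0:
        return DoseResult(cap, False, True, rho_cap, period)
    lo, hi = 0.0, cap
    while hi - lo > rel_tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if treated_period_multiplier(params, pk, mid, period) >= 1.0:
            lo = mid
        else:
            hi = mid
    dose = hi
    return DoseResult(dose, True, False,
                      treated_period_multiplier(params, pk, dose, period), period)


def fitness_report(params: ModelParams, pk: Optional[PKParams] = None,
                   periods_days: Tuple[float, ...] = ()) -> dict:
    """Scalar fitness summary (JSON-serializable)."""
    report = {
        "lambda_A": params.lambda_A,
        "lambda_B": params.lambda_B,
        "lambda_A_star": params.lambda_A_star,
        "lambda_P": malthusian_parameter(params.replace(
            growth=params.growth.__class__(mode="malthusian"))),
        "R0": basic_reproduction_number(params),
        "sensitive_fraction": sensitive_fraction_stable(params.replace(
            growth=params.growth.__class__(mode="malthusian"))),
    }
    if params.lambda_B < 0 < params.lambda_A:
        from .model import theta_star

        report["theta_star"] = theta_star(params)
    if pk is not None and periods_days:
        report["min_dose_per_period"] = {
            str(T): min_effective_dose(params, pk, T * 24.0).dose for T in periods_days
        }
    return report
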