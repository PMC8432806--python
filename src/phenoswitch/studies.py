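"""Reproducible validation studies.

Each function runs one self-contained numerical experiment at a frozen
design — the study sizes (replicates, draws, grids) are the package's
validation conventions — and returns plain dictionaries of summary
numbers.  The test suite and the acceptance script both drive these.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datasets import AssayDesign, generate, generic_protocol, scenario, scenario_pk
from .fitness import (
    basic_reproduction_number, malthusian_parameter, min_effective_dose,
    treated_period_multiplier,
)
from .fitting import classify_strategy, fit
from .model import GrowthLaw, ModelParams, SwitchingStrategy, cooperation_factor, \
    theta_epsilon_star, theta_star
from .ode import simulate
from .pde import simulate_pde
from .pkpd import PKParams
from .therapy import compare_burden, run_informed, run_periodic, select_period

HOURS = 24.0

# Frozen truth of the synthetic fitting studies: a fast-growing clonal
# line (doubling ~20 h) whose tolerant compartment persists (lambda_B > 0)
# so the constant bath produces the fall-then-rebound response.
STUDY_TRUTH = ModelParams(
    r_A=0.05, r_B=0.03, d_A=0.015, d_B=0.015, d_A_max=0.12,
    strategy_A=SwitchingStrategy(0.0, 0.95, 0.01),
    strategy_B=SwitchingStrategy(0.0, 0.9, 0.01),
    growth=GrowthLaw("malthusian"))


def _sub_seed(seed: Optional[int], k: int) -> Optional[int]:
    if seed is None:
        return None
    return int((seed * 1_000_003 + k) % (2 ** 31 - 1))


def informed_vs_periodic(name: str, window_days=(50.0, 150.0), n0: float = 1e5,
                         period_days: float = 3.0, safety: float = 2.0) -> dict:
    """Burden of theta-gated dosing relative to weekly periodic dosing at
    the maximally tolerated dose, over the same treatment window."""
    p, pk = scenario(name), scenario_pk(name)
    weekly = min_effective_dose(p, pk, 7.0 * HOURS)
    d_mtd = 1.5 * weekly.dose
    periodic = run_periodic(p, pk, d_mtd, 7.0, window_days=window_days, n0=n0,
                            horizon_days=window_days[1])
    dose = min(safety * min_effective_dose(p, pk, period_days * HOURS).dose,
               d_mtd * period_days / 7.0)
    informed = run_informed(p, pk, dose, period_days, window_days=window_days,
                            n0=n0, horizon_days=window_days[1])
    return {
        "burden_ratio": compare_burden(informed, periodic, window_days=window_days),
        "burden_informed": informed.burden,
        "burden_periodic": periodic.burden,
        "doses_given": len(informed.doses_given),
        "doses_skipped": len(informed.doses_skipped),
        "informed_resistance": informed.resistance,
    }


def period_selection(name: str = "wt_like", window_days=(50.0, 150.0),
                     n0: float = 1e5) -> dict:
    sel = select_period(scenario(name), scenario_pk(name),
                        window_days=window_days, n0=n0,
                        horizon_days=window_days[1])
    return {"chosen_T": sel.chosen_T, "dose": sel.dose,
            "per_period": sel.per_period}


def strategy_persistence() -> dict:
    """Sensitive-fraction extremes of the generic 21-day cyclic protocol."""
    proto = generic_protocol()
    out = {}
    for name in ("switch", "stay"):
        res = run_periodic(scenario(name), scenario_pk(name), **proto)
        tr = res.trajectory
        w = ((tr.times >= proto["window_days"][0] * HOURS)
             & (tr.times <= proto["window_days"][1] * HOURS))
        frac = tr.abar / np.maximum(tr.n_total, 1e-300)
        out[name] = {"min_sensitive_fraction": float(np.min(frac[w])),
                     "final_sensitive_fraction": float(frac[-1]),
                     "resistance": res.resistance}
    return out


def ode_pde_agreement(seed: Optional[int] = None, n_draws: int = 5,
                      t_end: float = 200.0, da: float = 0.25) -> dict:
    """Worst relative disagreement between the transport solver and the
    reduced ODE system over random Malthusian parameter draws."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    worst = 0.0
    for _ in range(n_draws):
        p = _random_params(rng)
        times, a_pde, b_pde, _ = simulate_pde(p, t_span=(0, t_end), n0=1e4, da=da)
        traj = simulate(p, t_span=(0, t_end), n0=1e4)
        a_ode = np.interp(times, traj.times, traj.abar)
        b_ode = np.interp(times, traj.times, traj.bbar)
        n_tot = a_ode + b_ode
        err = max(np.max(np.abs(a_ode - a_pde) / a_ode),
                  np.max(np.abs(b_ode - b_pde) / n_tot))
        worst = max(worst, float(err))
    return {"max_rel_error": worst, "n_draws": n_draws}


def _random_params(rng, plastic=True) -> ModelParams:
    r_A = rng.uniform(0.01, 0.1)
    r_B = rng.uniform(0.2, 1.0) * r_A

    def strat():
        p_min = rng.uniform(0.0, 0.9)
        p_max = min(rng.uniform(p_min, 1.0), 0.999)
        return SwitchingStrategy(p_min, p_max, rng.uniform(1e-3, 0.1))

    return ModelParams(r_A=r_A, r_B=r_B, d_A=rng.uniform(0.0, 0.08),
                       d_B=rng.uniform(0.0, 0.08),
                       d_A_max=rng.uniform(0.1, 0.3),
                       strategy_A=strat(), strategy_B=strat(),
                       growth=GrowthLaw("malthusian"))


def fitness_identities(seed: Optional[int] = None, n_draws: int = 1000) -> dict:
    """lambda_P bounds, the no-switching maximum rule and the
    sign(lambda_P) = sign(R0 - 1) relation over random draws."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    bound_viol = sign_viol = 0
    max_rule_err = 0.0
    for _ in range(n_draws):
        p = _random_params(rng)
        lam = malthusian_parameter(p)
        lo, hi = sorted((p.lambda_A, p.lambda_B))
        if not (lo - 1e-9 <= lam <= hi + 1e-9):
            bound_viol += 1
        r0 = basic_reproduction_number(p)
        if abs(lam) > 1e-12 and np.sign(lam) != np.sign(r0 - 1.0):
            sign_viol += 1
        locked = SwitchingStrategy(1.0, 1.0, 0.01)
        p_ns = p.replace(strategy_A=locked, strategy_B=locked)
        max_rule_err = max(max_rule_err,
                           abs(malthusian_parameter(p_ns) - hi))
    return {"bound_violations": bound_viol, "sign_violations": sign_viol,
            "no_switching_max_rule_max_abs_err": max_rule_err,
            "n_draws": n_draws}


def threshold_identities(seed: Optional[int] = None, n_draws: int = 1000) -> dict:
    """Closed-loop check of the theta* and theta*_eps inequalities."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    violations = 0
    for _ in range(n_draws):
        r_A = rng.uniform(0.02, 0.1)
        r_B = rng.uniform(0.1, 0.99) * r_A
        d = rng.uniform(r_B + 1e-4, r_A - 1e-4)
        n = rng.uniform(1.0, 8.0)
        p = ModelParams(r_A=r_A, r_B=r_B, d_A=d, d_B=d, d_A_max=d + 0.1,
                        strategy_A=SwitchingStrategy(0.0, 0.95, 0.01),
                        strategy_B=SwitchingStrategy(0.0, 0.9, 0.01),
                        growth=GrowthLaw("malthusian_allee", n=n))
        ts = theta_star(p)
        eps = rng.uniform(r_B / r_A + 1e-6, 1 - 1e-6)
        te = theta_epsilon_star(p, eps)
        for f_ in (0.5, 0.9, 1.1, 2.0):
            lam_b = r_B * cooperation_factor(ts * f_, n, r_A, r_B) - d
            if (lam_b < 0) != (f_ < 1.0):
                violations += 1
            gain = r_B * cooperation_factor(te * f_, n, r_A, r_B)
            if (gain < eps * r_A) != (f_ < 1.0):
                violations += 1
    return {"violations": violations, "n_draws": n_draws}


def parameter_recovery(seed: Optional[int] = None, n_replicates: int = 20) -> dict:
    """Growth-rate recovery from noisy synthetic assays.

    Study conditions: 10% lognormal count noise, triplicate wells on the
    standard day-{1,3,5,7} design, the switching strategy and the shared
    death rate known (the death rate is measurable independently and is
    unidentifiable jointly with the division rates from total counts).
    """
    truth = STUDY_TRUTH
    fx = {"strategy_B": truth.strategy_B, "d_A": truth.d_A}
    errs = []
    for rep in range(n_replicates):
        data = generate(truth, AssayDesign(cv=0.10, n_replicates=3),
                        seed=_sub_seed(seed, 100 + rep))
        res = fit(data, fixed=fx, seed=_sub_seed(seed, 200 + rep), n_starts=6)
        errs.append(abs(res.estimates["lambda_A"] - truth.lambda_A)
                    / truth.lambda_A)
    return {"median_rel_error": float(np.median(errs)),
            "worst_rel_error": float(np.max(errs)),
            "n_replicates": n_replicates}


def strategy_classification(seed: Optional[int] = None,
                            n_replicates: int = 20) -> dict:
    """Switch-vs-stay classification accuracy from treated + untreated
    assays at 10% noise (death rate known, high tolerant fitness truth)."""
    base = STUDY_TRUTH.replace(r_B=0.045)
    correct = 0
    for rep in range(n_replicates):
        lab = "switch" if rep % 2 == 0 else "stay"
        strat = (0.0, 0.9) if lab == "switch" else (0.95, 1.0)
        truth = base.replace(strategy_B=SwitchingStrategy(*strat, 0.01))
        data = generate(truth, AssayDesign(cv=0.10, n_replicates=3),
                        seed=_sub_seed(seed, 300 + rep))
        out = classify_strategy(data, seed=_sub_seed(seed, 400 + rep),
                                n_starts=4, fixed={"d_A": base.d_A})
        correct += out["label"] == lab
    return {"accuracy": correct / n_replicates, "n_replicates": n_replicates}


def untreated_only_indistinguishability(seed: Optional[int] = None) -> dict:
    """Relative objective gap between strategy-pinned fits to an
    untreated-only assay (practical non-identifiability)."""
    data = generate(STUDY_TRUTH,
                    AssayDesign(cv=0.10, conditions=("untreated",),
                                n_replicates=3),
                    seed=_sub_seed(seed, 500))
    fits = {}
    for lab, s in (("switch", (0.0, 0.9)), ("stay", (0.95, 1.0))):
        fits[lab] = fit(data,
                        fixed={"strategy_B": SwitchingStrategy(*s, 0.01)},
                        seed=_sub_seed(seed, 501), n_starts=5)
    lo = min(f.sse for f in fits.values())
    hi = max(f.sse for f in fits.values())
    return {"relative_gap": (hi - lo) / max(lo, 1e-300)}


def dose_bisection_check(seed: Optional[int] = None, n_draws: int = 15) -> dict:
    """Post-condition of the minimal-dose search and monotonicity of the
    Floquet multiplier in dose."""
    pk = PKParams(t_half=11.0)
    p_ref = scenario("wt_like")
    res = min_effective_dose(p_ref, pk, 72.0)
    rho_above = treated_period_multiplier(p_ref, pk, 1.01 * res.dose, 72.0)
    rng = np.random.default_rng(_sub_seed(seed, 4))
    mono_viol = 0
    for _ in range(n_draws):
        p = _random_params(rng)
        doses = [0.0, 0.5, 2.0, 8.0]
        rhos = [treated_period_multiplier(p, pk, d, 96.0) for d in doses]
        if not np.all(np.diff(rhos) < 0):
            mono_viol += 1
    return {"abs_rho_error": abs(res.rho - 1.0), "rho_above_below_one":
            bool(rho_above < 1.0), "monotonicity_violations": mono_viol,
            "n_draws": n_draws}


def sensitivity_structure() -> dict:
    """Finite-difference lambda_P sensitivities at lambda_A = lambda_B and
    the symmetry of the symmetric-strategy fitness surface."""
    def lam_p(lam_a, lam_b, strat_B, r_floor=0.05):
        r = r_floor + max(lam_a, lam_b, 0.0)
        p = ModelParams(r_A=r, r_B=r, d_A=r - lam_a, d_B=r - lam_b,
                        d_A_max=r - lam_a + 0.1,
                        strategy_A=SwitchingStrategy(0.9, 0.95, 0.01),
                        strategy_B=SwitchingStrategy(*strat_B, 0.01),
                        growth=GrowthLaw("malthusian"))
        return malthusian_parameter(p)

    lam0, h = 0.01, 1e-5
    out = {}
    for lab, strat in (("stay", (0.95, 1.0)), ("switch", (0.0, 0.9))):
        dA = (lam_p(lam0 + h, lam0, strat) - lam_p(lam0 - h, lam0, strat)) / (2 * h)
        dB = (lam_p(lam0, lam0 + h, strat) - lam_p(lam0, lam0 - h, strat)) / (2 * h)
        out[f"{lab}_sensitivity_ratio"] = dB / dA
    sym = (0.9, 0.95)
    asym = 0.0
    for la, lb in ((0.02, -0.01), (0.015, 0.005), (-0.005, 0.01)):
        asym = max(asym, abs(lam_p(la, lb, sym) - lam_p(lb, la, sym)))
    out["symmetric_surface_max_asymmetry"] = asym
    return out
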