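"""Least-squares parameter estimation from growth-assay time series.

Emulates the in-vitro protocol the model was built for: cell counts of a
clonal population on a few observation days, untreated and under a
constant lethal drug bath applied from t_treat onwards.  During fitting
the treated sensitive death rate is the step function d_A(t) = d_A for
t < t_treat and d_A_max afterwards (the bath saturates the effect), so no
pharmacokinetics enter the objective.

Conventions follow the assay fits: P*_AA = 0, Pmax_AA = 0.95,
sigma_A = sigma_B = 1e-2 h^-1, d_A = d_B, and the cost of tolerance
r_B <= r_A is enforced by fitting the ratio r_B / r_A.  The squared-error
objective sums (N(t_i) - Data_i)^2 jointly over all datasets; treated and
untreated conditions are fitted simultaneously because the switching
strategy is practically unidentifiable from untreated growth alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import GrowthLaw, ModelParams, SwitchingStrategy

__all__ = [
    "GrowthAssayDataset", "FitResult", "predicted_total", "sse", "fit",
    "refit_drug", "classify_strategy", "read_datasets", "write_datasets",
    "FIXED_SIGMA", "FIXED_STRATEGY_A",
]

FIXED_SIGMA = 1e-2  # h^-1, memory-decay rate fixed during fitting
FIXED_STRATEGY_A = SwitchingStrategy(0.0, 0.95, FIXED_SIGMA)


@dataclass(frozen=True)
class GrowthAssayDataset:
    """One growth-assay time series: counts at `times` (hours) under one
    condition ('untreated' or 'drug'); for the drug condition the constant
    lethal bath starts at `t_treat` (hours)."""

    times: tuple
    counts: tuple
    condition: str = "untreated"
    drug_name: str = ""
    t_treat: float = 72.0
    init: str = "eigen"  # composition at plating: "eigen" or "sensitive"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        counts = tuple(float(c) for c in self.counts)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if self.condition not in ("untreated", "drug"):
            raise ValueError("condition must be 'untreated' or 'drug'")
        if self.init not in ("eigen", "sensitive"):
            raise ValueError("init must be 'eigen' or 'sensitive'")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(c <= 0 for c in counts):
            raise ValueError("counts must be > 0")
        if self.condition == "drug" and not (0.0 <= self.t_treat <= times[-1]):
            raise ValueError("t_treat must lie within the observed window")


def read_datasets(path) -> list:
    """Read assay datasets from CSV with columns time_hours, count,
    condition, drug, t_treat_hours (one dataset per condition/drug pair)."""
    df = pd.read_csv(path)
    out = []
    for (cond, drug), grp in df.groupby(["condition", "drug"], dropna=False, sort=False):
        grp = grp.sort_values("time_hours")
        init = (str(grp["init"].iloc[0]) if "init" in grp.columns else "eigen")
        out.append(GrowthAssayDataset(
            tuple(grp["time_hours"]), tuple(grp["count"]), cond,
            "" if pd.isna(drug) else str(drug),
            float(grp["t_treat_hours"].iloc[0]), init))
    return out


def write_datasets(datasets: Sequence[GrowthAssayDataset], path) -> None:
    rows = []
    for ds in datasets:
        for t, c in zip(ds.times, ds.counts):
            rows.append({"time_hours": t, "count": c, "condition": ds.condition,
                         "drug": ds.drug_name, "t_treat_hours": ds.t_treat,
                         "init": ds.init})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- forward model ----------------------------------------------------------

def _predict_linear(params: ModelParams, t0: float, y0: np.ndarray,
                    times: np.ndarray, treat_at: Optional[float]) -> np.ndarray:
    """Matrix-exponential propagation of (Abar, Bbar, N_AA, N_BB) for
    Malthusian growth with (optionally) the step death rate at treat_at."""
    from .fitness import linear_generator

    J0 = linear_generator(params)
    J1 = linear_generator(params, delta_A=params.d_A_max) if treat_at is not None else None
    out = np.empty(len(times))
    for i, t in enumerate(times):
        if treat_at is None or t <= treat_at or t0 >= treat_at:
            J = J1 if (treat_at is not None and t0 >= treat_at) else J0
            y = expm(J * (t - t0)) @ y0
        else:
            y = expm(J1 * (t - treat_at)) @ (expm(J0 * (treat_at - t0)) @ y0)
        out[i] = y[0] + y[1]
    return out


def _predict_ode(params: ModelParams, t0: float, y0: np.ndarray,
                 times: np.ndarray, treat_at: Optional[float]) -> np.ndarray:
    from scipy.integrate import solve_ivp

    from .ode import rhs

    if treat_at is not None and t0 < treat_at < times[-1]:
        segs = [(t0, treat_at, params),
                (treat_at, times[-1], params.replace(d_A=params.d_A_max))]
    elif treat_at is not None and t0 >= treat_at:
        segs = [(t0, times[-1], params.replace(d_A=params.d_A_max))]
    else:
        segs = [(t0, times[-1], params)]
    y = np.append(np.asarray(y0, dtype=float), 0.0)
    preds = {t0: y[0] + y[1]}
    atol = 1e-9 * max(y[0] + y[1], 1.0)
    for a, b, pp in segs:
        t_eval = np.unique(np.concatenate([[b], times[(times > a) & (times <= b)]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method="LSODA",
                        rtol=1e-8, atol=atol, args=(pp, None, 0.0))
        if not sol.success:
            raise RuntimeError(f"prediction ODE failed: {sol.message}")
        for t, col in zip(sol.t, sol.y.T):
            preds[t] = col[0] + col[1]
        y = sol.y[:, -1]
    return np.array([preds[t] for t in times])


def predicted_total(params: ModelParams, dataset: GrowthAssayDataset,
                    structure: Optional[np.ndarray] = None) -> np.ndarray:
    """Model-predicted total count N(t_i) at the dataset's observation times.

    The population starts at the first observation on the stable
    exponential-growth (eigen) composition scaled to the first count --
    cells are expanded before plating, so the assay starts from a
    population with the steady-state phenotype split.  `structure` allows
    reuse of a precomputed eigen composition across datasets sharing the
    same parameters.
    """
    from .fitness import stable_structure

    times = np.asarray(dataset.times)
    t0 = times[0]
    if dataset.init == "sensitive":
        # freshly sorted drug-naive population: pure sensitive, retention
        # moment at the midpoint of its admissible band; the sorted
        # composition holds at plating, so the series must start there
        if t0 != 0.0:
            raise ValueError("sorted ('sensitive') datasets must include the"
                             " plating count at time 0")
        sA = params.strategy_A
        structure = np.array([1.0, 0.0, 0.5 * (sA.p_min + sA.p_max), 0.0])
    elif structure is None:
        structure = stable_structure(params)
    y0 = structure * dataset.counts[0]
    treat_at = dataset.t_treat if dataset.condition == "drug" else None
    if params.growth.mode == "malthusian":
        return _predict_linear(params, t0, y0, times, treat_at)
    return _predict_ode(params, t0, y0, times, treat_at)


def sse(params: ModelParams, datasets: Sequence[GrowthAssayDataset]) -> float:
    """Joint squared-error objective over all datasets."""
    total = 0.0
    for ds in datasets:
        resid = predicted_total(params, ds) - np.asarray(ds.counts)
        total += float(resid @ resid)
    return total


# -- optimization -----------------------------------------------------------

_FREE_NAMES = ("r_A", "rb_frac", "d_A", "dmax_frac", "p_min_BB", "gap_frac")


def _build_params(x_full: dict, growth: GrowthLaw) -> ModelParams:
    r_A = x_full["r_A"]
    r_B = x_full["rb_frac"] * r_A
    d_A = x_full["d_A"]
    if "d_A_max" in x_full:  # pinned directly (death rate itself free)
        d_A_max = max(x_full["d_A_max"], d_A)
    else:
        d_A_max = d_A + x_full["dmax_frac"] * (1.0 - d_A)
    p_min = x_full["p_min_BB"]
    p_max = p_min + x_full["gap_frac"] * (1.0 - p_min)
    return ModelParams(
        r_A=r_A, r_B=r_B, d_A=d_A, d_B=d_A, d_A_max=d_A_max,
        strategy_A=FIXED_STRATEGY_A,
        strategy_B=SwitchingStrategy(p_min, p_max, FIXED_SIGMA),
        growth=growth)


def _encode_fixed(fixed: dict) -> dict:
    """Translate natural parameter names into the internal reparameterized
    coordinates (r_B -> rb_frac etc.; requires r_A/d_A fixed too)."""
    out = dict(fixed)
    if "r_B" in out:
        out["rb_frac"] = out.pop("r_B") / out["r_A"]
    if "d_A_max" in out and "d_A" in out:
        out["dmax_frac"] = (out.pop("d_A_max") - out["d_A"]) / (1.0 - out["d_A"])
    if "p_max_BB" in out:
        out["gap_frac"] = ((out.pop("p_max_BB") - out["p_min_BB"])
                           / max(1.0 - out["p_min_BB"], 1e-12))
    return out


@dataclass
class FitResult:
    """Best-fit parameters, objective value and the multistart record."""

    params: ModelParams
    estimates: dict
    sse: float
    n_starts: int
    best_start_index: int
    start_sses: list
    converged: list
    fixed: dict
    seed: Optional[int]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "estimates": self.estimates, "sse": self.sse,
            "n_starts": self.n_starts, "best_start_index": self.best_start_index,
            "start_sses": self.start_sses, "converged": self.converged,
            "fixed": {k: (v if isinstance(v, (int, float, str)) else repr(v))
                      for k, v in self.fixed.items()},
            "seed": self.seed}, indent=2, default=float))


def fit(datasets: Sequence[GrowthAssayDataset], fixed: Optional[dict] = None,
        bounds: Optional[dict] = None, n_starts: int = 15,
        seed: Optional[int] = None, growth: Optional[GrowthLaw] = None,
        log_residuals: bool = False) -> FitResult:
    """Multistart bound-constrained least squares.

    Free parameters (unless pinned via `fixed`): r_A, r_B (as a fraction of
    r_A, enforcing the tolerance cost), d_A = d_B, d_A_max (as a fraction
    of the gap above d_A), and the tolerant retention pair (p_min_BB plus
    gap fraction).  Starts are Latin-hypercube samples of the box; each is
    polished with bounded trust-region least squares on the stacked
    residual vector and the best retained.  Default rate bounds cap
    division/death at 0.2 h^-1 (a 3.5 h doubling time is already beyond
    any cell line).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    growth = growth or GrowthLaw("malthusian")
    fixed = dict(fixed or {})
    if "strategy_B" in fixed:
        sB = fixed.pop("strategy_B")
        fixed["p_min_BB"] = sB.p_min
        fixed["gap_frac"] = (sB.p_max - sB.p_min) / max(1.0 - sB.p_min, 1e-12)
    fixed_enc = _encode_fixed(fixed) if fixed else {}
    free = [n for n in _FREE_NAMES if n not in fixed_enc]
    if "d_A_max" in fixed_enc:
        free = [n for n in free if n != "dmax_frac"]
    default_bounds = {"r_A": (1e-4, 0.2), "rb_frac": (0.0, 1.0),
                      "d_A": (0.0, 0.2), "dmax_frac": (0.0, 1.0),
                      "p_min_BB": (0.0, 1.0), "gap_frac": (0.0, 1.0)}
    if bounds:
        default_bounds.update(bounds)
    box = [default_bounds[n] for n in free]
    data_vec = np.concatenate([np.asarray(ds.counts) for ds in datasets])

    log_data = np.log(data_vec)

    def residuals(x):
        from .fitness import stable_structure

        full = dict(fixed_enc)
        full.update(dict(zip(free, x)))
        try:
            p = _build_params(full, growth)
            structure = stable_structure(p)
            pred = np.concatenate([predicted_total(p, ds, structure=structure)
                                   for ds in datasets])
        except (ValueError, FloatingPointError, RuntimeError):
            return np.full_like(data_vec, 1e12)
        pred = np.where(np.isfinite(pred), pred, 1e12)
        if log_residuals:
            return np.log(np.maximum(pred, 1e-12)) - log_data
        return pred - data_vec

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    starts = lo + sampler.random(n_starts) * (hi - lo)

    results, converged = [], []
    for x0 in starts:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=400)
        results.append(res)
        converged.append(bool(res.success))
    if not any(np.isfinite(r.cost) for r in results):
        raise RuntimeError("all optimization starts failed")
    sses = [2.0 * float(r.cost) for r in results]
    ibest = int(np.argmin(sses))
    full = dict(fixed_enc)
    full.update(dict(zip(free, results[ibest].x)))
    best = _build_params(full, growth)
    if log_residuals:
        # report the objective actually minimized (summed squared log error)
        pass
    estimates = {"r_A": best.r_A, "r_B": best.r_B, "d_A": best.d_A,
                 "d_B": best.d_B, "d_A_max": best.d_A_max,
                 "p_min_BB": best.strategy_B.p_min,
                 "p_max_BB": best.strategy_B.p_max,
                 "lambda_A": best.lambda_A, "lambda_A_star": best.lambda_A_star}
    return FitResult(best, estimates, sses[ibest], n_starts, ibest, sses,
                     converged, fixed, seed)


def refit_drug(datasets: Sequence[GrowthAssayDataset], base: FitResult,
               seed: Optional[int] = None, n_starts: int = 15) -> FitResult:
    """Cross-drug refit: growth rates frozen at the base fit, only the drug
    effect (d_A_max) and the tolerant retention pair re-estimated."""
    fixed = {"r_A": base.params.r_A, "r_B": base.params.r_B,
             "d_A": base.params.d_A}
    return fit(datasets, fixed=fixed, seed=seed, n_starts=n_starts,
               growth=base.params.growth)


def classify_strategy(datasets: Sequence[GrowthAssayDataset],
                      seed: Optional[int] = None, n_starts: int = 8,
                      sigma_B: float = FIXED_SIGMA,
                      fixed: Optional[dict] = None,
                      stay_margin: float = 0.02) -> dict:
    """Decide between the switch and stay tolerant strategies.

    Fits the remaining parameters twice, once with the tolerant retention
    pair pinned to the switch strategy (0, 0.9) and once to the stay
    strategy (0.95, 1), and compares the objectives.  The discriminating
    signal lives in the low-count segment of the treated series, so these
    fits minimize squared *log*-count error (the likelihood under
    multiplicative noise) rather than the raw squared error used for
    point estimation.  Because the stay parameterization can reproduce
    every switch-generated total-count curve (the converse is blocked by
    the r_B <= r_A cost bound), ties favour switch: the label is 'stay'
    only when the stay fit wins by more than `stay_margin` relatively.

    Classification from total counts alone is weakly powered; inspect
    `relative_gap` before trusting the label (see the methods note).
    """
    out = {}
    for label, (pmin, pmax) in (("switch", (0.0, 0.9)), ("stay", (0.95, 1.0))):
        fx = dict(fixed or {})
        fx["strategy_B"] = SwitchingStrategy(pmin, pmax, sigma_B)
        out[label] = fit(datasets, fixed=fx, seed=seed, n_starts=n_starts,
                         log_residuals=True)
    s_sw, s_st = out["switch"].sse, out["stay"].sse
    out["label"] = "stay" if s_sw > (1.0 + stay_margin) * s_st else "switch"
    out["relative_gap"] = abs(s_sw - s_st) / max(min(s_sw, s_st), 1e-300)
    return out
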