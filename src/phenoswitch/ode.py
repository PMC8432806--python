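"""Exact ODE reduction of the age-structured switching model.

Integrating the age-structured transport equations over age yields a
closed five-dimensional system for the sensitive and tolerant population
sizes (Abar, Bbar), the two phenotype-retention moments
N_AA = int beta_AA(a) A(t,a) da and N_BB = int beta_BB(a) B(t,a) da,
and the drug concentration C.  The reduction is exact: the age kernel
beta_ii is a shifted exponential, so its moment obeys its own ODE.

The retention moments are the effective pools of cells whose daughters
keep the parental phenotype; they are sandwiched between
p_min * pop and p_max * pop along any trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParams, reproduction_rate
from .pkpd import PKParams, DoseSchedule, treated_death_rate

__all__ = ["PopulationState", "Trajectory", "rhs", "initial_state", "simulate", "burden"]


@dataclass(frozen=True)
class PopulationState:
    """Model state at one instant: populations, retention moments, drug."""

    abar: float
    bbar: float
    n_aa: float
    n_bb: float
    c: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.abar, self.bbar, self.n_aa, self.n_bb, self.c])

    @classmethod
    def from_array(cls, y) -> "PopulationState":
        return cls(*(float(v) for v in y))

    @property
    def n_total(self) -> float:
        return self.abar + self.bbar

    @property
    def theta(self) -> float:
        return np.inf if self.abar == 0 else self.bbar / self.abar


@dataclass
class Trajectory:
    """Time grid (h), state matrix (n x 5), and the dosing actually applied."""

    times: np.ndarray
    states: np.ndarray  # columns: abar, bbar, n_aa, n_bb, c
    dose_log: list = field(default_factory=list)
    params: Optional[ModelParams] = None
    pk: Optional[PKParams] = None

    @property
    def abar(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def bbar(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def n_total(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    @property
    def c(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def theta(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.abar > 0, self.bbar / self.abar, np.inf)

    def state_at(self, t: float) -> PopulationState:
        y = np.array([np.interp(t, self.times, self.states[:, j]) for j in range(5)])
        return PopulationState.from_array(y)

    def final_state(self) -> PopulationState:
        return PopulationState.from_array(self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t_hours": self.times,
            "A": self.abar, "B": self.bbar,
            "N_AA": self.states[:, 2], "N_BB": self.states[:, 3],
            "C": self.c, "theta": self.theta, "N_total": self.n_total,
        })

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_summary(self, path, **extra) -> None:
        final = self.final_state()
        summary = {
            "t_end_hours": float(self.times[-1]),
            "final_state": {"A": final.abar, "B": final.bbar, "N_AA": final.n_aa,
                            "N_BB": final.n_bb, "C": final.c},
            "doses_given": len(self.dose_log),
            "params": self.params.to_dict() if self.params else None,
        }
        summary.update(extra)
        K = summary.get("params", {}).get("K") if summary.get("params") else None
        if K == float("inf"):
            summary["params"]["K"] = "inf"
        Path(path).write_text(json.dumps(summary, indent=2, default=float))


def rhs(t: float, y: np.ndarray, params: ModelParams, pk: Optional[PKParams],
        i_rate: float = 0.0) -> np.ndarray:
    """Time derivative of (Abar, Bbar, N_AA, N_BB, C).

    Each division removes the mother and adds two age-zero daughters; the
    retention moments receive the newborn flux weighted by p_max (newborn
    parents retain with probability p_max) and relax towards p_min * pop at
    the memory-decay rate sigma.  `i_rate` is the infusion rate over the
    current integration segment (piecewise constant).
    """
    abar, bbar, n_aa, n_bb, c = y
    sA, sB = params.strategy_A, params.strategy_B
    R_A = reproduction_rate("A", max(abar, 0.0), max(bbar, 0.0), params)
    R_B = reproduction_rate("B", max(abar, 0.0), max(bbar, 0.0), params)
    if pk is not None:
        delta_A = treated_death_rate(params.d_A, params.d_A_max, max(c, 0.0), pk.c_half)
        k_elim = pk.k_elim
    else:
        delta_A, k_elim = params.d_A, 0.0

    birth_A = 2.0 * R_A * n_aa + 2.0 * R_B * (bbar - n_bb)   # newborns of phenotype A
    birth_B = 2.0 * R_A * (abar - n_aa) + 2.0 * R_B * n_bb   # newborns of phenotype B

    d_abar = -(R_A + delta_A) * abar + birth_A
    d_bbar = -(R_B + params.d_B) * bbar + birth_B
    d_naa = (sA.p_max * birth_A - (R_A + delta_A) * n_aa
             + sA.sigma * (sA.p_min * abar - n_aa))
    d_nbb = (sB.p_max * birth_B - (R_B + params.d_B) * n_bb
             - sB.sigma * n_bb + sB.sigma * sB.p_min * bbar)
    d_c = i_rate - k_elim * c
    return np.array([d_abar, d_bbar, d_naa, d_nbb, d_c])


def initial_state(params: ModelParams, n0: float, mode: str = "eigen",
                  abar: Optional[float] = None, bbar: Optional[float] = None) -> PopulationState:
    """Initial condition of total size n0.

    'eigen' (default) places the population on the dominant eigenvector of
    the untreated linear generator — a tumour in steady exponential growth,
    where the retention moments sit at their stable-age-distribution
    values.  'explicit' takes user (abar, bbar) and sets each retention
    moment to the midpoint of its admissible band.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if mode == "explicit":
        if abar is None or bbar is None:
            raise ValueError("explicit mode requires abar and bbar")
        scale = n0 / (abar + bbar)
        abar, bbar = abar * scale, bbar * scale
        sA, sB = params.strategy_A, params.strategy_B
        return PopulationState(abar, bbar,
                               0.5 * (sA.p_min + sA.p_max) * abar,
                               0.5 * (sB.p_min + sB.p_max) * bbar, 0.0)
    if mode != "eigen":
        raise ValueError(f"unknown mode {mode!r}")
    from .fitness import stable_structure

    abar_f, bbar_f, naa_f, nbb_f = stable_structure(params)
    return PopulationState(n0 * abar_f, n0 * bbar_f, n0 * naa_f, n0 * nbb_f, 0.0)


def simulate(params: ModelParams, pk: Optional[PKParams] = None,
             schedule: Optional[DoseSchedule] = None,
             t_span: Sequence[float] = (0.0, 100.0),
             n0: float = 1e4, y0: Optional[PopulationState] = None,
             n_points: int = 400, rtol: float = 1e-8,
             atol: Optional[float] = None, method: str = "LSODA") -> Trajectory:
    """Integrate the reduced system under an arbitrary dosing schedule.

    Dose starts and infusion ends are hard integrator breakpoints, so the
    piecewise-constant infusion rate is exact within each segment and no
    event detection is needed.  Output is sampled on a uniform grid plus
    all breakpoints.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must satisfy t1 > t0")
    if y0 is None:
        y0 = initial_state(params, n0)
    y = y0.as_array().astype(float)
    if atol is None:
        atol = 1e-10 * max(y[0] + y[1], 1.0)
    schedule = schedule or DoseSchedule()
    if schedule.times and pk is None:
        raise ValueError("a dosing schedule requires PK parameters")

    bps = schedule.breakpoints()
    bps = bps[(bps > t0) & (bps < t1)]
    seg_edges = np.unique(np.concatenate([[t0, t1], bps]))
    grid = np.unique(np.concatenate([np.linspace(t0, t1, n_points), seg_edges]))

    times = [t0]
    states = [y.copy()]
    dose_log = []
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        mid = 0.5 * (a + b)
        if pk is not None:
            from .pkpd import infusion_rate

            i_rate = infusion_rate(schedule, pk, mid)
            if i_rate > 0 and any(abs(a - ti) < 1e-9 for ti in schedule.times):
                dose_log.append((a, i_rate * pk.vol * schedule.t_admin))
        else:
            i_rate = 0.0
        t_eval = grid[(grid > a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method=method,
                        rtol=rtol, atol=atol, args=(params, pk, i_rate))
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{a:g}, {b:g}] h: {sol.message}; "
                f"last state {y}")
        times.extend(sol.t.tolist())
        states.extend(sol.y.T)
        y = sol.y[:, -1].copy()

    states = np.asarray(states)
    # Reporting-only clip of tiny negative overshoot; never fed back.
    states[np.abs(states) < 1e-300] = 0.0
    return Trajectory(np.asarray(times), states, dose_log, params, pk)


def burden(traj: Trajectory, K: float, t_end: Optional[float] = None,
           t_start: float = 0.0) -> float:
    """Time-averaged total population as a fraction of carrying capacity.

    (1/(t_end - t_start)) int N(tau)/K dtau by trapezoidal quadrature on
    the output grid, with linear interpolation at the window edges.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    t_end = float(traj.times[-1]) if t_end is None else float(t_end)
    if t_start < traj.times[0] - 1e-9 or t_end > traj.times[-1] + 1e-9:
        raise ValueError("burden window must lie inside the trajectory")
    if t_end <= t_start:
        raise ValueError("empty burden window")
    n_tot = traj.n_total
    mask = (traj.times > t_start) & (traj.times < t_end)
    ts = np.concatenate([[t_start], traj.times[mask], [t_end]])
    ns = np.concatenate([[np.interp(t_start, traj.times, n_tot)],
                         n_tot[mask],
                         [np.interp(t_end, traj.times, n_tot)]])
    return float(np.trapezoid(ns / K, ts) / (t_end - t_start))
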