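"""Treatment schedulers and resistance classification.

Two schedulers are provided: unconditional periodic dosing, and the
model-informed (adaptive) scheduler that administers a dose at a decision
time only while the tolerant-to-sensitive ratio theta = Bbar/Abar sits
below the self-sustainability threshold theta* — keeping enough sensitive
competitors alive to suppress the tolerant pool while the drug keeps the
total population decaying.

All public interfaces take days (clinical convention); internals run in
hours.  Doses are in c_half * vol units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import ModelParams, theta_star
from .pkpd import PKParams, DoseSchedule
from .ode import Trajectory, simulate, burden, initial_state

__all__ = [
    "TherapyOutcome", "run_periodic", "run_informed", "select_period",
    "resistance_established", "sustained_decay", "compare_burden",
]

HOURS = 24.0


@dataclass
class TherapyOutcome:
    """Result of one scheduled treatment simulation."""

    trajectory: Trajectory
    doses_given: list
    doses_skipped: list
    burden: float
    resistance: bool
    theta_max: float
    window_days: Tuple[float, float]
    chosen_T: Optional[float] = None
    dose: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def cumulative_dose(self) -> float:
        return self.dose * len(self.doses_given)


def _windows(window_days, horizon_days):
    w0, w1 = float(window_days[0]) * HOURS, float(window_days[1]) * HOURS
    if horizon_days is None:
        horizon = w1 + 50.0 * HOURS
    else:
        horizon = float(horizon_days) * HOURS
    if not (0 <= w0 < w1 <= horizon):
        raise ValueError("treatment window must lie inside the horizon")
    return w0, w1, horizon


def _finish(traj: Trajectory, params: ModelParams, given, skipped,
            window_days, horizon_h, dose, theta_thresh=None) -> TherapyOutcome:
    K = params.growth.K
    b = burden(traj, K) if math.isfinite(K) else float("nan")
    w0, w1 = window_days[0] * HOURS, window_days[1] * HOURS
    mask = (traj.times >= w0) & (traj.times <= w1)
    theta_w = traj.theta[mask]
    theta_max = float(np.max(theta_w[np.isfinite(theta_w)])) if mask.any() else float("nan")
    thr = theta_thresh
    if thr is None:
        try:
            thr = theta_star(params)
        except ValueError:
            thr = None
    res = resistance_established(traj, window_days, thr) if thr is not None else False
    return TherapyOutcome(traj, list(given), list(skipped), b, res, theta_max,
                          tuple(window_days), dose=dose)


def run_periodic(params: ModelParams, pk: PKParams, dose: float, period_days: float,
                 window_days: Sequence[float] = (50.0, 275.0), n0: float = 1e5,
                 horizon_days: Optional[float] = None, **sim_kw) -> TherapyOutcome:
    """Administer `dose` every `period_days` inside the window, unconditionally."""
    w0, w1, horizon = _windows(window_days, horizon_days)
    schedule = DoseSchedule.periodic(w0, w1, period_days * HOURS, dose, pk.t_admin)
    traj = simulate(params, pk, schedule, t_span=(0.0, horizon), n0=n0, **sim_kw)
    given = [t for t, _ in traj.dose_log]
    return _finish(traj, params, given, [], window_days, horizon, dose)


def run_informed(params: ModelParams, pk: PKParams, dose: float, period_days: float,
                 theta_threshold: Optional[float] = None,
                 window_days: Sequence[float] = (50.0, 150.0), n0: float = 1e5,
                 horizon_days: Optional[float] = None, **sim_kw) -> TherapyOutcome:
    """theta-gated adaptive scheduler.

    At each decision time (every `period_days` from the window start) the
    dose is administered iff theta = Bbar/Abar < theta_threshold (default
    theta* from the model parameters), otherwise skipped; every decision is
    logged.  If sensitives are extinct at a decision point theta = inf and
    the dose is skipped.
    """
    w0, w1, horizon = _windows(window_days, horizon_days)
    if theta_threshold is None:
        theta_threshold = theta_star(params)
    if theta_threshold < 0:
        raise ValueError("theta_threshold must be >= 0")
    T = period_days * HOURS

    y = initial_state(params, n0)
    times_all = [np.array([0.0])]
    states_all = [y.as_array()[None, :]]
    given, skipped = [], []

    def run_segment(a, b, y0, seg_dose):
        schedule = (DoseSchedule((a,), (seg_dose,), pk.t_admin) if seg_dose > 0
                    else DoseSchedule())
        npts = max(8, int((b - a) / 6.0))
        traj = simulate(params, pk, schedule, t_span=(a, b), y0=y0,
                        n_points=npts, **sim_kw)
        return traj

    decision_times = np.arange(w0, w1 - 1e-9, T)
    edges = list(decision_times) + [w1, horizon]
    # burn-in up to the first decision time
    if w0 > 0:
        traj = run_segment(0.0, w0, y, 0.0)
        times_all.append(traj.times[1:])
        states_all.append(traj.states[1:])
        y = traj.final_state()
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a + 1e-9:
            continue
        if a in decision_times:
            th = y.theta
            if th < theta_threshold:
                given.append(a)
                seg_dose = dose
            else:
                skipped.append(a)
                seg_dose = 0.0
        else:
            seg_dose = 0.0
        traj = run_segment(a, b, y, seg_dose)
        times_all.append(traj.times[1:])
        states_all.append(traj.states[1:])
        y = traj.final_state()

    full = Trajectory(np.concatenate(times_all), np.vstack(states_all),
                      [(t, dose) for t in given], params, pk)
    out = _finish(full, params, given, skipped, window_days, horizon, dose,
                  theta_thresh=theta_threshold)
    out.diagnostics["theta_threshold"] = theta_threshold
    return out


def resistance_established(traj: Trajectory, window_days: Sequence[float],
                           theta_threshold: float, tail_frac: float = 0.2,
                           ) -> bool:
    """Classify a trajectory as having established drug tolerance.

    True iff over the final `tail_frac` of the dosing window both the
    median ratio theta exceeds the threshold and the least-squares slope of
    log N(t) is nonnegative while dosing continues (treatment has lost its
    effect on a tolerant-dominated population).
    """
    w0, w1 = float(window_days[0]) * HOURS, float(window_days[1]) * HOURS
    if w1 <= w0:
        return False
    t_tail = w1 - tail_frac * (w1 - w0)
    mask = (traj.times >= t_tail) & (traj.times <= w1)
    if mask.sum() < 3:
        return False
    theta_tail = traj.theta[mask]
    n_tail = traj.n_total[mask]
    if np.all(n_tail <= 0):
        return False
    med_theta = float(np.median(theta_tail))
    slope = float(np.polyfit(traj.times[mask], np.log(np.maximum(n_tail, 1e-300)), 1)[0])
    return med_theta > theta_threshold and slope >= 0.0


def sustained_decay(traj: Trajectory, window_days: Sequence[float],
                    tail_days: float = 30.0) -> bool:
    """Sustained population decay: N at window end below N at treatment
    start AND negative log-slope over the final `tail_days` of the window."""
    w0, w1 = float(window_days[0]) * HOURS, float(window_days[1]) * HOURS
    n0 = traj.state_at(w0).n_total
    n1 = traj.state_at(w1).n_total
    mask = (traj.times >= w1 - tail_days * HOURS) & (traj.times <= w1)
    if mask.sum() < 3 or n1 <= 0:
        return n1 < n0
    slope = float(np.polyfit(traj.times[mask], np.log(np.maximum(traj.n_total[mask], 1e-300)), 1)[0])
    return n1 < n0 and slope < 0.0


@dataclass
class PeriodSelection:
    """Result of the treatment-period search."""

    chosen_T: Optional[float]
    dose: Optional[float]
    outcome: Optional[TherapyOutcome]
    per_period: dict


def select_period(params: ModelParams, pk: PKParams,
                  candidates_days: Sequence[float] = (1, 2, 3, 4, 5, 6, 7),
                  d_mtd: Optional[float] = None,
                  window_days: Sequence[float] = (50.0, 150.0),
                  n0: float = 1e5, horizon_days: Optional[float] = None,
                  safety: float = 2.0, **sim_kw) -> PeriodSelection:
    """Choose the largest candidate period with sustained decay and no
    resistance under theta-gated dosing.

    For each period T the per-dose size is the minimal dose driving the
    treated Floquet multiplier to 1, inflated by the `safety` factor (the
    marginal dose only stalls growth; the closed-form sufficient-condition
    dose it stands in for is itself conservative) and capped at
    d_mtd * T / 7 so the cumulative dose never exceeds the weekly
    maximally tolerated schedule.  `d_mtd` defaults to 1.5x the minimal
    weekly-effective dose.
    """
    from .fitness import min_effective_dose

    if d_mtd is None:
        ref = min_effective_dose(params, pk, 7.0 * HOURS)
        if not ref.feasible:
            raise ValueError("cannot derive default d_mtd: weekly dosing infeasible")
        d_mtd = 1.5 * ref.dose if ref.dose > 0 else 1.0
    per_period = {}
    best = None
    for T in candidates_days:
        cap = d_mtd * T / 7.0
        dres = min_effective_dose(params, pk, T * HOURS, cap=cap)
        if not dres.feasible:
            per_period[T] = {"feasible": False, "reason": "no admissible dose",
                             "rho_at_cap": dres.rho}
            continue
        dose_T = min(safety * dres.dose, cap)
        out = run_informed(params, pk, dose_T, T, window_days=window_days,
                           n0=n0, horizon_days=horizon_days, **sim_kw)
        decay = sustained_decay(out.trajectory, window_days)
        ok = decay and not out.resistance
        per_period[T] = {"feasible": ok, "dose": dose_T, "decay": decay,
                         "resistance": out.resistance, "burden": out.burden}
        if ok and (best is None or T > best[0]):
            out.chosen_T = T
            best = (T, dose_T, out)
    if best is None:
        return PeriodSelection(None, None, None, per_period)
    return PeriodSelection(best[0], best[1], best[2], per_period)


def compare_burden(outcome_a: TherapyOutcome, outcome_b: TherapyOutcome,
                   window_days: Optional[Sequence[float]] = None) -> float:
    """Burden ratio A/B, optionally recomputed over a common window (days)."""
    if window_days is not None:
        Ka = outcome_a.trajectory.params.growth.K
        Kb = outcome_b.trajectory.params.growth.K
        w0, w1 = float(window_days[0]) * HOURS, float(window_days[1]) * HOURS
        ba = burden(outcome_a.trajectory, Ka, t_start=w0, t_end=w1)
        bb = burden(outcome_b.trajectory, Kb, t_start=w0, t_end=w1)
    else:
        ba, bb = outcome_a.burden, outcome_b.burden
    if bb == 0:
        raise ZeroDivisionError("reference burden is zero")
    return ba / bb
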