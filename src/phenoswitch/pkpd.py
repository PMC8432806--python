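"""One-compartment pharmacokinetics and sensitive-cell pharmacodynamics.

The drug concentration obeys dC/dt = I(t) - k_elim C with first-order
clearance k_elim = log(2)/t_half and a piecewise-constant infusion rate
I(t) = Dose/(Vol T_admin) inside each administration window.  Only the
ratio C/C_half enters the pharmacodynamics, so doses are carried in
dimensionless units of c_half * vol throughout.

The effect is a saturable (Emax) increase of the sensitive death rate:
d_A(t) = d_A + (d_A_max - d_A) C/(C + C_half); tolerant cells are not
directly affected by the drug.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PKParams",
    "DoseSchedule",
    "infusion_rate",
    "concentration",
    "periodic_steady_concentration",
    "treated_death_rate",
]


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic constants: half-life (h), distribution volume,
    half-effect concentration C_half, infusion duration (h)."""

    t_half: float
    vol: float = 1.0
    c_half: float = 1.0
    t_admin: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_half", "vol", "c_half", "t_admin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def k_elim(self) -> float:
        return math.log(2.0) / self.t_half


@dataclass(frozen=True)
class DoseSchedule:
    """Administration start times (h) and per-dose amounts (c_half*vol units)."""

    times: tuple = ()
    doses: tuple = ()
    t_admin: float = 1.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "doses", doses)
        if len(times) != len(doses):
            raise ValueError("times and doses must have equal length")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be >= 0")
        if any(t2 < t1 + self.t_admin - 1e-12 for t1, t2 in zip(times, times[1:])):
            raise ValueError("administrations must be ordered and non-overlapping")

    @classmethod
    def periodic(cls, start: float, end: float, period: float, dose: float,
                 t_admin: float = 1.0) -> "DoseSchedule":
        """Equal doses every `period` hours from `start` up to (excluding) `end`."""
        if period <= 0:
            raise ValueError("period must be > 0")
        times = np.arange(start, end, period)
        return cls(tuple(times), (dose,) * len(times), t_admin)

    @property
    def total_dose(self) -> float:
        return float(sum(self.doses))

    def breakpoints(self) -> np.ndarray:
        """Dose starts and infusion ends, for use as integrator restart points."""
        pts = [t for t in self.times] + [t + self.t_admin for t in self.times]
        return np.array(sorted(pts))


def infusion_rate(schedule: DoseSchedule, pk: PKParams, t: float) -> float:
    """Instantaneous infusion rate I(t) (concentration per hour)."""
    i = bisect.bisect_right(schedule.times, t) - 1
    if i >= 0 and schedule.times[i] < t < schedule.times[i] + schedule.t_admin:
        return schedule.doses[i] / (pk.vol * schedule.t_admin)
    return 0.0


def _single_dose_conc(dose: float, pk: PKParams, t_admin: float, tau) -> np.ndarray:
    """Concentration at time tau after the start of one administration, C(0)=0.

    Piecewise closed form of the linear ODE: saturating rise during the
    infusion, exponential decay afterwards.
    """
    tau = np.asarray(tau, dtype=float)
    k = pk.k_elim
    rate = dose / (pk.vol * t_admin)
    c_end = rate / k * (1.0 - math.exp(-k * t_admin))  # end-of-infusion peak
    rising = rate / k * (1.0 - np.exp(-k * np.clip(tau, 0.0, t_admin)))
    decaying = c_end * np.exp(-k * (tau - t_admin))
    return np.where(tau <= 0, 0.0, np.where(tau <= t_admin, rising, decaying))


def concentration(pk: PKParams, schedule: DoseSchedule, t_grid, c0: float = 0.0) -> np.ndarray:
    """Drug concentration on `t_grid` (hours) by exact superposition.

    The ODE is linear, so the trajectory is the sum of the closed-form
    single-dose responses plus the decaying initial condition.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    out = c0 * np.exp(-pk.k_elim * (t_grid - t_grid[0])) if t_grid.size else np.zeros(0)
    out = np.array(out, dtype=float)
    for t_i, dose in zip(schedule.times, schedule.doses):
        out = out + _single_dose_conc(dose, pk, schedule.t_admin, t_grid - t_i)
    return out


def periodic_steady_concentration(pk: PKParams, dose: float, period: float, phase) -> float:
    """Concentration of the periodic limit of repeated equal dosing.

    `phase` is the time (h) since the start of the most recent
    administration, 0 <= phase < period.  Obtained from the geometric-series
    accumulation of the piecewise closed form; for t_admin << period this
    reduces to (Dose/Vol) e^(-k tau) / (1 - e^(-k period)).
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    phase_arr = np.asarray(phase, dtype=float)
    if np.any((phase_arr < 0) | (phase_arr >= period)):
        raise ValueError("phase must lie in [0, period)")
    k = pk.k_elim
    decay = math.exp(-k * period)
    # Pre-dose trough: sum over earlier doses, C1(m*period) = C1(period) decay^(m-1).
    c_trough = float(_single_dose_conc(dose, pk, pk.t_admin, period)) / (1.0 - decay)
    within = _single_dose_conc(dose, pk, pk.t_admin, phase_arr)
    out = c_trough * np.exp(-k * phase_arr) + within
    return float(out) if out.ndim == 0 else out


def treated_death_rate(d_A: float, d_A_max: float, c, c_half: float):
    """Drug-elevated sensitive death rate d_A + (d_A_max - d_A) C/(C + C_half)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = d_A + (d_A_max - d_A) * c / (c + c_half)
    return float(out) if out.ndim == 0 else out
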