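"""Core model of memory-driven phenotype switching.

Two phenotypes share a clonal population: drug-sensitive cells (A) and
drug-tolerant persisters (B).  A daughter cell inherits the parental
phenotype with an age-dependent probability ``beta_ii(a)``: parents that
divide young bequeath their phenotype with probability up to ``p_max``,
while in old parents the intracellular signalling factors encoding the
phenotype have decayed (rate ``sigma``) and the retention probability has
relaxed to ``p_min``.  Growth laws range from pure Malthusian expansion to
logistic resource limitation, optionally with a frequency-dependent
cooperation (Allee) boost of the tolerant phenotype.

All rates are per hour; the canonical internal time unit is hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np

__all__ = [
    "SwitchingStrategy",
    "GrowthLaw",
    "ModelParams",
    "switching_probability",
    "cooperation_factor",
    "reproduction_rate",
    "theta_star",
    "theta_epsilon_star",
]

GrowthMode = Literal["malthusian", "logistic", "malthusian_allee", "logistic_allee"]


@dataclass(frozen=True)
class SwitchingStrategy:
    """Age-dependent phenotype-retention strategy (p_min, p_max, sigma).

    ``p_min``/``p_max`` are the asymptotic (old-parent) and newborn-parent
    probabilities that a daughter keeps the parental phenotype; ``sigma``
    (h^-1) is the decay rate of the intracellular memory factors.
    """

    p_min: float
    p_max: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError(
                f"require 0 <= p_min <= p_max <= 1, got ({self.p_min}, {self.p_max})"
            )
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class GrowthLaw:
    """Selects the reproduction-rate law shared by both phenotypes.

    ``K`` (cells) is the carrying capacity of the logistic modes; ``n`` is
    the Hill coefficient of the cooperation factor in the Allee modes.
    """

    mode: GrowthMode = "malthusian"
    K: float = math.inf
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("malthusian", "logistic", "malthusian_allee", "logistic_allee"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.is_logistic and not self.K > 0:
            raise ValueError("logistic growth requires K > 0")
        if self.is_allee and self.n < 1:
            raise ValueError("Allee modes require Hill coefficient n >= 1")

    @property
    def is_logistic(self) -> bool:
        return self.mode in ("logistic", "logistic_allee")

    @property
    def is_allee(self) -> bool:
        return self.mode in ("malthusian_allee", "logistic_allee")


@dataclass(frozen=True)
class ModelParams:
    """All rates and strategies of the two-phenotype switching model.

    r_i / d_i are division and death rates (h^-1); ``d_A_max`` is the fully
    saturated drug-induced death rate of sensitive cells.  The cost of
    tolerance is encoded by r_B <= r_A.
    """

    r_A: float
    r_B: float
    d_A: float
    d_B: float
    d_A_max: float
    strategy_A: SwitchingStrategy
    strategy_B: SwitchingStrategy
    growth: GrowthLaw = field(default_factory=GrowthLaw)

    def __post_init__(self) -> None:
        for name in ("r_A", "r_B", "d_A", "d_B", "d_A_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_B > self.r_A + 1e-12:
            raise ValueError("cost of tolerance requires r_B <= r_A")
        if self.d_A_max < self.d_A:
            raise ValueError("d_A_max must be >= d_A")

    # Intrinsic growth rates of the pure subpopulations.
    @property
    def lambda_A(self) -> float:
        return self.r_A - self.d_A

    @property
    def lambda_B(self) -> float:
        return self.r_B - self.d_B

    @property
    def lambda_A_star(self) -> float:
        """Growth rate of sensitive cells under saturating drug."""
        return self.r_A - self.d_A_max

    def replace(self, **kwargs) -> "ModelParams":
        d = {
            "r_A": self.r_A, "r_B": self.r_B, "d_A": self.d_A, "d_B": self.d_B,
            "d_A_max": self.d_A_max, "strategy_A": self.strategy_A,
            "strategy_B": self.strategy_B, "growth": self.growth,
        }
        d.update(kwargs)
        return ModelParams(**d)

    # -- flat key/value (de)serialization -----------------------------------
    def to_dict(self) -> dict:
        return {
            "r_A": self.r_A, "r_B": self.r_B, "d_A": self.d_A, "d_B": self.d_B,
            "d_A_max": self.d_A_max,
            "p_min_AA": self.strategy_A.p_min, "p_max_AA": self.strategy_A.p_max,
            "sigma_A": self.strategy_A.sigma,
            "p_min_BB": self.strategy_B.p_min, "p_max_BB": self.strategy_B.p_max,
            "sigma_B": self.strategy_B.sigma,
            "growth_mode": self.growth.mode,
            "K": self.growth.K, "n": self.growth.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            r_A=float(d["r_A"]), r_B=float(d["r_B"]),
            d_A=float(d["d_A"]), d_B=float(d["d_B"]),
            d_A_max=float(d["d_A_max"]),
            strategy_A=SwitchingStrategy(
                float(d["p_min_AA"]), float(d["p_max_AA"]), float(d["sigma_A"])),
            strategy_B=SwitchingStrategy(
                float(d["p_min_BB"]), float(d["p_max_BB"]), float(d["sigma_B"])),
            growth=GrowthLaw(
                mode=d.get("growth_mode", "malthusian"),
                K=float(d.get("K", math.inf)),
                n=float(d.get("n", 1.0))),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        d = self.to_dict()
        if math.isinf(d["K"]):
            d["K"] = "inf"
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelParams":
        d = json.loads(Path(path).read_text())
        if d.get("K") == "inf":
            d["K"] = math.inf
        return cls.from_dict(d)


def switching_probability(strategy: SwitchingStrategy, age) -> float:
    """Probability beta_ii(a) that a parent of the given age (hours) passes
    its phenotype to both daughters.

    beta_ii(a) = p_min + (p_max - p_min) exp(-sigma a); the cross-switch
    probability is the complement 1 - beta_ii(a).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = strategy.p_min + (strategy.p_max - strategy.p_min) * np.exp(-strategy.sigma * age)
    return float(out) if out.ndim == 0 else out


def cooperation_factor(theta, n: float, r_A: float, r_B: float):
    """Frequency-dependent fitness multiplier f_n(theta) of tolerant cells.

    f_n(theta) = (r_B + r_A theta^n) / (r_B (1 + theta^n)) is the Hill-type
    interpolation rising from 1 at theta = 0 (no tolerant cells, no gain)
    towards r_A / r_B as tolerant cells dominate, so the boosted rate
    r_B f_n never exceeds the sensitive division rate r_A.
    """
    if not (0 < r_B <= r_A):
        raise ValueError("require 0 < r_B <= r_A")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    with np.errstate(over="ignore", invalid="ignore"):
        tn = theta ** n
        out = np.where(np.isinf(tn), r_A / r_B,
                       (r_B + r_A * tn) / (r_B * (1.0 + tn)))
    return float(out) if out.ndim == 0 else out


def reproduction_rate(phenotype: str, abar: float, bbar: float, params: ModelParams) -> float:
    """Reproduction rate R_A or R_B at population state (abar, bbar).

    Malthusian modes return the intrinsic division rate; logistic modes
    scale it by the free capacity max(0, 1 - N/K); Allee modes multiply the
    tolerant (B) base rate by the cooperation factor at theta = bbar/abar.
    At abar = 0 the ratio is taken as +inf and the saturated factor r_A/r_B
    is used, so trajectories that drive sensitives extinct stay integrable.
    """
    if phenotype not in ("A", "B"):
        raise ValueError(f"phenotype must be 'A' or 'B', got {phenotype!r}")
    if abar < 0 or bbar < 0:
        raise ValueError("populations must be >= 0")
    g = params.growth
    base = params.r_A if phenotype == "A" else params.r_B
    if g.is_logistic:
        base *= max(0.0, 1.0 - (abar + bbar) / g.K)
    if phenotype == "B" and g.is_allee:
        theta = math.inf if abar == 0.0 else bbar / abar
        base *= cooperation_factor(theta, g.n, params.r_A, params.r_B)
    return base


def theta_star(params: ModelParams) -> float:
    """Threshold tolerant-to-sensitive ratio theta* = [-lambda_B/lambda_A]^(1/n).

    Below theta* the cooperation-boosted tolerant growth rate
    lambda_B(theta) = r_B f_n(theta) - d_B is negative, i.e. the tolerant
    pool cannot self-sustain (the identity is exact when d_A = d_B).
    Requires the fitted regime lambda_B < 0 < lambda_A.
    """
    lam_A, lam_B = params.lambda_A, params.lambda_B
    if not (lam_B < 0 < lam_A):
        raise ValueError(
            f"theta* requires lambda_B < 0 < lambda_A, got ({lam_B:g}, {lam_A:g})")
    return (-lam_B / lam_A) ** (1.0 / params.growth.n)


def theta_epsilon_star(params: ModelParams, epsilon: float) -> float:
    """Ratio threshold keeping the cooperation gain below a fraction epsilon.

    Returns [(eps r_A - r_B) / (r_A (1 - eps))]^(1/n); for theta below this
    value r_B f_n(theta) < eps r_A.  epsilon must lie in (r_B/r_A, 1).
    """
    r_A, r_B, n = params.r_A, params.r_B, params.growth.n
    if not (r_B / r_A < epsilon < 1.0):
        raise ValueError(f"epsilon must lie in (r_B/r_A, 1) = ({r_B / r_A:g}, 1)")
    return ((epsilon * r_A - r_B) / (r_A * (1.0 - epsilon))) ** (1.0 / n)
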