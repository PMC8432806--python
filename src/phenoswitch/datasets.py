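"""Seeded generator of synthetic growth-assay datasets and named
parameter scenarios.

The generator emulates the spheroid growth assays the model was designed
around: a clonal population counted on days 1, 3, 5 and 7, untreated or
bathed in a constant lethal drug concentration from 72 h of growth
onward, with multiplicative (lognormal, mean-preserving) count noise.

Scenario parameter sets
-----------------------
``switch`` / ``stay`` / ``symmetric`` are the generic illustration
strategies (tolerant retention pairs (0, 0.9), (0.95, 1) and (0.9, 0.95),
sensitive side fixed at (0.9, 0.95), sigma = 1e-2 h^-1) on a shared
generic rate set.  ``wt_like`` and ``m1_like`` are synthetic stand-ins
for fitted NSCLC docetaxel parameter sets: they are NOT fitted values but
are chosen once in the regime all the scheduling analysis assumes —
lambda_A > 0 > lambda_B (r_B < d_B, the tolerant pool decays unless
cooperation rescues it) and treated lambda_A* < 0 (the drug can reverse
sensitive growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import GrowthLaw, ModelParams, SwitchingStrategy
from .pkpd import PKParams
from .fitting import GrowthAssayDataset, predicted_total, FIXED_SIGMA

__all__ = ["AssayDesign", "generate", "scenario", "scenario_pk",
           "generic_protocol", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("switch", "stay", "symmetric", "wt_like", "m1_like")

# Generic strategy-experiment rates (synthetic stand-in for the generic
# parameter table): equal death rates with the tolerance cost entirely on
# the division rate, so lambda_A = 0.015 > 0 > lambda_B = -0.002 h^-1 and,
# at a cooperation-saturated tolerant-dominated state, both phenotypes are
# equally fit and the switching-leak asymmetry alone decides which
# composition is stable — the mechanism behind transient (switch) versus
# permanent (stay) resistance.  Saturated drug kill lambda_A* = -0.045.
_GENERIC = dict(r_A=0.035, r_B=0.018, d_A=0.02, d_B=0.02, d_A_max=0.08)
_GENERIC_GROWTH = GrowthLaw("logistic_allee", K=1e6, n=2.0)
_GENERIC_DOSE = 50.0  # per-administration dose, c_half*vol units
_STRAT_A_GENERIC = SwitchingStrategy(0.9, 0.95, FIXED_SIGMA)

# NSCLC-like stand-ins (docetaxel): slower spheroid growth, fitted-style
# conventions P*_AA = 0, Pmax_AA = 0.95, d_A = d_B, and a tolerant pool
# that drains faster than sensitives grow (|lambda_B| > lambda_A), so the
# self-sustainability threshold theta* exceeds 1 and sits above the stable
# exponential-growth ratio — the regime in which theta-gated dosing can
# hold the composition below threshold.
_STRAT_A_FIT = SwitchingStrategy(0.0, 0.95, FIXED_SIGMA)
_WT = dict(r_A=0.070, r_B=0.005, d_A=0.040, d_B=0.040, d_A_max=0.150)
_M1 = dict(r_A=0.080, r_B=0.004, d_A=0.045, d_B=0.045, d_A_max=0.200)
_NSCLC_GROWTH = GrowthLaw("logistic_allee", K=1e6, n=1.0)


def scenario(name: str) -> ModelParams:
    """Named, fully populated parameter sets (see module docstring)."""
    if name == "switch":
        return ModelParams(**_GENERIC, strategy_A=_STRAT_A_GENERIC,
                           strategy_B=SwitchingStrategy(0.0, 0.9, FIXED_SIGMA),
                           growth=_GENERIC_GROWTH)
    if name == "stay":
        return ModelParams(**_GENERIC, strategy_A=_STRAT_A_GENERIC,
                           strategy_B=SwitchingStrategy(0.95, 1.0, FIXED_SIGMA),
                           growth=_GENERIC_GROWTH)
    if name == "symmetric":
        return ModelParams(**_GENERIC, strategy_A=_STRAT_A_GENERIC,
                           strategy_B=_STRAT_A_GENERIC, growth=_GENERIC_GROWTH)
    if name == "wt_like":
        return ModelParams(**_WT, strategy_A=_STRAT_A_FIT,
                           strategy_B=SwitchingStrategy(0.2, 0.8, FIXED_SIGMA),
                           growth=_NSCLC_GROWTH)
    if name == "m1_like":
        return ModelParams(**_M1, strategy_A=_STRAT_A_FIT,
                           strategy_B=SwitchingStrategy(0.2, 0.8, FIXED_SIGMA),
                           growth=_NSCLC_GROWTH)
    raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def scenario_pk(name: str) -> PKParams:
    """PK stand-ins: the generic agent has the 6 h half-life used in the
    cyclic-therapy illustrations; the docetaxel-like agent an 11 h
    effective one-compartment half-life."""
    if name in ("switch", "stay", "symmetric"):
        return PKParams(t_half=6.0, vol=1.0, c_half=1.0, t_admin=1.0)
    if name in ("wt_like", "m1_like"):
        return PKParams(t_half=11.0, vol=1.0, c_half=1.0, t_admin=1.0)
    raise KeyError(f"unknown scenario {name!r}")


def generic_protocol() -> dict:
    """Cyclic-chemotherapy illustration protocol: 21-day cycles between
    days 50 and 275 at dose 50 (c_half*vol units), simulated to day 350
    from 1e5 cells."""
    return {"dose": _GENERIC_DOSE, "period_days": 21.0,
            "window_days": (50.0, 275.0), "n0": 1e5, "horizon_days": 350.0}


@dataclass(frozen=True)
class AssayDesign:
    """Observation design of one synthetic assay run."""

    days: tuple = (1.0, 3.0, 5.0, 7.0)
    t_treat: float = 72.0
    conditions: tuple = ("untreated", "drug")
    noise: str = "lognormal"  # or "none"
    cv: float = 0.10
    n_replicates: int = 1
    n0: float = 1000.0
    init: str = "eigen"  # composition at plating: "eigen" or "sensitive"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValueError("days must be increasing")
        if self.noise not in ("none", "lognormal"):
            raise ValueError("noise must be 'none' or 'lognormal'")


def generate(params_true: ModelParams, design: AssayDesign,
             seed: Optional[int] = None, drug_name: str = "docetaxel") -> list:
    """Simulate the assay and sample noisy counts; deterministic per seed.

    The forward model is the same one the fitting module uses (step death
    rate in the drug condition); lognormal noise is mean-preserving at the
    requested coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    times = tuple(24.0 * d for d in design.days)
    if design.init == "sensitive" and (not times or times[0] != 0.0):
        times = (0.0,) + times
    sig2 = np.log1p(design.cv ** 2)
    sig = np.sqrt(sig2)
    out = []
    for cond in design.conditions:
        # Anchor dataset: exact model mean at the first observation.
        template = GrowthAssayDataset(times, (design.n0,) * len(times), cond,
                                      drug_name if cond == "drug" else "",
                                      design.t_treat, design.init)
        # predicted_total anchors at counts[0]; propagate from n0 at t=0 by
        # prepending the origin when it is absent.
        t_with0 = times if times[0] == 0.0 else (0.0,) + times
        template0 = GrowthAssayDataset(
            t_with0, (design.n0,) * len(t_with0), cond,
            template.drug_name, design.t_treat if cond == "drug" else 72.0,
            design.init)
        mean0 = predicted_total(params_true, template0)
        mean_counts = mean0 if times[0] == 0.0 else mean0[1:]
        for _ in range(design.n_replicates):
            if design.noise == "lognormal" and design.cv > 0:
                mult = np.exp(sig * rng.standard_normal(len(times)) - 0.5 * sig2)
                counts = mean_counts * mult
            else:
                counts = mean_counts.copy()
            out.append(GrowthAssayDataset(times, tuple(counts), cond,
                                          template.drug_name, design.t_treat,
                                          design.init))
    return out
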