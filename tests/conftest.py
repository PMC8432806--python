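"""Shared fixtures: parameter factories and random draws used across tests."""

import numpy as np
import pytest

from phenoswitch.model import GrowthLaw, ModelParams, SwitchingStrategy


def make_params(r_A=0.04, r_B=0.03, d_A=0.01, d_B=0.035, d_A_max=0.2,
                strat_A=(0.9, 0.95, 0.01), strat_B=(0.0, 0.9, 0.01),
                growth=None):
    return ModelParams(
        r_A=r_A, r_B=r_B, d_A=d_A, d_B=d_B, d_A_max=d_A_max,
        strategy_A=SwitchingStrategy(*strat_A),
        strategy_B=SwitchingStrategy(*strat_B),
        growth=growth or GrowthLaw("malthusian"))


def random_params(rng, growth=None, plastic=True):
    """A random plausible Malthusian parameter draw."""
    r_A = rng.uniform(0.01, 0.1)
    r_B = rng.uniform(0.2, 1.0) * r_A
    d_A = rng.uniform(0.0, 0.08)
    d_B = rng.uniform(0.0, 0.08)
    d_A_max = d_A + rng.uniform(0.01, 0.2)
    def strat():
        p_min = rng.uniform(0.0, 0.9) if plastic else 1.0
        p_max = rng.uniform(p_min, 1.0) if plastic else 1.0
        if plastic and p_max >= 0.999:
            p_max = 0.999  # keep strictly plastic (some switching)
        return SwitchingStrategy(p_min, p_max, rng.uniform(1e-3, 0.1))
    return ModelParams(r_A=r_A, r_B=r_B, d_A=d_A, d_B=d_B, d_A_max=d_A_max,
                       strategy_A=strat(), strategy_B=strat(),
                       growth=growth or GrowthLaw("malthusian"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
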