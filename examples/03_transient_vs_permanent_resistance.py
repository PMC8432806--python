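"""Cyclic chemotherapy against the switch and stay inheritance strategies.

Reproduces the qualitative dichotomy of the generic 21-day protocol:
a tolerant pool that relinquishes its phenotype with age ("switch")
yields transient resistance and re-sensitisation after therapy, while
strong retention ("stay") converts the tumour permanently.
"""

import numpy as np

from phenoswitch import run_periodic, scenario, scenario_pk
from phenoswitch.datasets import generic_protocol

proto = generic_protocol()
print(f"protocol: dose {proto['dose']} every {proto['period_days']:g} d, "
      f"days {proto['window_days'][0]:g}-{proto['window_days'][1]:g}")

for name in ("switch", "stay"):
    out = run_periodic(scenario(name), scenario_pk(name), **proto)
    tr = out.trajectory
    w = (tr.times >= proto["window_days"][0] * 24) & \
        (tr.times <= proto["window_days"][1] * 24)
    frac = tr.abar / np.maximum(tr.n_total, 1e-300)
    print(f"{name:6s}: min sensitive fraction during therapy = "
          f"{frac[w].min():.3f}; at day 350 = {frac[-1]:.3f}; "
          f"resistance established = {out.resistance}")
print("switch keeps >40% sensitive cells and reverts after therapy;")
print("stay is driven to a tolerant-dominated state that persists.")
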