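"""Configuration loading and experiment drivers.

A run configuration is a YAML or JSON document with blocks

    seed:       integer (propagated to every stochastic component)
    scenario:   optional named scenario (overridden by `model`)
    model:      flat ModelParams keys (r_A ... growth_mode, K, n)
    pk:         t_half, vol, c_half, t_admin (hours)
    schedule:   start_day, end_day, period_days, dose  (days at the
                interface; converted to hours internally)
    simulate:   t_end_days, n0, n_points
    therapy:    window (days), informed period candidates, d_mtd, n0

Every artifact written by a driver embeds the configuration hash and the
seed so that reruns are reproducible and traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelParams
from .pkpd import PKParams, DoseSchedule
from . import datasets as _datasets

__all__ = ["load_config", "config_hash", "build_model", "build_pk",
           "build_schedule", "run_manifest"]

HOURS = 24.0


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_model(config: dict) -> ModelParams:
    if "model" in config and config["model"]:
        d = dict(config["model"])
        if d.get("K") in ("inf", None):
            d["K"] = float("inf")
        return ModelParams.from_dict(d)
    if "scenario" in config:
        return _datasets.scenario(config["scenario"])
    raise KeyError("config needs a 'model' block or a 'scenario' name")


def build_pk(config: dict) -> Optional[PKParams]:
    if "pk" in config and config["pk"]:
        return PKParams(**config["pk"])
    if "scenario" in config:
        return _datasets.scenario_pk(config["scenario"])
    return None


def build_schedule(config: dict, pk: Optional[PKParams]) -> Optional[DoseSchedule]:
    blk = config.get("schedule")
    if not blk:
        return None
    t_admin = pk.t_admin if pk is not None else 1.0
    return DoseSchedule.periodic(
        float(blk["start_day"]) * HOURS, float(blk["end_day"]) * HOURS,
        float(blk["period_days"]) * HOURS, float(blk["dose"]), t_admin)


def run_manifest(config: dict) -> dict:
    from importlib.metadata import version

    try:
        ver = version("phenoswitch")
    except Exception:
        ver = "unknown"
    return {"config_hash": config_hash(config), "seed": config.get("seed"),
            "package_version": ver}
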