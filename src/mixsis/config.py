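"""Run-configuration loading and validation (YAML or JSON).

A config names the model (``sis`` or ``general``), its parameter block,
the mixing level or grid, and optional solver/simulation settings.
Unknown keys are rejected before any computation runs.

Example (YAML)::

    model: sis
    lambda1: 0.55
    lambda2: 2.0
    m_grid: 201
    seed: 1

    # or raw rates instead of lambdas:
    # p: 1.0
    # upsilon: [0.11, 0.4]
    # delta: [0.2, 0.2]

    # for the general model:
    # model: general
    # units: percent
    # group1: {nu_S: 1, nu_I: 15, delta_I: 60, delta_S: 70}
    # group2: {nu_S: 1, nu_I: 80, delta_I: 1, delta_S: 20}
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .sis_core import EffectiveRates, SISParameters, ValidationError, effective_rates
from .general_contagion import ConditionalRates

_TOP_KEYS = {
    "model", "lambda1", "lambda2", "p", "upsilon", "delta", "m", "m_grid",
    "units", "group1", "group2", "seed", "tol", "n1", "n2", "periods",
    "replicates", "initial_fraction", "heterogeneity_sigma",
}
_GROUP_KEYS = {"nu_S", "nu_I", "delta_I", "delta_S"}


@dataclass
class RunConfig:
    """Validated run configuration."""

    model: str  # "sis" | "general"
    rates: EffectiveRates | None = None
    sis_params: SISParameters | None = None
    group1: ConditionalRates | None = None
    group2: ConditionalRates | None = None
    m: float | None = None
    m_grid: np.ndarray | None = None
    seed: int = 0
    tol: float = 1e-12
    extras: dict | None = None  # simulator settings passthrough


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) in {where}: {sorted(unknown)}")


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config")
    model = data.get("model", "sis")
    if model not in ("sis", "general"):
        raise ValidationError(f"model must be 'sis' or 'general', got {model!r}")

    cfg = RunConfig(model=model, seed=int(data.get("seed", 0)),
                    tol=float(data.get("tol", 1e-12)))

    if model == "sis":
        if "lambda1" in data or "lambda2" in data:
            if not ("lambda1" in data and "lambda2" in data):
                raise ValidationError("lambda1 and lambda2 must come together")
            cfg.rates = EffectiveRates.from_pair(float(data["lambda1"]),
                                                 float(data["lambda2"]))
        elif "p" in data:
            ups = data.get("upsilon")
            dels = data.get("delta")
            if not (isinstance(ups, (list, tuple)) and len(ups) == 2
                    and isinstance(dels, (list, tuple)) and len(dels) == 2):
                raise ValidationError(
                    "raw-rate config needs p, upsilon: [u1, u2], delta: [d1, d2]")
            cfg.sis_params = SISParameters(float(data["p"]), float(ups[0]),
                                           float(ups[1]), float(dels[0]),
                                           float(dels[1]))
            cfg.rates = effective_rates(cfg.sis_params)
        else:
            raise ValidationError("sis config needs lambda1/lambda2 or raw rates")
    else:
        scale = {"percent": 100.0, "fraction": 1.0}
        units = data.get("units", "fraction")
        if units not in scale:
            raise ValidationError("units must be 'percent' or 'fraction'")
        groups = []
        for key in ("group1", "group2"):
            block = data.get(key)
            if not isinstance(block, dict):
                raise ValidationError(f"general config needs a {key} mapping")
            _reject_unknown(block, _GROUP_KEYS, key)
            groups.append(ConditionalRates(
                *(float(block[k]) / scale[units]
                  for k in ("nu_S", "nu_I", "delta_I", "delta_S"))))
        cfg.group1, cfg.group2 = groups

    if "m" in data:
        cfg.m = float(data["m"])
    if "m_grid" in data:
        spec = data["m_grid"]
        if isinstance(spec, int):
            cfg.m_grid = np.linspace(0.0, 1.0, spec)
        else:
            cfg.m_grid = np.asarray(spec, dtype=float)
    cfg.extras = {k: data[k] for k in
                  ("n1", "n2", "periods", "replicates", "initial_fraction",
                   "heterogeneity_sigma") if k in data}
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    return parse_config(data)
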