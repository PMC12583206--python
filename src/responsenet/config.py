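"""YAML run-configuration parsing.

A run config has up to four sections::

    sim:      # SimConfig fields (n_patients, T, d_z, ..., seed)
    model:    # ModelConfig fields except d_x/k (taken from the cohort)
    train:    # TrainConfig fields (epochs, batch_size, lr, ...)
    priors:   # clinical priors:
      anchor: {mean: [...], var: [...]}          # or per-timestep lists
      safe_region: {kind: box, lower: [...], upper: [...]}
      #            {kind: ball, center: [...], radius: r}
      stage_curves: {stageA: [[...], ...]}       # (T, k) per stage
      decay_rho: 0.9
      margin: 0.1
      weights: {lambda1: 0.1, lambda2: 0.1, ...}

Absent sections fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .cohort import ClinicalPriors, SafeRegion
from .model import ModelConfig
from .simulate import SimConfig
from .training import TrainConfig

__all__ = ["load_run_config", "priors_from_dict", "sim_config_from_dict"]


def priors_from_dict(obj: dict | None) -> ClinicalPriors:
    obj = obj or {}
    anchor = obj.get("anchor") or {}
    region = None
    if "safe_region" in obj and obj["safe_region"]:
        r = obj["safe_region"]
        region = SafeRegion(
            kind=r["kind"],
            lower=r.get("lower"),
            upper=r.get("upper"),
            center=r.get("center"),
            radius=r.get("radius"),
        )
    return ClinicalPriors(
        anchor_mean=np.asarray(anchor["mean"]) if "mean" in anchor else None,
        anchor_var=np.asarray(anchor["var"]) if "var" in anchor else None,
        safe_region=region,
        stage_curves={s: np.asarray(c) for s, c in (obj.get("stage_curves") or {}).items()},
        decay_rho=float(obj.get("decay_rho", 1.0)),
        loss_weights=obj.get("weights") or {},
        margin=float(obj.get("margin", 0.1)),
    )


def sim_config_from_dict(obj: dict | None) -> SimConfig:
    return SimConfig(**(obj or {}))


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run config into typed sections.

    Returns {"sim": SimConfig | None, "model": dict, "train": TrainConfig,
    "priors": ClinicalPriors}; the model section stays a dict because d_x/k
    are only known once a cohort is loaded.
    """
    obj = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "sim": sim_config_from_dict(obj["sim"]) if "sim" in obj else None,
        "model": obj.get("model") or {},
        "train": TrainConfig(**(obj.get("train") or {})),
        "priors": priors_from_dict(obj.get("priors")),
    }


def model_config_for_cohort(model_section: dict, d_x: int, k: int) -> ModelConfig:
    return ModelConfig(d_x=d_x, k=k, **model_section)
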