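"""Configuration-file loading for the controller and the synthetic plant.

Accepted layout is a YAML mapping with optional ``controller`` and ``plant``
sections; a flat mapping of controller keys (``target_temp_c``,
``eval_interval_s``, ``scaling_factor``, ``mode``) is also accepted for the
simple controller-only file format.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .controller import ControllerConfig
from .plant import Artifact, PlantConfig

_CONTROLLER_KEYS = {
    "target_temp_c": "target_temp",
    "target_temp": "target_temp",
    "eval_interval_s": "eval_interval",
    "eval_interval": "eval_interval",
    "scaling_factor": "scaling_factor",
    "mode": "mode",
}


def controller_config_from_mapping(mapping: Mapping) -> ControllerConfig:
    kwargs = {}
    for key, value in mapping.items():
        if key not in _CONTROLLER_KEYS:
            raise ValueError(f"unknown controller key {key!r}")
        kwargs[_CONTROLLER_KEYS[key]] = value
    if "eval_interval" in kwargs:
        kwargs["eval_interval"] = int(kwargs["eval_interval"])
    return ControllerConfig(**kwargs)


def plant_config_from_mapping(mapping: Mapping) -> PlantConfig:
    kwargs = dict(mapping)
    schedule = kwargs.pop("artifact_schedule", None)
    if schedule is not None:
        kwargs["artifact_schedule"] = tuple(
            Artifact(*entry) if not isinstance(entry, Mapping) else Artifact(**entry)
            for entry in schedule
        )
    return PlantConfig(**kwargs)


def load_config(path: str | Path) -> tuple[ControllerConfig, PlantConfig]:
    """Load (controller, plant) configs from YAML; absent sections use
    package defaults."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    if "controller" in data or "plant" in data:
        controller = controller_config_from_mapping(data.get("controller") or {})
        plant = plant_config_from_mapping(data.get("plant") or {})
    else:
        controller = controller_config_from_mapping(data)
        plant = PlantConfig()
    return controller, plant
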