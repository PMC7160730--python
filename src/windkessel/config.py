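"""Configuration: one flat key namespace, validated and round-trippable.

Keys use the customary symbol names (``R_DAV``, ``C_a1``, ``k_V1``,
``t_Vmax``, ``K_Vc`` ...) so a configuration file reads like the model's
parameter table.  Unknown keys are rejected by name; an empty file yields
the full default parameterization.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .chambers import AtriumParameters, VentricleParameters
from .circuit import CircuitParameters
from .engine import SimulationConfig

__all__ = ["ModelConfig", "ScenarioSpec", "load_config", "save_config", "config_from_flat"]

log = logging.getLogger("windkessel")

SCHEMA_VERSION = 1


class ScenarioSpec(BaseModel):
    """A named experiment: calibration targets and/or direct activation
    parameter overrides (see :mod:`windkessel.scenarios`)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    target_IVCD_ms: Optional[float] = None
    target_dPdt_max: Optional[float] = None
    t_Vmax: Optional[float] = None
    K_Vc: Optional[float] = None


class ModelConfig(BaseModel):
    """Validated bundle of chamber, circuit, and run parameters."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    schema_version: int = SCHEMA_VERSION
    ventricle: VentricleParameters = Field(default_factory=VentricleParameters)
    atrium: AtriumParameters = Field(default_factory=AtriumParameters)
    circuit: CircuitParameters = Field(default_factory=CircuitParameters)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    scenarios: tuple[ScenarioSpec, ...] = ()

    def to_flat(self) -> dict:
        """Flat key -> value mapping (inverse of :func:`config_from_flat`)."""
        flat: dict = {"schema_version": self.schema_version}
        for section in (self.ventricle, self.atrium, self.circuit, self.simulation):
            flat.update(section.model_dump())
        if self.scenarios:
            flat["scenarios"] = [s.model_dump(exclude_none=True) for s in self.scenarios]
        return flat


_SECTIONS = {
    "ventricle": VentricleParameters,
    "atrium": AtriumParameters,
    "circuit": CircuitParameters,
    "simulation": SimulationConfig,
}


def _key_owner() -> dict:
    owner: dict = {}
    for section, model in _SECTIONS.items():
        for key in model.model_fields:
            owner[key] = section
    return owner


_KEY_OWNER = _key_owner()


def config_from_flat(flat: dict) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a flat key mapping."""
    buckets: dict = {name: {} for name in _SECTIONS}
    scenarios = []
    schema_version = SCHEMA_VERSION
    for key, value in flat.items():
        if key == "schema_version":
            schema_version = int(value)
            if schema_version != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported schema_version {schema_version} "
                    f"(this build reads version {SCHEMA_VERSION})"
                )
        elif key == "scenarios":
            scenarios = [ScenarioSpec(**item) for item in value]
        elif key in _KEY_OWNER:
            buckets[_KEY_OWNER[key]][key] = value
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return ModelConfig(
        schema_version=schema_version,
        ventricle=VentricleParameters(**buckets["ventricle"]),
        atrium=AtriumParameters(**buckets["atrium"]),
        circuit=CircuitParameters(**buckets["circuit"]),
        simulation=SimulationConfig(**buckets["simulation"]),
        scenarios=tuple(scenarios),
    )


def load_config(path) -> ModelConfig:
    """Read a flat YAML configuration file; empty file -> all defaults.

    The effective parameters are echoed to the ``windkessel`` logger so a
    run is reproducible from its log alone.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a flat key/value mapping")
    cfg = config_from_flat(data)
    log.info("effective configuration: %s", cfg.to_flat())
    return cfg


def save_config(cfg: ModelConfig, path) -> None:
    """Write the flat representation; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_flat(), sort_keys=False))
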