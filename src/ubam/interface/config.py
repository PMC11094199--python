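"""Run configuration: schema validation, defaults and round-trippable dumps."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..homogeneous import PARAM_FIELDS, ModelParams

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]

logger = logging.getLogger(__name__)

_INIT_KEYS = {"u", "b", "a", "m"}
_INTEGRATION_KEYS = {"t_end", "dt_out", "rtol", "atol"}
_TOP_KEYS = {"params", "init", "integration", "module", "options", "out_dir", "seed", "log_level"}

_INTEGRATION_DEFAULTS = {"t_end": 1000.0, "dt_out": 1.0, "rtol": 1e-8, "atol": 1e-10}


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


@dataclass
class RunConfig:
    params: ModelParams
    init: dict[str, float]
    integration: dict[str, float]
    module: str | None = None
    options: dict = field(default_factory=dict)
    out_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "init": dict(self.init),
            "integration": dict(self.integration),
            "module": self.module,
            "options": dict(self.options),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _require_mapping(obj, path: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _from_dict(doc: dict) -> RunConfig:
    doc = _require_mapping(doc, "<root>")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"<root>: unknown keys {sorted(unknown)}")
    if "params" not in doc:
        raise ConfigError("params: required block is missing")

    raw_params = _require_mapping(doc["params"], "params")
    unknown = set(raw_params) - set(PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"params: unknown keys {sorted(unknown)}")
    missing = set(PARAM_FIELDS) - set(raw_params)
    if missing:
        raise ConfigError(f"params: missing keys {sorted(missing)}")
    try:
        params = ModelParams.from_dict(raw_params)
    except ValueError as exc:
        raise ConfigError(f"params: {exc}") from exc

    init = _require_mapping(doc.get("init", {}), "init")
    unknown = set(init) - _INIT_KEYS
    if unknown:
        raise ConfigError(f"init: unknown keys {sorted(unknown)}")
    full_init = {
        "u": float(init.get("u", 1.0 - 1e-3)),
        "b": float(init.get("b", 1e-3)),
        "a": float(init.get("a", 0.0)),
        "m": float(init.get("m", params.m0)),
    }

    integration = _require_mapping(doc.get("integration", {}), "integration")
    unknown = set(integration) - _INTEGRATION_KEYS
    if unknown:
        raise ConfigError(f"integration: unknown keys {sorted(unknown)}")
    full_integration = {**_INTEGRATION_DEFAULTS, **{k: float(v) for k, v in integration.items()}}

    seed = doc.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError(f"seed: expected an integer, got {seed!r}")

    return RunConfig(
        params=params,
        init=full_init,
        integration=full_integration,
        module=doc.get("module"),
        options=_require_mapping(doc.get("options", {}), "options"),
        out_dir=doc.get("out_dir"),
        seed=seed,
        log_level=str(doc.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON/YAML config; defaults are filled in."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ConfigError(f"{path}: empty config")
    return _from_dict(doc)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective config as JSON (a YAML subset, so it round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
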