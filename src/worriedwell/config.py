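"""Run configuration: defaults, file loading and validation.

A run configuration merges the package defaults with overrides from a
YAML (or JSON) file or CLI flags.  Unknown keys are rejected and every
override is re-validated through the model's own invariants, so a config
file cannot smuggle in an inadmissible parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import CompartmentState, ModelParameters
from .scenarios import HORIZON_DEFAULT_DAYS, default_parameters, regime
from .simulation import OUTPUT_STEP_DEFAULT

__all__ = ["ConfigError", "RunConfig", "load_config"]

_PARAM_KEYS = ("alpha", "beta_P", "beta_W", "beta_WP", "gamma_P", "gamma_W", "delta_P")
_SEED_KEYS = ("I_P0", "I_W0", "R_P0")
_OTHER_KEYS = (
    "regime",
    "horizon_days",
    "output_step_days",
    "output_dir",
    "seed",
    "verbosity",
)
KNOWN_KEYS = frozenset(_PARAM_KEYS + _SEED_KEYS + _OTHER_KEYS)


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated inputs of one run."""

    params: ModelParameters
    initial_state: CompartmentState
    regime_name: str | None = None
    horizon_days: float = HORIZON_DEFAULT_DAYS
    output_step_days: float = OUTPUT_STEP_DEFAULT
    output_dir: Path = field(default_factory=lambda: Path("."))
    seed: int = 0
    verbosity: int = 1

    def describe(self) -> dict:
        """The complete effective configuration, for logging."""
        return {
            **self.params.as_dict(),
            "S0": self.initial_state.S,
            "I_P0": self.initial_state.I_P,
            "I_W0": self.initial_state.I_W,
            "R_P0": self.initial_state.R_P,
            "regime": self.regime_name,
            "horizon_days": self.horizon_days,
            "output_step_days": self.output_step_days,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
        }


def build_config(overrides: dict) -> RunConfig:
    """Merge ``overrides`` onto the defaults and validate everything.

    The susceptible fraction is always derived as 1 - I_P0 - I_W0 - R_P0.
    """
    unknown = sorted(set(overrides) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys {unknown}")

    regime_name = overrides.get("regime")
    if regime_name is not None:
        params = regime(regime_name, overrides.get("alpha"))
    else:
        params = default_parameters()
        if "alpha" in overrides:
            params = _set_param(params, "alpha", overrides["alpha"])
    for key in _PARAM_KEYS:
        if key == "alpha":
            continue
        if key in overrides:
            params = _set_param(params, key, overrides[key])

    ip0 = float(overrides.get("I_P0", 0.01))
    iw0 = float(overrides.get("I_W0", 0.01))
    rp0 = float(overrides.get("R_P0", 0.0))
    try:
        initial = CompartmentState.from_seeds(ip0, iw0, rp0)
    except ValueError as exc:
        raise ConfigError(f"invalid initial fractions: {exc}") from exc

    horizon = float(overrides.get("horizon_days", HORIZON_DEFAULT_DAYS))
    step = float(overrides.get("output_step_days", OUTPUT_STEP_DEFAULT))
    if horizon <= 0:
        raise ConfigError(f"horizon_days must be positive, got {horizon}")
    if not 0 < step <= horizon:
        raise ConfigError(f"output_step_days must lie in (0, horizon_days], got {step}")

    return RunConfig(
        params=params,
        initial_state=initial,
        regime_name=regime_name,
        horizon_days=horizon,
        output_step_days=step,
        output_dir=Path(overrides.get("output_dir", ".")),
        seed=int(overrides.get("seed", 0)),
        verbosity=int(overrides.get("verbosity", 1)),
    )


def _set_param(params: ModelParameters, key: str, value) -> ModelParameters:
    try:
        return params.replace(**{key: float(value)})
    except ValueError as exc:
        raise ConfigError(f"invalid value for {key}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file (JSON being a YAML subset)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return build_config(raw)
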