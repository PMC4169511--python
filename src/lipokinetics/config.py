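"""Run configuration: YAML loading, validation and preset resolution."""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .parameters import PRESET_VARIANT, PRESETS, ExperimentDesign, RateConstants

__all__ = ["RunConfig", "ConfigError", "load_config"]

_ENGINES = ("ode", "ssa", "hybrid")


class ConfigError(ValueError):
    """Configuration schema violation, reporting the offending key path."""


@dataclass
class RunConfig:
    rates: RateConstants
    variant: str
    design: ExperimentDesign
    engine: str = "hybrid"
    n_cells: int = 1000
    seed: int = 0
    out_dir: str = "results"
    preset: str | None = None


def _check_keys(mapping, allowed, path):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path!r}")


def _build_rates(spec, path):
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise ConfigError(f"unknown preset {spec!r} at {path!r}; available: {sorted(PRESETS)}")
        return PRESETS[spec], PRESET_VARIANT[spec], spec
    if not isinstance(spec, dict):
        raise ConfigError(f"{path!r} must be a preset name or a mapping of rates")
    allowed = [f.name for f in fields(RateConstants)]
    _check_keys(spec, allowed, path)
    required = {"k_A", "k_E", "k_L", "d_E", "k_M"}
    missing = required - set(spec)
    if missing:
        raise ConfigError(f"missing rate(s) {sorted(missing)} at {path!r}")
    for k, v in spec.items():
        if not isinstance(v, (int, float)) or v < 0:
            raise ConfigError(f"rate {path}.{k} must be a number >= 0, got {v!r}")
    return RateConstants(**{k: float(v) for k, v in spec.items()}), None, None


def _build_design(spec, path):
    if not isinstance(spec, dict):
        raise ConfigError(f"{path!r} must be a mapping")
    allowed = [f.name for f in fields(ExperimentDesign)]
    _check_keys(spec, allowed, path)
    if "L_ex0" not in spec:
        raise ConfigError(f"missing key {path}.L_ex0")
    try:
        return ExperimentDesign(**spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid design at {path!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Unknown keys are rejected with their key path; rate presets are
    selectable by name (``streamlined_slow``, ``multilipoplex_fast``,
    ``multilipoplex_slow``) and then also fix the network variant.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    _check_keys(raw, ("rates", "variant", "design", "engine", "n_cells", "seed", "out_dir"), "<top>")
    for key in ("rates", "design"):
        if key not in raw:
            raise ConfigError(f"missing required key {key!r}")

    rates, preset_variant, preset = _build_rates(raw["rates"], "rates")
    variant = raw.get("variant", preset_variant)
    if variant is None:
        raise ConfigError("explicit rates require a 'variant' key")
    if variant not in ("streamlined", "multilipoplex"):
        raise ConfigError(f"unknown variant {variant!r}")
    if preset_variant is not None and variant != preset_variant:
        raise ConfigError(
            f"variant {variant!r} conflicts with preset {raw['rates']!r} ({preset_variant})"
        )
    design = _build_design(raw["design"], "design")
    engine = raw.get("engine", "hybrid")
    if engine not in _ENGINES:
        raise ConfigError(f"unknown engine {engine!r}; expected one of {_ENGINES}")
    n_cells = raw.get("n_cells", 1000)
    if not isinstance(n_cells, int) or n_cells < 1:
        raise ConfigError(f"n_cells must be a positive integer, got {n_cells!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(rates=rates, variant=variant, design=design, engine=engine,
                     n_cells=n_cells, seed=seed, out_dir=str(raw.get("out_dir", "results")),
                     preset=preset)
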