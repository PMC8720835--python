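"""Run-configuration loading, validation and round-tripping (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiment import TreatmentSpec
from .navigators import MODEL_IDS, StrategyParams
from .plume import PlumeParams, SensorParams
from .wind import WindParams

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]

#: Benchmark-table admissible ranges enforced on file-loaded configurations.
RELEASE_RATE_RANGE = (50.0, 200.0)
THRESHOLD_RANGE = (500.0, 2400.0)


class ConfigError(ValueError):
    """A configuration file violated the schema; message names the key path."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one benchmark campaign."""

    wind: WindParams = WindParams(meander_amplitude=0.15)
    plume: PlumeParams = PlumeParams()
    sensor: SensorParams = SensorParams()
    navigators: dict[str, StrategyParams] = field(
        default_factory=lambda: {m: StrategyParams.for_model(m)
                                 for m in MODEL_IDS})
    treatment: TreatmentSpec | None = None
    dt: float = 0.01
    time_cap_factor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.time_cap_factor <= 0:
            raise ConfigError("time_cap_factor must be > 0")


_WIND_KEYS = {"mean_speed", "meander_amplitude", "meander_omega",
              "noise_amplitude", "phase"}
_PLUME_KEYS = {"source_position", "release_rate", "r0", "spread_rate",
               "puff_mass", "transverse_diffusivity"}
_SENSOR_KEYS = {"threshold"}
_NAV_KEYS = {"alpha", "alpha_growth", "surge_time", "cast_time",
             "sweep_multiplier", "cast_half_cycles", "ground_speed"}
_TREATMENT_KEYS = {"variable", "levels", "n_per_model", "models", "seed",
                   "share_plume"}
_TOP_KEYS = {"wind", "plume", "sensor", "navigators", "treatment", "dt",
             "time_cap_factor", "seed"}


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")


def _check_range(value: float, lo: float, hi: float, path: str) -> None:
    if not (lo <= value <= hi):
        raise ConfigError(
            f"'{path}' = {value} outside the benchmark range {lo}-{hi}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Omitted keys take the benchmark defaults (mean wind 1 m/s, meandering
    rate 0.1 rad/s, no wind noise, r0 = 1 mm, release rate 100 puffs/s,
    threshold 620 a.u.).  Unknown keys and out-of-range release rate /
    sensor threshold are rejected with the offending key path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "<top>")
    try:
        wind_d = dict(raw.get("wind", {}))
        _check_keys(wind_d, _WIND_KEYS, "wind")
        wind = WindParams(**wind_d)

        plume_d = dict(raw.get("plume", {}))
        _check_keys(plume_d, _PLUME_KEYS, "plume")
        if "source_position" in plume_d:
            plume_d["source_position"] = tuple(plume_d["source_position"])
        plume = PlumeParams(**plume_d)
        _check_range(plume.release_rate, *RELEASE_RATE_RANGE,
                     "plume.release_rate")

        sensor_d = dict(raw.get("sensor", {}))
        _check_keys(sensor_d, _SENSOR_KEYS, "sensor")
        sensor = SensorParams(**sensor_d)
        _check_range(sensor.threshold, *THRESHOLD_RANGE, "sensor.threshold")

        nav_d = raw.get("navigators", {})
        navigators = {}
        for model in MODEL_IDS:
            overrides = dict(nav_d.get(model, {}))
            _check_keys(overrides, _NAV_KEYS, f"navigators.{model}")
            navigators[model] = StrategyParams.for_model(model, **overrides)
        unknown_models = set(nav_d) - set(MODEL_IDS)
        if unknown_models:
            raise ConfigError(
                f"unknown model(s) {sorted(unknown_models)} under 'navigators'")

        treatment = None
        if "treatment" in raw and raw["treatment"] is not None:
            tr = dict(raw["treatment"])
            _check_keys(tr, _TREATMENT_KEYS, "treatment")
            tr["levels"] = tuple(float(x) for x in tr.get("levels", ()))
            if "models" in tr:
                tr["models"] = tuple(tr["models"])
            treatment = TreatmentSpec(**tr)

        dt = float(raw.get("dt", 0.01))
        if dt <= 0:
            raise ConfigError(f"'dt' must be > 0, got {dt}")
        return RunConfig(wind=wind, plume=plume, sensor=sensor,
                         navigators=navigators, treatment=treatment, dt=dt,
                         time_cap_factor=float(raw.get("time_cap_factor", 50.0)),
                         seed=int(raw.get("seed", 0)))
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: RunConfig) -> dict:
    d: dict = {
        "wind": {k: getattr(cfg.wind, k) for k in sorted(_WIND_KEYS)},
        "plume": {k: (list(getattr(cfg.plume, k))
                      if k == "source_position" else getattr(cfg.plume, k))
                  for k in sorted(_PLUME_KEYS)},
        "sensor": {"threshold": cfg.sensor.threshold},
        "navigators": {m: {k: getattr(p, k) for k in sorted(_NAV_KEYS)}
                       for m, p in cfg.navigators.items()},
        "dt": cfg.dt,
        "time_cap_factor": cfg.time_cap_factor,
        "seed": cfg.seed,
    }
    if cfg.treatment is not None:
        t = cfg.treatment
        d["treatment"] = {"variable": t.variable,
                          "levels": list(t.levels),
                          "n_per_model": t.n_per_model,
                          "models": list(t.models),
                          "seed": t.seed,
                          "share_plume": t.share_plume}
    return d


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig to YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=True))
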