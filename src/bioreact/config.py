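"""Run configuration: defaults, YAML loading, strict validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .hardware import ChannelRole, ChannelTable, PumpConfig
from .ph import CalibrationCurve, SensorModel
from .twin import CultureParams


@dataclass(frozen=True)
class SimConfig:
    """Simulation-side knobs shared by the interpreter and the twin."""

    max_steps: int = 100_000      # executed-instruction guard
    dt_max_h: float = 0.1         # Euler sub-step ceiling for the twin
    reservoir_ml: float = 500.0   # fresh-media reservoir volume
    wall_clock: bool = False      # reserved for real-hardware timing


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulated run needs: pump, channels, twin, sensor, seed."""

    pump: PumpConfig = field(default_factory=PumpConfig)
    channels: ChannelTable = field(default_factory=ChannelTable.default)
    twin: CultureParams = field(default_factory=CultureParams)
    sensor: SensorModel = field(default_factory=SensorModel)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    @classmethod
    def default(cls, n_wells: int = 6, seed: int = 0) -> "RunConfig":
        return cls(channels=ChannelTable.default(n_wells), seed=seed)


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")


def _dataclass_from(section: str, cls, data: dict, **overrides):
    spec = {f.name: f for f in fields(cls)}
    _check_keys(section, data, set(spec))
    coerced = {}
    for key, value in data.items():
        # YAML 1.1 reads exponents like 1.2e6 (no sign) as strings; coerce
        annotation = str(spec[key].type)
        if isinstance(value, str) and annotation in ("int", "float"):
            try:
                value = int(value) if annotation == "int" else float(value)
            except ValueError:
                raise ConfigError(
                    f"{section}.{key}: expected a number, got {value!r}"
                ) from None
        coerced[key] = value
    try:
        return cls(**{**coerced, **overrides})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} configuration: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected.

    Top-level sections: ``pump``, ``channels``, ``twin``, ``sensor``,
    ``sim``, ``seed``.  Every section is optional and falls back to the
    package defaults.  ``channels`` maps channel id -> role
    (well / fresh-media / waste / sensor-line); ``sensor`` takes the
    calibration line (``slope``, ``intercept``, ``ph_low``, ``ph_high``)
    plus ``noise_sd`` and ``quantize_10bit``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("config", raw, {"pump", "channels", "twin", "sensor", "sim", "seed"})

    pump = _dataclass_from("pump", PumpConfig, raw.get("pump", {}))
    twin = _dataclass_from("twin", CultureParams, raw.get("twin", {}))
    sim = _dataclass_from("sim", SimConfig, raw.get("sim", {}))

    sensor_raw = dict(raw.get("sensor", {}))
    _check_keys("sensor", sensor_raw,
                {"slope", "intercept", "ph_low", "ph_high", "noise_sd", "quantize_10bit"})
    default_sensor = SensorModel()
    curve = default_sensor.curve
    curve_keys = {k: sensor_raw.pop(k) for k in ("slope", "intercept", "ph_low", "ph_high")
                  if k in sensor_raw}
    if curve_keys:
        base = {"slope": curve.slope, "intercept": curve.intercept,
                "ph_low": curve.ph_low, "ph_high": curve.ph_high,
                "n_replicates": curve.n_replicates}
        try:
            curve = CalibrationCurve(**{**base, **curve_keys})
        except ValueError as exc:
            raise ConfigError(f"invalid sensor calibration: {exc}") from exc
    sensor = SensorModel(
        curve=curve,
        noise_sd=float(sensor_raw.get("noise_sd", default_sensor.noise_sd)),
        quantize_10bit=bool(sensor_raw.get("quantize_10bit", default_sensor.quantize_10bit)),
    )

    if "channels" in raw:
        chan_raw = raw["channels"]
        if not isinstance(chan_raw, dict):
            raise ConfigError("channels must map channel id -> role")
        table: dict[str, ChannelRole] = {}
        for cid, entry in chan_raw.items():
            role_str = entry.get("role") if isinstance(entry, dict) else entry
            try:
                table[str(cid)] = ChannelRole(role_str)
            except ValueError:
                raise ConfigError(
                    f"channel {cid!r}: unknown role {role_str!r} "
                    f"(expected one of {[r.value for r in ChannelRole]})"
                ) from None
        channels = ChannelTable(table)
    else:
        channels = ChannelTable.default()

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return RunConfig(pump=pump, channels=channels, twin=twin,
                     sensor=sensor, sim=sim, seed=seed)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out as YAML (round-trips through load_config)."""
    data: dict[str, Any] = {
        "seed": config.seed,
        "pump": {
            "capacity_ml": config.pump.capacity_ml,
            "steps_per_ml": config.pump.steps_per_ml,
            "max_rate_ml_min": config.pump.max_rate_ml_min,
            "default_rate_ml_min": config.pump.default_rate_ml_min,
        },
        "channels": {cid: role.value for cid, role in config.channels.channels.items()},
        "twin": {f.name: getattr(config.twin, f.name) for f in fields(CultureParams)},
        "sensor": {
            "slope": config.sensor.curve.slope,
            "intercept": config.sensor.curve.intercept,
            "ph_low": config.sensor.curve.ph_low,
            "ph_high": config.sensor.curve.ph_high,
            "noise_sd": config.sensor.noise_sd,
            "quantize_10bit": config.sensor.quantize_10bit,
        },
        "sim": {f.name: getattr(config.sim, f.name) for f in fields(SimConfig)},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
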