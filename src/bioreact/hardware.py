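"""Device contracts and simulated backends: syringe pump, selector, stirrers.

The physical rig is a stepper-driven syringe pump holding a disposable 10-mL
syringe, a servo selector that routes flow between the pump, the culture
wells, a fresh-media reservoir and the waste line (which carries the
colorimetric pH sensor), and one magnetic stirrer per well.  This module
defines the :class:`DeviceBus` contract those devices present to the script
interpreter, the pump calibration procedure (mass of water dispensed per set
flow rate over a one-minute collection), and two backends:

* :class:`RecordingBus` — a stateless stub that only logs calls; used for
  dry-running and validating scripts.
* :class:`SimulatedBus` — a full closed-loop backend that moves media
  between digital-twin wells, the reservoir and waste, and synthesises
  sensor readings from the media routed past the waste-line sensor.

Direction convention: ``B`` (backward) withdraws/aspirates from the selected
channel into the syringe; ``F`` (forward) dispenses from the syringe to the
selected channel.  This matches a lead-screw pump where backward plunger
travel fills the syringe.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import twin as twin_mod
from .errors import (
    ConfigError,
    DegenerateDesignError,
    OverdrawError,
    SyringeOverfillError,
    SyringeUnderflowError,
    VolumeRangeError,
)
from .ph import SensorModel, SensorReading, make_reading
from .twin import CultureParams, WellState

#: Water density used to convert collected mass to volume in pump calibration.
WATER_DENSITY_G_PER_ML = 1.000

#: Collection time per calibration point (minutes).
CALIBRATION_COLLECT_MIN = 1.0


@dataclass(frozen=True)
class PumpConfig:
    """Syringe-pump geometry and rate limits."""

    capacity_ml: float = 10.0        # disposable 10-mL syringe
    steps_per_ml: int = 800          # stepper steps per mL of plunger travel
    max_rate_ml_min: float = 10.0
    default_rate_ml_min: float = 2.0

    def __post_init__(self) -> None:
        if min(self.capacity_ml, self.steps_per_ml, self.max_rate_ml_min,
               self.default_rate_ml_min) <= 0:
            raise ConfigError("all pump parameters must be strictly positive")
        if self.default_rate_ml_min > self.max_rate_ml_min:
            raise ConfigError("default flow rate exceeds max flow rate")


def volume_to_steps(volume_ml: float, config: PumpConfig) -> int:
    """Motor steps for a plunger travel of ``volume_ml`` (rounded to nearest)."""
    if volume_ml <= 0:
        raise VolumeRangeError("volume must be > 0")
    if volume_ml > config.capacity_ml:
        raise VolumeRangeError(
            f"volume {volume_ml} mL exceeds syringe capacity {config.capacity_ml} mL"
        )
    return int(round(volume_ml * config.steps_per_ml))


def steps_to_volume(steps: int, config: PumpConfig) -> float:
    """Inverse of :func:`volume_to_steps`; exact to half a step quantum."""
    return steps / config.steps_per_ml


@dataclass(frozen=True)
class PumpCalibration:
    """OLS line relating dispensed mass (g/min collection) to set flow rate."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, int, float], ...]  # (set_rate, replicate, mass_g)


def calibrate_pump(points: Iterable[tuple[float, float]]) -> PumpCalibration:
    """Fit the pump calibration line from (set rate mL/min, collected mass g) pairs.

    Each point is one one-minute collection weighed on a balance.  All
    replicates enter a single ordinary least-squares fit.  With an accurate
    pump and water (density ~1 g/mL) the slope is ~1 g per (mL/min).
    """
    pts = [(float(r), float(m)) for r, m in points]
    rates = np.array([p[0] for p in pts])
    masses = np.array([p[1] for p in pts])
    if np.unique(rates).size < 2:
        raise DegenerateDesignError(
            "pump calibration needs >= 2 distinct set-rate levels"
        )
    fit = stats.linregress(rates, masses)
    reps: dict[float, int] = {}
    tagged = []
    for r, m in pts:
        reps[r] = reps.get(r, 0) + 1
        tagged.append((r, reps[r], m))
    return PumpCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=tuple(tagged),
    )


def read_pump_points(path: str | Path) -> list[tuple[float, float]]:
    """Read a pump-calibration CSV ``set_rate_ml_min,replicate,mass_g``."""
    df = pd.read_csv(path)
    need = {"set_rate_ml_min", "mass_g"}
    if not need <= set(df.columns):
        raise ValueError(f"calibration CSV must have columns {sorted(need)}")
    return list(zip(df["set_rate_ml_min"].astype(float), df["mass_g"].astype(float)))


class ChannelRole(str, Enum):
    WELL = "well"
    FRESH_MEDIA = "fresh-media"
    WASTE = "waste"
    SENSOR_LINE = "sensor-line"


@dataclass(frozen=True)
class ChannelTable:
    """Map of selector channel ids to their roles.

    Exactly one fresh-media and one waste channel are required; any number
    of wells.  The selector is exclusive: selecting a channel closes all
    others.
    """

    channels: dict[str, ChannelRole]

    def __post_init__(self) -> None:
        roles = list(self.channels.values())
        if roles.count(ChannelRole.FRESH_MEDIA) != 1:
            raise ConfigError("channel table needs exactly one fresh-media channel")
        if roles.count(ChannelRole.WASTE) != 1:
            raise ConfigError("channel table needs exactly one waste channel")

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def role(self, channel: str) -> ChannelRole:
        try:
            return self.channels[channel]
        except KeyError:
            raise ConfigError(f"unknown channel {channel!r}") from None

    @property
    def fresh(self) -> str:
        return next(c for c, r in self.channels.items() if r is ChannelRole.FRESH_MEDIA)

    @property
    def waste(self) -> str:
        return next(c for c, r in self.channels.items() if r is ChannelRole.WASTE)

    @property
    def wells(self) -> list[str]:
        return [c for c, r in self.channels.items() if r is ChannelRole.WELL]

    @classmethod
    def default(cls, n_wells: int = 6) -> "ChannelTable":
        table = {f"W{i + 1}": ChannelRole.WELL for i in range(n_wells)}
        table["FRESH"] = ChannelRole.FRESH_MEDIA
        table["WASTE"] = ChannelRole.WASTE
        return cls(table)


class DeviceBus(abc.ABC):
    """Contract every hardware backend (simulated or serial) must provide."""

    @abc.abstractmethod
    def run_pump(
        self, volume_ml: float, direction: str, channel: str,
        rate_ml_min: float | None = None,
    ) -> float:
        """Move ``volume_ml`` in ``direction`` via ``channel``; return duration (s)."""

    @abc.abstractmethod
    def set_channel(self, channel: str) -> None:
        """Switch the selector to ``channel`` (closing all others)."""

    @abc.abstractmethod
    def set_stirrer(self, channel: str, on: bool) -> None:
        """Switch the stirrer of ``channel`` on or off."""

    @abc.abstractmethod
    def read_green_intensity(self) -> float:
        """Green-channel intensity of the media currently in the sensor line."""

    def elapse(self, seconds: float) -> None:
        """Advance backend-side time (no-op for stateless backends)."""


def _pump_duration_s(volume_ml: float, rate_ml_min: float) -> float:
    return volume_ml / rate_ml_min * 60.0


@dataclass
class RecordingBus(DeviceBus):
    """Stateless backend that validates volumes and logs every call."""

    pump: PumpConfig = field(default_factory=PumpConfig)
    calls: list[tuple] = field(default_factory=list)

    def run_pump(self, volume_ml, direction, channel, rate_ml_min=None):
        rate = rate_ml_min or self.pump.default_rate_ml_min
        if not 0 < volume_ml <= self.pump.capacity_ml:
            raise VolumeRangeError(f"volume {volume_ml} mL outside (0, capacity]")
        self.calls.append(("pump", volume_ml, direction, channel, rate))
        return _pump_duration_s(volume_ml, rate)

    def set_channel(self, channel):
        self.calls.append(("channel", channel))

    def set_stirrer(self, channel, on):
        self.calls.append(("stir", channel, on))

    def read_green_intensity(self):
        return float("nan")


class SimulatedBus(DeviceBus):
    """Closed-loop simulated backend over digital-twin wells.

    Media moved by the pump is transferred between the twin's wells, the
    fresh-media reservoir and the waste container; every dispense to waste
    routes the aliquot past the colorimetric sensor and logs one
    :class:`~bioreact.ph.SensorReading` attributed to the well the media was
    drawn from.  Culture dynamics advance only while time passes (Wait
    commands and pump runs).
    """

    def __init__(
        self,
        pump: PumpConfig,
        channels: ChannelTable,
        params: CultureParams,
        sensor: SensorModel | None = None,
        wells: dict[str, WellState] | None = None,
        reservoir_ml: float = 500.0,
        seed: int | None = None,
        dt_max_h: float = 0.1,
    ):
        self.pump = pump
        self.channels = channels
        self.params = params
        self.sensor = sensor or SensorModel()
        if wells is None:
            wells = {c: params.initial_well() for c in channels.wells}
        if set(wells) != set(channels.wells):
            raise ConfigError("twin wells must match the channel table's wells")
        self.wells: dict[str, WellState] = dict(wells)
        self.reservoir_ml = float(reservoir_ml)
        self.waste_ml = 0.0
        self.waste_acid = 0.0
        self.syringe_ml = 0.0
        self.syringe_acid = 0.0
        self.syringe_source: str | None = None
        self.active_channel: str | None = None
        self.stirrers: dict[str, bool] = {}
        self.sensor_line_ph = params.fresh_ph
        self.clock_s = 0.0
        self.dt_max_h = dt_max_h
        self.rng = np.random.default_rng(seed)
        self.sensor_log: list[SensorReading] = []
        # trajectory rows: (elapsed_h, well, cells, volume_ml, acid_load, ph)
        self._trajectory: list[tuple[float, str, float, float, float, float]] = []
        self._record_all_wells()

    # -- bookkeeping ---------------------------------------------------

    def _record_all_wells(self) -> None:
        t_h = self.clock_s / 3600.0
        for name, st in self.wells.items():
            self._trajectory.append(
                (t_h, name, st.cells, st.volume_ml, st.acid_load, self.params.ph_of(st))
            )

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._trajectory,
            columns=["elapsed_h", "well", "cells", "volume_ml", "acid_load", "ph"],
        )

    def total_volume_ml(self) -> float:
        """Volume ledger: wells + syringe + reservoir + waste."""
        return (
            sum(w.volume_ml for w in self.wells.values())
            + self.syringe_ml + self.reservoir_ml + self.waste_ml
        )

    def _aliquot_ph(self, volume_ml: float, acid: float) -> float:
        if volume_ml <= 0:
            return self.params.fresh_ph
        return self.params.fresh_ph - acid / (self.params.beta * volume_ml)

    # -- DeviceBus contract --------------------------------------------

    def elapse(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("cannot elapse negative time")
        if seconds == 0:
            return
        dt_h = seconds / 3600.0
        n, h = twin_mod._euler_substeps(dt_h, self.dt_max_h)
        for _ in range(n):
            for name, st in self.wells.items():
                self.wells[name] = twin_mod.advance(st, h, self.params, dt_max_h=h)
            self.clock_s += h * 3600.0
            self._record_all_wells()
        # absorb accumulated float error in the clock
        self.clock_s = round(self.clock_s, 6)

    def set_channel(self, channel: str) -> None:
        self.channels.role(channel)  # raises ConfigError on unknown id
        self.active_channel = channel

    def set_stirrer(self, channel: str, on: bool) -> None:
        if channel not in self.channels and channel not in self.channels.wells:
            # stirrers sit on wells, but tolerate any configured channel id
            self.channels.role(channel)
        self.stirrers[channel] = on

    def read_green_intensity(self) -> float:
        return self.sensor.measure(self.sensor_line_ph, self.rng)

    def run_pump(self, volume_ml, direction, channel=None, rate_ml_min=None) -> float:
        channel = channel or self.active_channel
        if channel is None:
            raise ConfigError("no channel selected for pump run")
        role = self.channels.role(channel)
        rate = rate_ml_min or self.pump.default_rate_ml_min
        if rate > self.pump.max_rate_ml_min:
            raise ConfigError(f"rate {rate} exceeds max {self.pump.max_rate_ml_min}")
        if not 0 < volume_ml <= self.pump.capacity_ml:
            raise VolumeRangeError(f"volume {volume_ml} mL outside (0, capacity]")
        direction = direction.upper()
        if direction == "B":
            self._withdraw(volume_ml, channel, role)
        elif direction == "F":
            self._dispense(volume_ml, channel, role)
        else:
            raise ValueError(f"direction must be 'F' or 'B', got {direction!r}")
        duration = _pump_duration_s(volume_ml, rate)
        self.elapse(duration)
        if direction == "F" and role is ChannelRole.WASTE:
            self._log_sensor_reading()
        return duration

    # -- transfers -----------------------------------------------------

    def _withdraw(self, volume_ml: float, channel: str, role: ChannelRole) -> None:
        if self.syringe_ml + volume_ml > self.pump.capacity_ml + 1e-9:
            raise SyringeOverfillError(
                f"withdrawing {volume_ml} mL would exceed syringe capacity"
            )
        if role is ChannelRole.WELL:
            well = self.wells[channel]
            if volume_ml > well.volume_ml + 1e-9:
                raise OverdrawError(
                    f"cannot withdraw {volume_ml} mL from {channel} "
                    f"holding {well.volume_ml:.3f} mL"
                )
            acid_moved = (
                well.acid_load * volume_ml / well.volume_ml if well.volume_ml > 0 else 0.0
            )
            self.wells[channel] = replace(
                well,
                volume_ml=well.volume_ml - volume_ml,
                acid_load=max(well.acid_load - acid_moved, 0.0),
            )
            self.syringe_acid += acid_moved
        elif role is ChannelRole.FRESH_MEDIA:
            if volume_ml > self.reservoir_ml + 1e-9:
                raise OverdrawError("fresh-media reservoir exhausted")
            self.reservoir_ml -= volume_ml
        else:
            raise ConfigError(f"cannot withdraw from {role.value} channel {channel}")
        self.syringe_ml += volume_ml
        self.syringe_source = channel
        self._record_all_wells()

    def _dispense(self, volume_ml: float, channel: str, role: ChannelRole) -> None:
        if volume_ml > self.syringe_ml + 1e-9:
            raise SyringeUnderflowError(
                f"cannot dispense {volume_ml} mL from a syringe holding "
                f"{self.syringe_ml:.3f} mL"
            )
        acid_out = (
            self.syringe_acid * volume_ml / self.syringe_ml if self.syringe_ml > 0 else 0.0
        )
        if role is ChannelRole.WELL:
            well = self.wells[channel]
            self.wells[channel] = replace(
                well,
                volume_ml=well.volume_ml + volume_ml,
                acid_load=well.acid_load + acid_out,
            )
        elif role is ChannelRole.WASTE:
            self.waste_ml += volume_ml
            self.waste_acid += acid_out
            self.sensor_line_ph = self._aliquot_ph(volume_ml, acid_out)
        elif role is ChannelRole.FRESH_MEDIA:
            self.reservoir_ml += volume_ml  # pushing back to the reservoir
        else:
            raise ConfigError(f"cannot dispense to {role.value} channel {channel}")
        self.syringe_ml = max(self.syringe_ml - volume_ml, 0.0)
        self.syringe_acid = max(self.syringe_acid - acid_out, 0.0)
        self._record_all_wells()

    def _log_sensor_reading(self) -> None:
        intensity = self.read_green_intensity()
        reading = make_reading(
            self.clock_s,
            self.syringe_source or self.channels.waste,
            intensity,
            self.sensor.curve,
        )
        self.sensor_log.append(reading)
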