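"""Colorimetric pH sensing via the phenol-red indicator.

Culture media containing phenol red shifts yellow -> pink as pH rises over
roughly 6.8-8.2; the redder the medium, the more green light it absorbs, so
the green-channel intensity seen by an ambient-light sensor behind the tubing
falls linearly with pH over that window.  This module fits and applies that
straight-line calibration, provides the forward (pH -> intensity) sensor
model used by the simulated device bus, and reads/writes the CSV monitoring
log produced during culture runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationRangeError, DegenerateDesignError

#: pH window over which phenol red changes colour (yellow -> pink) and the
#: linear intensity model is informative.
PHENOL_RED_WINDOW = (6.8, 8.2)

#: Guard band (pH units) beyond the calibration range within which an
#: estimate is still reported rather than suppressed.
RANGE_GUARD_PH = 0.1

LOG_COLUMNS = ["elapsed_s", "channel", "green_intensity", "ph_estimate", "in_range"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Straight line ``intensity = slope * pH + intercept`` with its validity window.

    Parameters
    ----------
    slope : float
        Intensity counts per pH unit; negative for phenol red (more pink =
        less transmitted green light).
    intercept : float
        Intensity counts at pH 0 (extrapolated).
    ph_low, ph_high : float
        pH range spanned by the calibration points; estimates outside
        ``[ph_low - 0.1, ph_high + 0.1]`` are flagged.
    n_replicates : int
        Replicates per level in the calibration design.
    r_squared : float
        Coefficient of determination of the fit (1.0 for an exact line).
    """

    slope: float
    intercept: float
    ph_low: float
    ph_high: float
    n_replicates: int = 1
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if not self.ph_low < self.ph_high:
            raise ValueError("require ph_low < ph_high")
        lo, hi = PHENOL_RED_WINDOW
        if self.ph_low < lo or self.ph_high > hi:
            raise CalibrationRangeError(
                f"calibration range [{self.ph_low}, {self.ph_high}] outside "
                f"phenol-red window [{lo}, {hi}]"
            )

    def in_range(self, ph: float, guard: float = RANGE_GUARD_PH) -> bool:
        """Whether ``ph`` lies within the validity window widened by ``guard``."""
        return (self.ph_low - guard) <= ph <= (self.ph_high + guard)


#: The shipped default calibration: green intensity falls 57.7 counts per pH
#: unit from an extrapolated 1032 counts, fit from DMEM between pH 6.90 and
#: 7.83 with triplicate readings.
DEFAULT_CALIBRATION = CalibrationCurve(
    slope=-57.7, intercept=1032.0, ph_low=6.90, ph_high=7.83, n_replicates=3
)


def fit_calibration(
    ph: Sequence[float], intensity: Sequence[float], n_replicates: int | None = None
) -> CalibrationCurve:
    """Least-squares calibration line over replicate (pH, green-intensity) points.

    All points are pooled into one ordinary least-squares fit of intensity on
    pH.  The validity window of the returned curve is the [min, max] of the
    calibration pH levels.

    Raises
    ------
    CalibrationRangeError
        If any pH level falls outside the phenol-red window (the indicator is
        uninformative there, so such points must not enter the fit).
    DegenerateDesignError
        If fewer than two distinct pH levels are supplied.
    """
    ph = np.asarray(ph, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ph.shape != intensity.shape or ph.ndim != 1:
        raise ValueError("ph and intensity must be 1-D sequences of equal length")
    lo, hi = PHENOL_RED_WINDOW
    bad = (ph < lo) | (ph > hi)
    if bad.any():
        raise CalibrationRangeError(
            f"pH level(s) {sorted(set(np.round(ph[bad], 3)))} outside the "
            f"phenol-red window [{lo}, {hi}]"
        )
    levels = np.unique(ph)
    if levels.size < 2:
        raise DegenerateDesignError(
            "calibration needs >= 2 distinct pH levels, got "
            f"{levels.size}"
        )
    fit = stats.linregress(ph, intensity)
    if n_replicates is None:
        counts = [int(np.sum(ph == lv)) for lv in levels]
        n_replicates = min(counts)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ph_low=float(levels.min()),
        ph_high=float(levels.max()),
        n_replicates=int(n_replicates),
        r_squared=float(fit.rvalue**2),
    )


def intensity_to_ph(intensity: float, curve: CalibrationCurve = DEFAULT_CALIBRATION) -> float:
    """Invert the calibration line: ``pH = (G - b) / a``.

    Values outside the validity window are returned as-is; callers decide how
    to flag them (see :meth:`CalibrationCurve.in_range`).  Monitoring never
    halts on an out-of-window reading.
    """
    return (float(intensity) - curve.intercept) / curve.slope


def ph_to_intensity(
    ph: float,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    quantize_10bit: bool = False,
) -> float:
    """Forward sensor model: expected green intensity at ``ph`` plus optional noise.

    With ``noise_sd`` = 0 this is exactly ``a * pH + b``.  Gaussian noise is
    additive on intensity counts.  ``quantize_10bit`` rounds and clips the
    reading to the 0-1023 range of a 10-bit ADC.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    value = curve.slope * float(ph) + curve.intercept
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        value += rng.normal(0.0, noise_sd)
    if quantize_10bit:
        value = float(np.clip(round(value), 0, 1023))
    return value


@dataclass(frozen=True)
class SensorModel:
    """Bundle of calibration curve + noise parameters used by the simulated bus."""

    curve: CalibrationCurve = DEFAULT_CALIBRATION
    noise_sd: float = 2.0
    quantize_10bit: bool = False

    def measure(self, ph: float, rng: np.random.Generator) -> float:
        return ph_to_intensity(
            ph, self.curve, noise_sd=self.noise_sd, rng=rng,
            quantize_10bit=self.quantize_10bit,
        )


@dataclass(frozen=True)
class SensorReading:
    """One time-stamped pH reading from the waste-line sensor.

    ``ph_estimate`` is ``None`` when the converted value falls outside the
    calibration window by more than the guard band; ``in_range`` reports
    whether it lies strictly inside the window.
    """

    elapsed_s: float
    channel: str
    green_intensity: float
    ph_estimate: float | None
    in_range: bool


def make_reading(
    elapsed_s: float, channel: str, intensity: float,
    curve: CalibrationCurve = DEFAULT_CALIBRATION,
) -> SensorReading:
    """Convert a raw intensity into a flagged :class:`SensorReading`."""
    ph = intensity_to_ph(intensity, curve)
    in_range = curve.ph_low <= ph <= curve.ph_high
    estimate = ph if curve.in_range(ph) else None
    return SensorReading(
        elapsed_s=float(elapsed_s),
        channel=channel,
        green_intensity=float(intensity),
        ph_estimate=estimate,
        in_range=in_range,
    )


def readings_to_frame(readings: Iterable[SensorReading]) -> pd.DataFrame:
    rows = [
        (r.elapsed_s, r.channel, r.green_intensity, r.ph_estimate, r.in_range)
        for r in readings
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(readings: Sequence[SensorReading], path: str | Path) -> None:
    """Write the monitoring log as CSV, one row per reading (header always present)."""
    readings_to_frame(readings).to_csv(path, index=False)


def read_log(path: str | Path) -> list[SensorReading]:
    """Read a monitoring-log CSV back into :class:`SensorReading` objects.

    Raises ``ValueError`` naming the offending data line on malformed rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log is missing column(s) {missing}")
    out: list[SensorReading] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ph_est = row.ph_estimate
            ph_est = None if pd.isna(ph_est) else float(ph_est)
            out.append(
                SensorReading(
                    elapsed_s=float(row.elapsed_s),
                    channel=str(row.channel),
                    green_intensity=float(row.green_intensity),
                    ph_estimate=ph_est,
                    in_range=bool(row.in_range),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed log row at line {i}: {exc}") from exc
    return out
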