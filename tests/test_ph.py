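"""Colorimetric pH calibration, conversion and the monitoring log."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioreact import (
    DEFAULT_CALIBRATION,
    CalibrationCurve,
    fit_calibration,
    intensity_to_ph,
    ph_to_intensity,
    read_log,
    write_log,
)
from bioreact.errors import CalibrationRangeError, DegenerateDesignError
from bioreact.ph import make_reading

# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_the_shipped_dmem_line_exactly():
    # noise-free points on the shipped line: green = -57.7 * pH + 1032
    levels = [6.90, 7.40, 7.83]
    ph = np.repeat(levels, 3)
    g = -57.7 * ph + 1032.0
    curve = fit_calibration(ph, g)
    assert curve.slope == pytest.approx(-57.7, abs=1e-9)
    assert curve.intercept == pytest.approx(1032.0, abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
    assert (curve.ph_low, curve.ph_high) == (6.90, 7.83)


def test_fit_single_level_is_degenerate():
    with pytest.raises(DegenerateDesignError):
        fit_calibration([7.0, 7.0, 7.0], [628.1, 628.0, 628.2])


def test_fit_rejects_levels_outside_phenol_red_window():
    with pytest.raises(CalibrationRangeError):
        fit_calibration([6.5, 7.4], [1000.0, 605.0])


def test_fit_recovers_slope_under_sensor_noise(rng):
    # 5 levels x 3 replicates, Gaussian noise sd 2 counts on intensity
    levels = np.array([6.90, 7.10, 7.30, 7.55, 7.83])
    ph = np.repeat(levels, 3)
    g = -57.7 * ph + 1032.0 + rng.normal(0, 2.0, size=ph.size)
    curve = fit_calibration(ph, g)
    assert curve.slope == pytest.approx(-57.7, abs=2.0)
    assert curve.n_replicates == 3


# ---------------------------------------------------------------------------
# conversion


def test_intensity_605_is_ph_7p40():
    assert intensity_to_ph(605.02) == pytest.approx(7.40, abs=1e-9)


@pytest.mark.parametrize("ph_value, expected", [(7.83, 580.209), (6.90, 633.87)])
def test_forward_model_on_the_printed_line(ph_value, expected):
    assert ph_to_intensity(ph_value, noise_sd=0.0) == pytest.approx(expected, abs=1e-9)


def test_intercept_reading_maps_to_ph_zero_and_is_flagged():
    value = intensity_to_ph(DEFAULT_CALIBRATION.intercept)
    assert value == pytest.approx(0.0, abs=1e-12)
    assert not DEFAULT_CALIBRATION.in_range(value)


@settings(derandomize=True, max_examples=200)
@given(st.floats(6.8, 8.2))
def test_round_trip_is_identity_on_the_window(ph_value):
    back = intensity_to_ph(ph_to_intensity(ph_value, noise_sd=0.0))
    assert back == pytest.approx(ph_value, abs=1e-9)


def test_intensity_strictly_decreases_with_ph():
    grid = np.linspace(6.8, 8.2, 50)
    g = [ph_to_intensity(p, noise_sd=0.0) for p in grid]
    assert all(a > b for a, b in zip(g, g[1:]))


def test_noise_is_seeded_and_unbiased():
    rng = np.random.default_rng(7)
    draws = [ph_to_intensity(7.4, noise_sd=2.0, rng=rng) for _ in range(10_000)]
    # CLT: mean of 10k draws at sd 2 lies within ~3 se of 605.02
    assert np.mean(draws) == pytest.approx(605.02, abs=0.06)
    rng2 = np.random.default_rng(7)
    assert ph_to_intensity(7.4, noise_sd=2.0, rng=rng2) == draws[0]


def test_quantized_mode_yields_10bit_integers():
    rng = np.random.default_rng(0)
    v = ph_to_intensity(7.4, noise_sd=2.0, rng=rng, quantize_10bit=True)
    assert v == int(v) and 0 <= v <= 1023


# ---------------------------------------------------------------------------
# validity window / flagging


def test_out_of_window_reading_is_flagged_not_errored():
    reading = make_reading(0.0, "W1", 1000.0)  # pH ~0.55: far below the window
    assert reading.ph_estimate is None
    assert reading.in_range is False


def test_in_window_reading_keeps_estimate():
    g = ph_to_intensity(7.4, noise_sd=0.0)
    reading = make_reading(10.0, "W1", g)
    assert reading.ph_estimate == pytest.approx(7.4, abs=1e-9)
    assert reading.in_range is True


def test_curve_invariants():
    with pytest.raises(ValueError):
        CalibrationCurve(slope=0.0, intercept=1.0, ph_low=6.9, ph_high=7.8)
    with pytest.raises(CalibrationRangeError):
        CalibrationCurve(slope=-57.7, intercept=1032, ph_low=6.0, ph_high=7.8)


# ---------------------------------------------------------------------------
# log I/O


def test_empty_log_is_header_only(tmp_path):
    path = tmp_path / "log.csv"
    write_log([], path)
    assert path.read_text().strip() == "elapsed_s,channel,green_intensity,ph_estimate,in_range"
    assert read_log(path) == []


def test_log_round_trip(tmp_path, rng):
    readings = []
    t = 0.0
    for i in range(20):
        t += float(rng.integers(1, 100))
        g = ph_to_intensity(float(rng.uniform(6.9, 7.8)), noise_sd=2.0, rng=rng)
        readings.append(make_reading(t, f"W{i % 6 + 1}", g))
    # include an out-of-window reading with a suppressed estimate
    readings.append(make_reading(t + 1, "W1", 1000.0))
    path = tmp_path / "log.csv"
    write_log(readings, path)
    back = read_log(path)
    assert len(back) == len(readings)
    for a, b in zip(readings, back):
        assert a.elapsed_s == b.elapsed_s and a.channel == b.channel
        assert a.green_intensity == pytest.approx(b.green_intensity, abs=1e-9)
        if a.ph_estimate is None:
            assert b.ph_estimate is None
        else:
            assert a.ph_estimate == pytest.approx(b.ph_estimate, abs=1e-9)
        assert a.in_range == b.in_range


def test_malformed_log_row_names_the_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "elapsed_s,channel,green_intensity,ph_estimate,in_range\n"
        "0.0,W1,605.0,7.4,True\n"
        "oops,W1,not-a-number,7.4,True\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_log(path)
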