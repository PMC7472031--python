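"""Streaming in-space detector: calibration, state machine, full-trace runs."""

import numpy as np
import pytest

from ianeedle.detector import (
    IN_SPACE,
    SEARCHING,
    Detector,
    DetectorConfig,
    calibrate,
    detect_trace,
)
from ianeedle.joints import JOINT_REFERENCE
from ianeedle.simulate import calibration_segment, default_scenario, simulate_trace
from ianeedle.trace import ImpedanceTrace

FS = 33.0


def make_trace(values, fs=FS):
    values = np.asarray(values, dtype=float)
    return ImpedanceTrace(np.arange(values.size) / fs, values)


def test_config_requires_exactly_one_limits_source():
    with pytest.raises(ValueError, match="exactly one"):
        DetectorConfig()
    with pytest.raises(ValueError, match="exactly one"):
        DetectorConfig(reference=(1500.0, 50.0), calibration_window=(0.0, 5.0))
    DetectorConfig(reference=(1500.0, 50.0))
    DetectorConfig(calibration_window=(0.0, 5.0))


def test_calibrate_constant_segment_collapses_limits():
    config = DetectorConfig(reference=(0.0, 1.0))
    limits = calibrate(make_trace(np.full(50, 1537.3)), config)
    assert limits.cl == pytest.approx(1537.3, rel=1e-9)
    assert limits.ucl == pytest.approx(1537.3, rel=1e-9)
    assert limits.lcl == pytest.approx(1537.3, rel=1e-9)
    assert limits.n == 50


def test_calibrate_recovers_generator_mean_within_sampling_error():
    mu, sigma = JOINT_REFERENCE["right_knee"]
    sim = calibration_segment("right_knee", n_samples=242, seed=7)
    config = DetectorConfig(reference=(mu, sigma))
    limits = calibrate(sim.trace, config)
    assert abs(limits.mu - mu) < 3.0 * sigma / np.sqrt(242)


def test_calibrate_on_filtered_data_shrinks_sigma(rng):
    noise = make_trace(1500.0 + 50.0 * rng.standard_normal(500))
    filtered_cfg = DetectorConfig(reference=(0.0, 1.0), filter_enabled=True)
    raw_cfg = DetectorConfig(reference=(0.0, 1.0), filter_enabled=False)
    assert calibrate(noise, filtered_cfg).sigma < calibrate(noise, raw_cfg).sigma


def test_calibrate_rejects_short_segment():
    config = DetectorConfig(reference=(0.0, 1.0))
    with pytest.raises(ValueError):
        calibrate(make_trace([1500.0]), config)


def test_debounce_entry_on_nth_consecutive_sample():
    config = DetectorConfig(reference=(1500.0, 50.0), debounce=10)
    det = Detector(config)
    for i in range(9):
        rec = det.process_sample(i / FS, 1500.0)
        assert rec.state == SEARCHING
    rec = det.process_sample(9 / FS, 1500.0)
    assert rec.state == IN_SPACE


def test_single_violation_exits_immediately():
    # Raw mode isolates the state-machine contract from filter smoothing.
    config = DetectorConfig(reference=(1500.0, 50.0), debounce=5,
                            filter_enabled=False)
    det = Detector(config)
    for i in range(10):
        det.process_sample(i / FS, 1500.0)
    assert det.state == IN_SPACE
    rec = det.process_sample(10 / FS, 1500.0 + 10 * 50.0)
    assert rec.state == SEARCHING
    assert not rec.in_control
    assert len(det.events) == 1


def test_stream_fold_equals_batch_bitwise(rng):
    config = DetectorConfig.for_joint("right_knee")
    sim = simulate_trace(default_scenario("right_knee", seed=3))
    result = detect_trace(sim.trace, config)
    det = Detector(config)
    records = [det.process_sample(t, m)
               for t, m in zip(sim.trace.times, sim.trace.magnitudes)]
    assert np.array_equal(result.filtered, np.array([r.filtered for r in records]))
    assert np.array_equal(result.in_control, np.array([r.in_control for r in records]))
    assert list(result.states) == [r.state for r in records]
    assert result.events == det.finalize_events()


def test_non_monotone_timestamps_rejected():
    det = Detector(DetectorConfig(reference=(1500.0, 50.0)))
    det.process_sample(0.0, 1500.0)
    with pytest.raises(ValueError, match="non-monotone"):
        det.process_sample(0.0, 1500.0)


def test_sampling_rate_mismatch_names_both_rates():
    config = DetectorConfig(reference=(1500.0, 50.0), sampling_rate=33.0)
    trace = make_trace(np.full(100, 1500.0), fs=25.0)
    with pytest.raises(ValueError, match="25") as excinfo:
        detect_trace(trace, config)
    assert "33" in str(excinfo.value)


def test_trace_entirely_above_ucl_yields_no_events():
    config = DetectorConfig(reference=(1500.0, 50.0))
    result = detect_trace(make_trace(np.full(200, 2500.0)), config)
    assert result.events == []
    assert not result.in_control.any()


def test_trace_at_center_line_yields_one_full_interval():
    config = DetectorConfig(reference=(1500.0, 50.0), debounce=10)
    trace = make_trace(np.full(200, 1500.0))
    result = detect_trace(trace, config)
    assert len(result.events) == 1
    entry, exit_ = result.events[0]
    assert entry == pytest.approx(trace.times[9])  # debounce ramp-in
    assert exit_ == pytest.approx(trace.times[-1])


def test_default_scenario_single_interval_with_expected_timing():
    scenario = default_scenario("right_knee", seed=11)
    sim = simulate_trace(scenario)
    result = detect_trace(sim.trace, DetectorConfig.for_joint("right_knee"))
    assert len(result.events) == 1
    entry, exit_ = result.events[0]
    # Entry while the needle descends toward the cavity; exit after the
    # dye rise crosses the upper control limit at ~27.98 s.
    assert 10.77 < entry < 22.89
    assert exit_ > 27.98


def test_detection_latency_within_analytic_bound():
    config = DetectorConfig(reference=(1500.0, 50.0), debounce=10)
    spec = config.filter_spec()
    step_index = 50
    values = np.concatenate([np.full(step_index, 1500.0 + 20 * 50.0),
                             np.full(150, 1500.0)])
    result = detect_trace(make_trace(values), config)
    assert len(result.events) == 1
    entry_index = int(round(result.events[0][0] * FS))
    settle = int(np.ceil(-np.log(0.01) / np.log(1.0 / abs(spec.a_coeffs[1]))))
    assert entry_index - step_index <= config.debounce + settle


def test_raw_mode_skips_filtering(rng):
    trace = make_trace(1500.0 + 50.0 * rng.standard_normal(300))
    config = DetectorConfig(reference=(1500.0, 50.0), filter_enabled=False)
    result = detect_trace(trace, config)
    assert np.array_equal(result.filtered, trace.magnitudes)


def test_calibration_window_mode_runs_end_to_end():
    rng = np.random.default_rng(5)
    values = np.concatenate([
        np.full(100, 2500.0),
        1500.0 + 5.0 * rng.standard_normal(300),
    ])
    trace = make_trace(values)
    config = DetectorConfig(
        calibration_window=(150 / FS, 350 / FS), debounce=10
    )
    result = detect_trace(trace, config)
    assert result.limits.cl == pytest.approx(1500.0, abs=2.0)
    assert len(result.events) == 1
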