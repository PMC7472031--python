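"""Synthetic trace generator, saline depth model, and evaluation harness."""

import numpy as np
import pytest

from ianeedle.detector import DetectorConfig
from ianeedle.filtering import design_lowpass, filter_samples
from ianeedle.joints import JOINT_REFERENCE
from ianeedle.simulate import (
    BreathingArtifact,
    SalineModel,
    ScenarioSpec,
    Segment,
    calibration_segment,
    default_scenario,
    evaluate_detector,
    simulate_saline_depth,
    simulate_trace,
)


def test_default_scenario_schedule_and_sample_count():
    scenario = default_scenario("right_knee")
    starts = [s.start for s in scenario.segments]
    ends = [s.end for s in scenario.segments]
    labels = [s.label for s in scenario.segments]
    assert labels == ["subcutaneous", "transition", "intra_articular", "dye_injection"]
    assert starts == [0.0, 10.77, 22.89, 22.98]
    assert ends == [10.77, 22.89, 22.98, 32.0]
    assert len(simulate_trace(scenario).trace) == 1056  # 32 s at 33 S/s


@pytest.mark.parametrize("joint,mu,sigma", [
    ("right_knee", 1537.3, 88.5),
    ("left_knee", 1367.2, 8.0),
    ("right_elbow", 2012.5, 7.4),
    ("left_elbow", 2001.8, 12.6),
])
def test_default_scenario_uses_reference_joint_statistics(joint, mu, sigma):
    scenario = default_scenario(joint)
    intra = next(s for s in scenario.segments if s.label == "intra_articular")
    assert intra.mean == mu
    if joint == "right_knee":
        # SD split into breathing sinusoid (5% of mean) + Gaussian remainder.
        breathing = [a for a in scenario.artifacts if isinstance(a, BreathingArtifact)]
        assert len(breathing) == 1
        sine_sd = breathing[0].amplitude / np.sqrt(2.0)
        assert np.hypot(intra.sd, sine_sd) == pytest.approx(sigma, rel=1e-9)
    else:
        assert intra.sd == sigma


def test_unknown_joint_rejected():
    with pytest.raises(ValueError, match="unknown joint"):
        default_scenario("left_shoulder")


def test_identical_seeds_reproduce_traces_bitwise():
    a = simulate_trace(default_scenario("left_knee", seed=42))
    b = simulate_trace(default_scenario("left_knee", seed=42))
    assert np.array_equal(a.trace.magnitudes, b.trace.magnitudes)
    assert np.array_equal(a.clean, b.clean)
    c = simulate_trace(default_scenario("left_knee", seed=43))
    assert not np.array_equal(a.trace.magnitudes, c.trace.magnitudes)


def test_intra_articular_statistics_recovered_across_seeds():
    mu, sigma = JOINT_REFERENCE["left_knee"]
    means, sds = [], []
    for seed in range(30):
        seg = calibration_segment("left_knee", n_samples=242, seed=seed)
        means.append(seg.trace.magnitudes.mean())
        sds.append(seg.trace.magnitudes.std(ddof=1))
    se_mean = sigma / np.sqrt(242 * 30)
    assert abs(np.mean(means) - mu) < 3 * se_mean
    se_sd = sigma / np.sqrt(2 * 241 * 30)
    assert abs(np.mean(sds) - sigma) < 3 * se_sd + 0.01 * sigma


def test_right_knee_total_sd_includes_breathing():
    mu, sigma = JOINT_REFERENCE["right_knee"]
    sds = [
        calibration_segment("right_knee", n_samples=242, seed=seed)
        .trace.magnitudes.std(ddof=1)
        for seed in range(30)
    ]
    assert np.mean(sds) == pytest.approx(sigma, rel=0.10)


def test_segment_labels_follow_schedule():
    sim = simulate_trace(default_scenario("right_knee"))
    t = sim.trace.times
    assert set(sim.labels[t < 10.77]) == {"subcutaneous"}
    assert set(sim.labels[(t >= 10.77) & (t < 22.89)]) == {"transition"}
    assert set(sim.labels[(t >= 22.89) & (t < 22.98)]) == {"intra_articular"}
    assert set(sim.labels[t >= 22.98]) == {"dye_injection"}


def test_spike_artifact_visible_raw_suppressed_filtered():
    scenario = default_scenario("left_knee", seed=2)
    sim = simulate_trace(scenario)
    spike_idx = int(np.argmin(np.abs(sim.trace.times - 15.0)))
    transition_sd = scenario.segments[1].sd
    raw_dev = abs(sim.trace.magnitudes[spike_idx] - sim.clean[spike_idx])
    assert raw_dev > 5 * transition_sd
    # The low-pass filter must knock the spike down by at least 80%.
    spec = design_lowpass(1, 0.04)
    no_spike = ScenarioSpec(
        segments=scenario.segments, artifacts=(), seed=scenario.seed
    )
    base = simulate_trace(no_spike)
    with_f = filter_samples(sim.trace.magnitudes, spec)
    without_f = filter_samples(base.trace.magnitudes, spec)
    filtered_dev = np.max(np.abs(with_f - without_f))
    spike_amp = scenario.artifacts[0].amplitude
    assert filtered_dev < 0.2 * spike_amp


def test_dye_rise_crosses_ucl_at_sharp_rise_time():
    for joint in JOINT_REFERENCE:
        scenario = default_scenario(joint)
        sim = simulate_trace(scenario)
        mu, sigma = JOINT_REFERENCE[joint]
        ucl = mu + 3 * sigma
        crossed = sim.trace.times[sim.clean > ucl]
        dye_crossings = crossed[crossed > 22.98]
        assert dye_crossings.size > 0
        assert dye_crossings[0] == pytest.approx(27.98, abs=1.0 / 33.0 + 1e-9)


def test_scenario_segments_must_be_contiguous():
    with pytest.raises(ValueError, match="contiguous"):
        ScenarioSpec(segments=(
            Segment("subcutaneous", 0.0, 5.0, 2500.0, 10.0),
            Segment("intra_articular", 6.0, 10.0, 1500.0, 10.0),
        ))


def test_saline_model_depth_invariance_is_exact():
    model = SalineModel(solution_resistance=150.0, cpe_magnitude=5e3, cpe_exponent=0.8)
    spectra = simulate_saline_depth(model, [2.0, 4.0, 6.0], [100_000.0])
    mags = [s.magnitudes[0] for s in spectra]
    assert mags[0] == mags[1] == mags[2]  # machine-precision identical


def test_saline_cpe_dispersion_and_flat_limit():
    model = SalineModel(150.0, 5e3, 0.8)
    (spectrum,) = simulate_saline_depth(model, [2.0], [10.0, 100_000.0])
    assert spectrum.magnitudes[0] > spectrum.magnitudes[1]
    nearly_resistive = SalineModel(150.0, 1e-9, 1.0)
    (flat,) = simulate_saline_depth(nearly_resistive, [2.0], [10.0, 100_000.0])
    assert np.allclose(flat.magnitudes, 150.0, rtol=1e-3)


def test_saline_rejects_empty_or_invalid_inputs():
    model = SalineModel(150.0, 5e3, 0.8)
    with pytest.raises(ValueError):
        simulate_saline_depth(model, [], [100.0])
    with pytest.raises(ValueError):
        simulate_saline_depth(model, [2.0], [])
    with pytest.raises(ValueError):
        simulate_saline_depth(model, [-2.0], [100.0])
    with pytest.raises(ValueError):
        SalineModel(150.0, 5e3, 1.5)


def noiseless_scenario(joint="right_knee"):
    scenario = default_scenario(joint)
    segments = tuple(
        Segment(s.label, s.start, s.end, s.mean, 0.0, s.shape,
                rise_tau=s.rise_tau, rise_amplitude=s.rise_amplitude)
        for s in scenario.segments
    )
    return ScenarioSpec(segments=segments, artifacts=(), seed=scenario.seed)


def test_noiseless_scenario_classified_perfectly():
    config = DetectorConfig.for_joint("right_knee")
    result = evaluate_detector(config, noiseless_scenario(), n_traces=3,
                               guard_band=0.5, base_seed=0)
    assert result.accuracy == 1.0


def test_all_in_band_scenario_has_zero_specificity():
    mu, _ = JOINT_REFERENCE["right_knee"]
    scenario = ScenarioSpec(
        segments=(
            Segment("subcutaneous", 0.0, 5.0, mu, 5.0),
            Segment("intra_articular", 5.0, 10.0, mu, 5.0),
        ),
        seed=1,
    )
    config = DetectorConfig.for_joint("right_knee")
    result = evaluate_detector(config, scenario, n_traces=2, guard_band=0.5)
    assert result.specificity == 0.0
    assert result.tn == 0


def test_evaluate_requires_intra_articular_segment():
    scenario = ScenarioSpec(
        segments=(Segment("subcutaneous", 0.0, 5.0, 2500.0, 10.0),), seed=0
    )
    config = DetectorConfig.for_joint("right_knee")
    with pytest.raises(ValueError, match="intra_articular"):
        evaluate_detector(config, scenario, n_traces=1)


def test_evaluation_deterministic_given_seed():
    config = DetectorConfig.for_joint("left_knee")
    scenario = default_scenario("left_knee")
    a = evaluate_detector(config, scenario, n_traces=5, base_seed=9)
    b = evaluate_detector(config, scenario, n_traces=5, base_seed=9)
    assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)
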