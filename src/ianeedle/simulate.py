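"""Synthetic needle-insertion traces and a detector evaluation harness.

The generator reproduces the statistical structure of the in vivo recordings
this package's detector was designed around: a 33 S/s impedance-magnitude
stream that starts high in subcutaneous tissue, ramps down as the needle
travels toward the joint cavity, sits at the joint's intra-articular
(mean, SD) while the tip rests in synovial fluid, and rises — slowly at
first, then sharply — once contrast dye displaces the conductive fluid.
Hand-movement spikes and (for the right knee) a 0.3 Hz breathing oscillation
are added as artifacts.  Everything is deterministic given a seed.

Timeline of the default scenario (seconds from stream start):

* 0 – 10.77     subcutaneous tissue, high constant mean (2500 ohm default)
* 10.77 – 22.89 transition: linear ramp down to the joint mean
* 22.89 – 22.98 intra-articular dwell at the joint (mean, SD)
* 22.98 – 32    dye injection: accelerating exponential rise from the joint
                mean, crossing the +3 sigma limit at 27.98 s and plateauing
* spike at 15 s (clinician hand movement), +800 ohm for one sample
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import DetectorConfig, detect_trace
from .joints import BREATHING_SD_FRACTION, JOINT_SAMPLE_COUNT, joint_reference
from .trace import ImpedanceTrace

__all__ = [
    "Segment",
    "SpikeArtifact",
    "BreathingArtifact",
    "ScenarioSpec",
    "SimulatedTrace",
    "SalineModel",
    "EvaluationResult",
    "default_scenario",
    "calibration_segment",
    "simulate_trace",
    "simulate_saline_depth",
    "evaluate_detector",
]

SEGMENT_LABELS = ("subcutaneous", "transition", "intra_articular", "dye_injection")
SEGMENT_SHAPES = ("constant", "linear_ramp", "exponential_rise")

# Default scenario constants (ohms / seconds).  The subcutaneous level is a
# representative high-impedance value — the in vivo recordings report it only
# qualitatively ("very high") — and is freely configurable.
SUBCUTANEOUS_MEAN = 2500.0
SUBCUTANEOUS_SD = 100.0
TRANSITION_SD = 50.0
DYE_PLATEAU = 3000.0
DYE_RISE_TAU = 0.5
SUBCUTANEOUS_END = 10.77
TRANSITION_END = 22.89
INTRA_ARTICULAR_END = 22.98
SCENARIO_END = 32.0
SHARP_RISE_TIME = 27.98
SPIKE_TIME = 15.0
SPIKE_AMPLITUDE = 800.0
BREATHING_FREQUENCY = 0.3


@dataclass(frozen=True)
class Segment:
    """One tissue phase of the insertion timeline.

    ``mean`` is the segment's level: the constant value, the ramp's end
    value (ramping from the previous segment's final level), or the plateau
    cap of an exponential rise.  ``sd`` is the per-sample Gaussian noise SD.
    For ``exponential_rise``, the mean path is
    ``prev + rise_amplitude * (exp((t - start)/rise_tau) - 1)`` capped at
    ``mean`` — slow at first, then sharp, as a dye front displacing synovial
    fluid behaves.
    """

    label: str
    start: float
    end: float
    mean: float
    sd: float
    shape: str = "constant"
    rise_tau: float | None = None
    rise_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.shape not in SEGMENT_SHAPES:
            raise ValueError(f"unknown segment shape {self.shape!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.sd < 0:
            raise ValueError("segment sd must be >= 0")
        if self.shape == "exponential_rise" and (
            self.rise_tau is None or self.rise_amplitude is None
        ):
            raise ValueError("exponential_rise requires rise_tau and rise_amplitude")


@dataclass(frozen=True)
class SpikeArtifact:
    """Additive single-sample excursion (hand movement) at ``time``."""

    time: float
    amplitude: float = SPIKE_AMPLITUDE


@dataclass(frozen=True)
class BreathingArtifact:
    """Additive sinusoid active on [start, end]; phase 0 at window start."""

    start: float
    end: float
    amplitude: float
    frequency: float = BREATHING_FREQUENCY
    phase: float = 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Ordered, contiguous tissue segments plus artifact events and a seed."""

    segments: tuple[Segment, ...]
    artifacts: tuple = ()
    sampling_rate: float = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "artifacts", tuple(self.artifacts))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if abs(cur.start - prev.end) > 1e-9:
                raise ValueError(
                    f"segments must be contiguous: {prev.label} ends at {prev.end}, "
                    f"{cur.label} starts at {cur.start}"
                )

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def has_label(self, label: str) -> bool:
        return any(s.label == label for s in self.segments)


@dataclass(frozen=True)
class SimulatedTrace:
    """A synthetic trace with its per-sample ground truth.

    ``labels`` gives each sample's true tissue segment; ``clean`` the
    noiseless, artifact-free mean trajectory the noise was added to.
    """

    trace: ImpedanceTrace
    labels: np.ndarray
    clean: np.ndarray
    scenario: ScenarioSpec


@dataclass(frozen=True)
class SalineModel:
    """Monopolar needle in saline: solution resistance + electrode CPE.

    Because the needle shaft is insulated and only the tip is exposed, the
    effective electrode area — hence the impedance — does not change with
    immersion depth.  Z(f) = R_s + Q * (j 2 pi f)^(-alpha).
    """

    solution_resistance: float
    cpe_magnitude: float
    cpe_exponent: float

    def __post_init__(self) -> None:
        if self.solution_resistance < 0:
            raise ValueError("solution_resistance must be >= 0")
        if self.cpe_magnitude < 0:
            raise ValueError("cpe_magnitude must be >= 0")
        if not 0.0 < self.cpe_exponent <= 1.0:
            raise ValueError("cpe_exponent must lie in (0, 1]")


def _mean_path(scenario: ScenarioSpec, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless mean trajectory, per-sample labels, per-sample noise SD."""
    clean = np.empty_like(times)
    labels = np.empty(times.shape, dtype=object)
    sds = np.empty_like(times)
    prev_level = scenario.segments[0].mean
    for seg in scenario.segments:
        mask = (times >= seg.start - 1e-12) & (times < seg.end - 1e-12)
        if seg is scenario.segments[-1]:
            mask |= times >= seg.end - 1e-12
        t = times[mask]
        if seg.shape == "constant":
            values = np.full(t.shape, seg.mean)
            end_level = seg.mean
        elif seg.shape == "linear_ramp":
            frac = (t - seg.start) / (seg.end - seg.start)
            values = prev_level + (seg.mean - prev_level) * frac
            end_level = seg.mean
        else:  # exponential_rise
            rise = seg.rise_amplitude * (np.exp((t - seg.start) / seg.rise_tau) - 1.0)
            values = np.minimum(prev_level + rise, seg.mean)
            end_rise = seg.rise_amplitude * (
                np.exp((seg.end - seg.start) / seg.rise_tau) - 1.0
            )
            end_level = min(prev_level + end_rise, seg.mean)
        clean[mask] = values
        labels[mask] = seg.label
        sds[mask] = seg.sd
        prev_level = end_level
    return clean, labels, sds


def _artifact_signal(scenario: ScenarioSpec, times: np.ndarray) -> np.ndarray:
    signal = np.zeros_like(times)
    for art in scenario.artifacts:
        if isinstance(art, SpikeArtifact):
            idx = int(np.argmin(np.abs(times - art.time)))
            signal[idx] += art.amplitude
        elif isinstance(art, BreathingArtifact):
            mask = (times >= art.start) & (times <= art.end)
            signal[mask] += art.amplitude * np.sin(
                2.0 * np.pi * art.frequency * (times[mask] - art.start) + art.phase
            )
        else:
            raise ValueError(f"unknown artifact type {type(art).__name__}")
    return signal


def default_scenario(joint: str, subcutaneous_mean: float = SUBCUTANEOUS_MEAN,
                     dye_plateau: float = DYE_PLATEAU, seed: int = 0) -> ScenarioSpec:
    """The reference insertion timeline for one of the four joints.

    The intra-articular segment carries the joint's reference (mean, SD);
    for the right knee the SD is split into a 0.3 Hz breathing sinusoid
    contributing 5% of the mean and a Gaussian remainder, so the segment's
    total SD still matches the reference value.  The dye rise is calibrated
    to cross the joint's +3 sigma limit at 27.98 s.
    """
    mu, sigma = joint_reference(joint)
    artifacts: list = [SpikeArtifact(time=SPIKE_TIME)]
    intra_sd = sigma
    if joint == "right_knee":
        breathing_sd = BREATHING_SD_FRACTION * mu
        intra_sd = float(np.sqrt(max(sigma**2 - breathing_sd**2, 0.0)))
        artifacts.append(
            BreathingArtifact(
                start=TRANSITION_END,
                end=SHARP_RISE_TIME,
                amplitude=float(np.sqrt(2.0) * breathing_sd),
            )
        )
    # Amplitude such that the mean path reaches mu + 3*sigma (the UCL) at
    # the sharp-rise time, matching the recorded dye timeline.
    rise_amplitude = 3.0 * sigma / (
        np.exp((SHARP_RISE_TIME - INTRA_ARTICULAR_END) / DYE_RISE_TAU) - 1.0
    )
    segments = (
        Segment("subcutaneous", 0.0, SUBCUTANEOUS_END, subcutaneous_mean,
                SUBCUTANEOUS_SD, "constant"),
        Segment("transition", SUBCUTANEOUS_END, TRANSITION_END, mu,
                TRANSITION_SD, "linear_ramp"),
        Segment("intra_articular", TRANSITION_END, INTRA_ARTICULAR_END, mu,
                intra_sd, "constant"),
        Segment("dye_injection", INTRA_ARTICULAR_END, SCENARIO_END, dye_plateau,
                intra_sd, "exponential_rise",
                rise_tau=DYE_RISE_TAU, rise_amplitude=float(rise_amplitude)),
    )
    return ScenarioSpec(segments=segments, artifacts=tuple(artifacts), seed=seed)


def simulate_trace(scenario: ScenarioSpec,
                   rng: np.random.Generator | None = None) -> SimulatedTrace:
    """Draw one trace from the scenario; deterministic given the seed/rng."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    fs = scenario.sampling_rate
    n = int(round((scenario.end - scenario.start) * fs))
    times = scenario.start + np.arange(n) / fs
    clean, labels, sds = _mean_path(scenario, times)
    noise = rng.standard_normal(n) * sds
    raw = clean + _artifact_signal(scenario, times) + noise
    return SimulatedTrace(
        trace=ImpedanceTrace(times, raw),
        labels=labels,
        clean=clean,
        scenario=scenario,
    )


def calibration_segment(joint: str, n_samples: int = JOINT_SAMPLE_COUNT,
                        sampling_rate: float = 33.0, seed: int = 0,
                        rng: np.random.Generator | None = None) -> SimulatedTrace:
    """Standalone intra-articular dwell of *n_samples* at the joint statistics.

    Used to emulate the reference calibration recordings (242 samples per
    joint).  The right knee includes its breathing component so the sample
    SD reproduces the published total.
    """
    if n_samples < 2:
        raise ValueError("calibration segment needs at least 2 samples")
    mu, sigma = joint_reference(joint)
    duration = n_samples / sampling_rate
    artifacts: tuple = ()
    intra_sd = sigma
    if joint == "right_knee":
        breathing_sd = BREATHING_SD_FRACTION * mu
        intra_sd = float(np.sqrt(max(sigma**2 - breathing_sd**2, 0.0)))
        artifacts = (
            BreathingArtifact(start=0.0, end=duration,
                              amplitude=float(np.sqrt(2.0) * breathing_sd)),
        )
    scenario = ScenarioSpec(
        segments=(Segment("intra_articular", 0.0, duration, mu, intra_sd, "constant"),),
        artifacts=artifacts,
        sampling_rate=sampling_rate,
        seed=seed,
    )
    return simulate_trace(scenario, rng=rng)


def simulate_saline_depth(model: SalineModel, depths, frequencies):
    """Needle-in-saline spectra at several immersion depths.

    Returns one :class:`ImpedanceSpectrum` per depth.  Because the insulated
    shaft keeps the exposed-tip area constant, the model is depth-invariant:
    all returned spectra are identical, exactly.
    """
    from .circuits import ImpedanceSpectrum

    depths = np.asarray(depths, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if depths.size == 0:
        raise ValueError("depth list must be non-empty")
    if f.size == 0:
        raise ValueError("frequency list must be non-empty")
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * np.pi * f
    z = model.solution_resistance + model.cpe_magnitude * (1j * omega) ** (
        -model.cpe_exponent
    )
    spectrum = ImpedanceSpectrum(f, np.abs(z), np.rad2deg(np.angle(z)))
    return [spectrum for _ in range(depths.size)]


@dataclass(frozen=True)
class EvaluationResult:
    """Per-sample confusion counts of the detector over simulated traces."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_total: int
    n_excluded: int

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        n = self.n_evaluated
        return (self.tp + self.tn) / n if n else 0.0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0


def evaluate_detector(config: DetectorConfig, scenario: ScenarioSpec,
                      n_traces: int = 100, guard_band: float = 0.5,
                      base_seed=None) -> EvaluationResult:
    """Benchmark the detector's per-sample classification on seeded traces.

    For each simulated trace the per-sample prediction is the filtered
    in-control flag; the per-sample ground truth is whether the noiseless
    mean trajectory lies within the control limits — i.e. what an ideal,
    noise-free chart would report.  Samples within ``guard_band`` seconds of
    a ground-truth transition (a limit crossing of the mean path) are
    excluded, since no causal filter can be graded fairly inside its own
    settling window.  Deterministic given ``base_seed`` (defaults to the
    scenario seed).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if guard_band < 0:
        raise ValueError("guard_band must be >= 0")
    if not scenario.has_label("intra_articular"):
        raise ValueError("scenario must contain an intra_articular segment")
    if base_seed is None:
        base_seed = scenario.seed
    ss = (base_seed if isinstance(base_seed, np.random.SeedSequence)
          else np.random.SeedSequence(base_seed))
    tp = tn = fp = fn = 0
    n_total = n_excluded = 0
    for child in ss.spawn(n_traces):
        sim = simulate_trace(scenario, rng=np.random.default_rng(child))
        result = detect_trace(sim.trace, config)
        limits = result.limits
        truth = (sim.clean >= limits.lcl) & (sim.clean <= limits.ucl)
        times = sim.trace.times
        keep = np.ones(times.shape, dtype=bool)
        changes = np.flatnonzero(truth[1:] != truth[:-1]) + 1
        for idx in changes:
            keep &= np.abs(times - times[idx]) > guard_band
        pred = result.in_control
        t, p = truth[keep], pred[keep]
        tp += int(np.sum(t & p))
        tn += int(np.sum(~t & ~p))
        fp += int(np.sum(~t & p))
        fn += int(np.sum(t & ~p))
        n_total += times.size
        n_excluded += int(np.sum(~keep))
    return EvaluationResult(tp=tp, tn=tn, fp=fp, fn=fn,
                            n_total=n_total, n_excluded=n_excluded)
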