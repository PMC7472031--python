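"""Streaming intra-articular placement detector.

Each incoming sample is low-pass filtered, classified against the Shewhart
limits of the intra-articular reference, and fed to a small state machine:

* ``searching`` -> ``in_space`` after ``debounce`` consecutive in-control
  samples (the debounce suppresses indicator chatter on noise; debounce = 1
  reproduces the per-sample indicator of the original flow).
* ``in_space`` -> ``searching`` on the first out-of-control sample — this is
  what retracts the indicator when the contrast-dye rise drives the
  magnitude through the upper limit.

Processing a trace in one call and folding samples one at a time through
:meth:`Detector.process_sample` produce bitwise-identical records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control_chart import ControlLimits, compute_control_limits
from .filtering import FilterSpec, StreamingFilter, design_lowpass, filter_samples
from .joints import joint_reference
from .trace import ImpedanceTrace

__all__ = [
    "SEARCHING",
    "IN_SPACE",
    "DetectorConfig",
    "SampleRecord",
    "DetectionResult",
    "Detector",
    "calibrate",
    "detect_trace",
]

logger = logging.getLogger(__name__)

SEARCHING = "searching"
IN_SPACE = "in_space"


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration of the streaming detector.

    Exactly one limits source must be set: ``reference`` — a (mu, sigma)
    pair of intra-articular statistics (see :func:`DetectorConfig.for_joint`
    for the shipped per-joint defaults) — or ``calibration_window`` — a
    (start, end) time span on the incoming stream whose samples are used to
    compute the limits.

    Parameters
    ----------
    sampling_rate
        Stream rate in samples per second (33 in the reference setup).
    measurement_frequency
        Metadata: the single excitation frequency in Hz (100 kHz).
    filter_order, wn
        Low-pass design; first order with wn = 0.04 by default.
    k
        Control-limit multiplier (3 -> 99.73% normal coverage).
    debounce
        Consecutive in-control samples required to declare in-space
        (10 samples, about 0.3 s at 33 S/s).
    filter_enabled
        When False the chart runs on raw magnitudes (comparison mode).
    """

    sampling_rate: float = 33.0
    measurement_frequency: float = 100_000.0
    filter_order: int = 1
    wn: float = 0.04
    k: float = 3.0
    debounce: int = 10
    filter_enabled: bool = True
    reference: tuple[float, float] | None = None
    calibration_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.debounce < 1:
            raise ValueError("debounce must be >= 1")
        if not 0.0 < self.wn < 1.0:
            raise ValueError("normalized cutoff wn must lie in (0, 1)")
        if (self.reference is None) == (self.calibration_window is None):
            raise ValueError(
                "exactly one limits source must be configured: "
                "reference=(mu, sigma) or calibration_window=(start, end)"
            )
        if self.calibration_window is not None:
            start, end = self.calibration_window
            if not end > start:
                raise ValueError("calibration_window end must exceed start")

    @classmethod
    def for_joint(cls, joint: str, **overrides) -> "DetectorConfig":
        """Config with ``reference`` taken from the shipped joint table."""
        return cls(reference=joint_reference(joint), **overrides)

    def filter_spec(self) -> FilterSpec:
        return design_lowpass(self.filter_order, self.wn)

    def reference_limits(self) -> ControlLimits:
        """Limits from the configured reference statistics."""
        if self.reference is None:
            raise ValueError("config uses a calibration window, not reference statistics")
        mu, sigma = self.reference
        return ControlLimits(mu=float(mu), sigma=float(sigma), k=self.k)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample detector output."""

    time: float
    raw: float
    filtered: float
    in_control: bool
    state: str


@dataclass
class DetectionResult:
    """Full-trace detector output.

    Per-sample arrays (times, raw, filtered, in_control, states) plus the
    list of (entry_time, exit_time) intervals spent in the in-space state
    and the limits the classification used.
    """

    times: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray
    in_control: np.ndarray
    states: np.ndarray
    events: list[tuple[float, float]]
    limits: ControlLimits

    def __post_init__(self) -> None:
        for entry, exit_ in self.events:
            if not (self.times[0] <= entry <= exit_ <= self.times[-1]):
                raise ValueError("events must lie within the trace time span")

    def to_frame(self) -> pd.DataFrame:
        """Per-sample records as a DataFrame."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "raw_ohm": self.raw,
                "filtered_ohm": self.filtered,
                "in_control": self.in_control,
                "state": self.states,
            }
        )


class Detector:
    """Stateful streaming detector; see module docstring for the state machine."""

    def __init__(self, config: DetectorConfig, limits: ControlLimits | None = None):
        if limits is None:
            limits = config.reference_limits()
        self.config = config
        self.limits = limits
        self._filter = StreamingFilter(config.filter_spec()) if config.filter_enabled else None
        self._run = 0
        self._state = SEARCHING
        self._last_time: float | None = None
        self._entry_time: float | None = None
        self.events: list[tuple[float, float]] = []

    @property
    def state(self) -> str:
        return self._state

    @property
    def indicator_on(self) -> bool:
        """The in-space indicator (the original system's LED)."""
        return self._state == IN_SPACE

    def process_sample(self, time: float, magnitude: float) -> SampleRecord:
        """Consume one (time, magnitude) sample and advance the state machine."""
        if self._last_time is not None and time <= self._last_time:
            raise ValueError(
                f"non-monotone timestamp: {time!r} after {self._last_time!r}"
            )
        self._last_time = float(time)
        filtered = self._filter.push(magnitude) if self._filter is not None else float(magnitude)
        in_control = self.limits.classify(filtered)
        if in_control:
            self._run += 1
            if self._state == SEARCHING and self._run >= self.config.debounce:
                self._state = IN_SPACE
                self._entry_time = float(time)
                logger.info("state transition -> in_space at t=%.3f s (filtered=%.1f ohm)",
                            time, filtered)
        else:
            self._run = 0
            if self._state == IN_SPACE:
                self._state = SEARCHING
                self.events.append((self._entry_time, float(time)))
                self._entry_time = None
                logger.info("state transition -> searching at t=%.3f s (filtered=%.1f ohm)",
                            time, filtered)
        return SampleRecord(float(time), float(magnitude), filtered, in_control, self._state)

    def finalize_events(self) -> list[tuple[float, float]]:
        """Close a still-open in-space interval at the last processed time."""
        events = list(self.events)
        if self._state == IN_SPACE and self._entry_time is not None:
            events.append((self._entry_time, self._last_time))
        return events


def calibrate(trace_segment: ImpedanceTrace, config: DetectorConfig) -> ControlLimits:
    """Compute control limits from an in-space calibration segment.

    The segment is filtered per the config (unless filtering is disabled)
    before the mean/SD are taken, matching how the detector will see the
    stream; the returned limits carry the sample count.
    """
    if len(trace_segment) < 2:
        raise ValueError("calibration segment must contain at least 2 samples")
    x = trace_segment.magnitudes
    if config.filter_enabled:
        x = filter_samples(x, config.filter_spec())
    return compute_control_limits(x, k=config.k, n=len(trace_segment))


def _check_uniform(trace: ImpedanceTrace, fs: float) -> None:
    if len(trace) < 2:
        return
    dt = np.diff(trace.times)
    if np.any(np.abs(dt * fs - 1.0) > 0.01):
        inferred = trace.sampling_rate
        raise ValueError(
            f"trace sampling rate {inferred:.4g} S/s does not match the configured "
            f"{fs:.4g} S/s within 1%"
        )


def detect_trace(trace: ImpedanceTrace, config: DetectorConfig,
                 limits: ControlLimits | None = None) -> DetectionResult:
    """Run the full streaming algorithm over a trace.

    Equivalent — bit for bit — to folding :meth:`Detector.process_sample`
    over the samples.  With ``limits_source = calibration_window`` the limits
    are first computed from the configured window of this trace, then the
    whole trace is processed against them.
    """
    _check_uniform(trace, config.sampling_rate)
    if limits is None and config.calibration_window is not None:
        start, end = config.calibration_window
        mask = (trace.times >= start) & (trace.times <= end)
        if int(mask.sum()) < 2:
            raise ValueError(
                f"calibration window [{start}, {end}] covers fewer than 2 samples"
            )
        limits = calibrate(
            ImpedanceTrace(trace.times[mask], trace.magnitudes[mask]), config
        )
    det = Detector(config, limits=limits)
    n = len(trace)
    raw = trace.magnitudes
    filtered = np.empty(n)
    in_control = np.empty(n, dtype=bool)
    states = np.empty(n, dtype=object)
    for i in range(n):
        rec = det.process_sample(trace.times[i], raw[i])
        filtered[i] = rec.filtered
        in_control[i] = rec.in_control
        states[i] = rec.state
    return DetectionResult(
        times=trace.times.copy(),
        raw=raw.copy(),
        filtered=filtered,
        in_control=in_control,
        states=states,
        events=det.finalize_events(),
        limits=det.limits,
    )
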