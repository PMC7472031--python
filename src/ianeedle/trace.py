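"""Impedance-magnitude time series container.

A trace is the stream an impedance analyzer emits while the needle electrode
is advanced: time in seconds from stream start, impedance magnitude in ohms
(at a single measurement frequency, 100 kHz by convention), and an optional
phase channel in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImpedanceTrace"]


@dataclass(frozen=True)
class ImpedanceTrace:
    """Uniformly sampled impedance-magnitude time series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    magnitudes
        Impedance magnitude in ohms, one value per time point.
    phases
        Optional impedance phase in degrees, one value per time point.
    """

    times: np.ndarray
    magnitudes: np.ndarray
    phases: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        mags = np.asarray(self.magnitudes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "magnitudes", mags)
        if times.ndim != 1 or mags.ndim != 1:
            raise ValueError("times and magnitudes must be one-dimensional")
        if times.size == 0:
            raise ValueError("trace must contain at least one sample")
        if times.size != mags.size:
            raise ValueError(
                f"times ({times.size}) and magnitudes ({mags.size}) differ in length"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(mags))):
            raise ValueError("trace contains non-finite values")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            bad = times[1:][np.diff(times) <= 0][0]
            raise ValueError(f"times must be strictly increasing (violation at t={bad!r})")
        if self.phases is not None:
            phases = np.asarray(self.phases, dtype=float)
            object.__setattr__(self, "phases", phases)
            if phases.shape != times.shape:
                raise ValueError("phases must match times in length")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Time span of the trace in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in samples per second, from the median inter-sample interval."""
        if len(self) < 2:
            raise ValueError("sampling rate undefined for a single-sample trace")
        return 1.0 / float(np.median(np.diff(self.times)))

    def with_magnitudes(self, magnitudes: np.ndarray) -> "ImpedanceTrace":
        """Return a copy of this trace with the magnitude channel replaced."""
        return ImpedanceTrace(self.times.copy(), np.asarray(magnitudes, dtype=float),
                              None if self.phases is None else self.phases.copy())
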