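"""Shewhart individual-value control chart for impedance magnitudes.

The chart summarizes an in-space calibration sample by its mean mu and
sample standard deviation sigma (N-1 denominator) and draws a center line
CL = mu with control limits UCL = mu + k*sigma and LCL = mu - k*sigma.
With the default multiplier k = 3 and normally distributed data, 99.73% of
in-space samples fall inside the limits; a value beyond either limit is
evidence the needle tip is in a different tissue layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ControlLimits",
    "compute_control_limits",
    "classify_sample",
    "classify_samples",
    "coverage_probability",
]


@dataclass(frozen=True)
class ControlLimits:
    """Center line and control limits derived from (mu, sigma, k).

    cl, ucl and lcl are exact functions of the stored mu/sigma/k, never
    stored separately, so the defining identities cannot drift.  ``n`` is
    the calibration sample count when known (informational).
    """

    mu: float
    sigma: float
    k: float = 3.0
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k < 0:
            raise ValueError("limit multiplier k must be >= 0")

    @property
    def cl(self) -> float:
        """Center line (the calibration mean)."""
        return self.mu

    @property
    def ucl(self) -> float:
        """Upper control limit mu + k*sigma."""
        return self.mu + self.k * self.sigma

    @property
    def lcl(self) -> float:
        """Lower control limit mu - k*sigma."""
        return self.mu - self.k * self.sigma

    def classify(self, value: float) -> bool:
        """True when *value* is in-control (see :func:`classify_sample`)."""
        return classify_sample(value, self)


def compute_control_limits(samples, k: float = 3.0, n: int | None = None) -> ControlLimits:
    """Compute chart limits from a calibration sample.

    mu is the arithmetic mean, sigma the sample standard deviation with the
    N-1 denominator.  At least two samples are required; an all-identical
    sample is allowed and collapses the limits onto the center line.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if x.size < 2:
        raise ValueError("control limits require at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    return ControlLimits(mu=mu, sigma=sigma, k=float(k), n=n if n is not None else int(x.size))


def classify_sample(value: float, limits: ControlLimits) -> bool:
    """Classify a magnitude against the limits; True means in-control.

    Out-of-control iff value > UCL or value < LCL (strict inequalities), so
    a value exactly on a limit still counts as in-control.
    """
    return not (value > limits.ucl or value < limits.lcl)


def classify_samples(values: np.ndarray, limits: ControlLimits) -> np.ndarray:
    """Vectorized :func:`classify_sample`; boolean array, True = in-control."""
    v = np.asarray(values, dtype=float)
    return ~((v > limits.ucl) | (v < limits.lcl))


def coverage_probability(
    k: float,
    monte_carlo: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that a normal variate lies within mu +/- k*sigma.

    Closed form 2*Phi(k) - 1 by default (0.9973 at k = 3).  When
    ``monte_carlo`` is given, estimates the probability instead by
    classifying that many standard-normal draws against limits built from
    (mu=0, sigma=1, k); the two routes agree within sampling error.
    """
    if k < 0:
        raise ValueError("limit multiplier k must be >= 0")
    if monte_carlo is None:
        return float(2.0 * stats.norm.cdf(k) - 1.0)
    if monte_carlo < 1:
        raise ValueError("monte_carlo sample count must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    draws = rng.standard_normal(int(monte_carlo))
    limits = ControlLimits(mu=0.0, sigma=1.0, k=float(k))
    return float(np.mean(classify_samples(draws, limits)))
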