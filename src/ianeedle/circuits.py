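"""Equivalent-circuit impedance models for tissue layers.

A biological tissue layer seen from a monopolar needle electrode is well
approximated over 10 Hz - 100 kHz by a series resistor R1 (electrolyte /
deep-tissue access resistance) feeding a parallel resistor-capacitor branch
(R2 || C1) that captures the dispersive, capacitive behaviour of cell
membranes:

    Z(w) = R1 + R2 / (1 + j * w * R2 * C1),   w = 2 * pi * f

The magnitude falls monotonically from R1 + R2 at DC to R1 at high frequency,
and the phase is zero at both extremes with a capacitive (negative) minimum
in between.  Different layers (fat, muscle, synovial fluid) fit to different
(R1, R2, C1) triples, which is what makes impedance a usable needle-position
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RRCCircuit",
    "ImpedanceSpectrum",
    "FitError",
    "rrc_impedance",
    "impedance_spectrum",
    "normalize_spectrum",
    "fit_rrc",
]


@dataclass(frozen=True)
class RRCCircuit:
    """Series resistance plus a parallel resistor-capacitor branch.

    Parameters
    ----------
    r_series
        Series (access) resistance R1 in ohms, >= 0.
    r_parallel
        Parallel branch resistance R2 in ohms, > 0.
    capacitance
        Parallel branch capacitance C1 in farads, >= 0.
    """

    r_series: float
    r_parallel: float
    capacitance: float

    def __post_init__(self) -> None:
        if self.r_series < 0:
            raise ValueError("r_series must be >= 0")
        if self.r_parallel <= 0:
            raise ValueError("r_parallel must be > 0")
        if self.capacitance < 0:
            raise ValueError("capacitance must be >= 0")

    def impedance(self, frequency):
        """Complex impedance at *frequency* (Hz, scalar or array)."""
        return rrc_impedance(self, frequency)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Impedance magnitude/phase sampled over a frequency sweep.

    frequencies are in Hz (strictly increasing, > 0), magnitudes in ohms
    (> 0; dimensionless after normalization), phases in degrees.
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)
        object.__setattr__(self, "phases", p)
        if f.size == 0:
            raise ValueError("spectrum must contain at least one frequency")
        if not (f.size == m.size == p.size):
            raise ValueError("frequencies, magnitudes and phases must have equal length")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("magnitudes must be positive")

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def complex_impedance(self) -> np.ndarray:
        """Complex impedance reconstructed from magnitude and phase."""
        return self.magnitudes * np.exp(1j * np.deg2rad(self.phases))


class FitError(RuntimeError):
    """Raised when circuit fitting fails to converge.

    Carries the best parameters reached (``best``) and the residual norm
    (``residual``) so a caller can inspect the partial result.
    """

    def __init__(self, message: str, best: RRCCircuit, residual: float):
        super().__init__(message)
        self.best = best
        self.residual = residual


def rrc_impedance(circuit: RRCCircuit, frequency):
    """Complex impedance of *circuit* at *frequency* (Hz).

    Accepts a scalar or array of non-negative frequencies; returns a complex
    scalar/array.  Magnitude and phase follow from ``abs`` and ``np.angle``.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    omega = 2.0 * np.pi * f
    z = circuit.r_series + circuit.r_parallel / (
        1.0 + 1j * omega * circuit.r_parallel * circuit.capacitance
    )
    if np.isscalar(frequency):
        return complex(z)
    return z


def impedance_spectrum(circuit: RRCCircuit, frequencies) -> ImpedanceSpectrum:
    """Evaluate *circuit* over a strictly increasing positive frequency sweep."""
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("frequency sweep must be non-empty")
    if np.any(f <= 0):
        raise ValueError("sweep frequencies must be positive")
    if f.size > 1 and np.any(np.diff(f) <= 0):
        raise ValueError("sweep frequencies must be strictly increasing")
    z = rrc_impedance(circuit, f)
    return ImpedanceSpectrum(f, np.abs(z), np.rad2deg(np.angle(z)))


def normalize_spectrum(spectrum: ImpedanceSpectrum) -> ImpedanceSpectrum:
    """Divide magnitudes by the magnitude at the lowest frequency.

    The result is dimensionless with first value exactly 1; scale-invariant,
    so spectra of geometrically similar layers overlay.
    """
    ref = float(spectrum.magnitudes[0])
    if ref == 0.0 or not np.isfinite(ref):
        raise ZeroDivisionError("reference magnitude at the lowest frequency is zero")
    return ImpedanceSpectrum(
        spectrum.frequencies.copy(),
        spectrum.magnitudes / ref,
        spectrum.phases.copy(),
    )


def _initial_guess(spectrum: ImpedanceSpectrum) -> RRCCircuit:
    # Heuristic: high-frequency magnitude ~ R1, low-frequency ~ R1 + R2;
    # corner frequency taken where the magnitude crosses its mid level.
    m = spectrum.magnitudes
    f = spectrum.frequencies
    hi = float(m[-1])
    lo = float(m[0])
    r1 = max(hi, 1e-12)
    r2 = max(lo - hi, 1e-9 * lo, 1e-12)
    drop = lo - hi
    if drop <= 1e-9 * lo:
        # Flat spectrum: effectively no capacitive branch.
        return RRCCircuit(r1, r2, 0.0)
    mid = hi + 0.5 * drop
    idx = int(np.argmin(np.abs(m - mid)))
    f_mid = float(f[idx])
    c = 1.0 / (2.0 * np.pi * f_mid * r2)
    return RRCCircuit(r1, r2, c)


def fit_rrc(
    spectrum: ImpedanceSpectrum,
    initial_guess: RRCCircuit | None = None,
    max_nfev: int = 2000,
) -> RRCCircuit:
    """Fit an :class:`RRCCircuit` to a measured spectrum.

    Minimizes the summed squared *relative* error of the complex impedance
    (real and imaginary residuals each divided by the measured magnitude),
    which weights all frequency decades evenly.  A deterministic local
    least-squares solver is used, seeded by a magnitude-plateau heuristic
    when no initial guess is given.

    Returns
    -------
    RRCCircuit
        The fitted circuit.  The relative-residual norm of the last
        successful fit is reported as ``fit_rrc.last_residual``; on failure
        it travels on the raised :class:`FitError`.

    Raises
    ------
    ValueError
        If the spectrum has fewer than 5 points or spans less than a decade.
    FitError
        If the solver does not converge; the exception carries best-so-far
        parameters.
    """
    if len(spectrum) < 5:
        raise ValueError("fit requires at least 5 spectrum points")
    span = spectrum.frequencies[-1] / spectrum.frequencies[0]
    if span < 10.0:
        raise ValueError("fit requires the sweep to span at least one frequency decade")

    z_meas = spectrum.complex_impedance
    scale = np.abs(z_meas)
    f = spectrum.frequencies
    guess = initial_guess if initial_guess is not None else _initial_guess(spectrum)

    def residuals(p):
        circuit = RRCCircuit(p[0], max(p[1], 1e-300), p[2])
        z = rrc_impedance(circuit, f)
        r = (z - z_meas) / scale
        return np.concatenate([r.real, r.imag])

    x0 = np.array([guess.r_series, guess.r_parallel, guess.capacitance], dtype=float)
    x_scale = np.maximum(np.abs(x0), [1.0, 1.0, 1e-12])
    result = least_squares(
        residuals,
        x0,
        bounds=([0.0, 1e-300, 0.0], [np.inf, np.inf, np.inf]),
        x_scale=x_scale,
        max_nfev=max_nfev,
        method="trf",
    )
    fitted = RRCCircuit(float(result.x[0]), float(result.x[1]), float(result.x[2]))
    residual = float(np.sqrt(2.0 * result.cost))
    if not result.success:
        raise FitError(f"circuit fit did not converge: {result.message}", fitted, residual)
    fit_rrc.last_residual = residual
    return fitted


fit_rrc.last_residual = float("nan")
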