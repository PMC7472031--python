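"""Delimited-text readers/writers and run configuration.

Traces and spectra travel as comma-delimited text with mandatory headers:

* traces:  ``time_s,magnitude_ohm`` or ``time_s,magnitude_ohm,phase_deg``
* spectra: ``frequency_hz,magnitude_ohm,phase_deg``

Values are written with shortest round-trip float formatting, so
write -> read is an identity to full precision and two writes of the same
object are byte-identical.  The run configuration is JSON with defaults
matching the reference setup (order 1, wn 0.04, k 3, 33 S/s, and the
shipped per-joint intra-articular statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circuits import ImpedanceSpectrum
from .detector import DetectorConfig
from .joints import JOINT_REFERENCE
from .trace import ImpedanceTrace

__all__ = [
    "TRACE_HEADER",
    "TRACE_HEADER_PHASE",
    "SPECTRUM_HEADER",
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "load_config",
]

TRACE_HEADER = "time_s,magnitude_ohm"
TRACE_HEADER_PHASE = "time_s,magnitude_ohm,phase_deg"
SPECTRUM_HEADER = "frequency_hz,magnitude_ohm,phase_deg"


class ParseError(ValueError):
    """Malformed delimited-text input."""


def _parse_rows(path: Path, expected_headers: tuple[str, ...]) -> tuple[str, list[list[float]]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].strip()
    if header not in expected_headers:
        raise ParseError(
            f"{path}:1: unexpected header {header!r}; expected one of "
            + " | ".join(repr(h) for h in expected_headers)
        )
    width = header.count(",") + 1
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != width:
            raise ParseError(f"{path}:{lineno}: expected {width} fields, found {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return header, rows


def read_trace(path) -> ImpedanceTrace:
    """Read a trace file, validating the header and time ordering."""
    header, rows = _parse_rows(Path(path), (TRACE_HEADER, TRACE_HEADER_PHASE))
    data = np.asarray(rows, dtype=float)
    times = data[:, 0]
    if times.size > 1:
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            bad = times[1:][diffs <= 0][0]
            raise ValueError(f"{path}: non-monotone time axis at t={bad!r}")
    phases = data[:, 2] if header == TRACE_HEADER_PHASE else None
    return ImpedanceTrace(times, data[:, 1], phases)


def _fmt(value: float) -> str:
    return repr(float(value))


def write_trace(trace: ImpedanceTrace, path) -> None:
    """Write a trace with full float precision; deterministic byte-for-byte."""
    lines = []
    if trace.phases is None:
        lines.append(TRACE_HEADER)
        for t, m in zip(trace.times, trace.magnitudes):
            lines.append(f"{_fmt(t)},{_fmt(m)}")
    else:
        lines.append(TRACE_HEADER_PHASE)
        for t, m, p in zip(trace.times, trace.magnitudes, trace.phases):
            lines.append(f"{_fmt(t)},{_fmt(m)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum file (frequency_hz,magnitude_ohm,phase_deg)."""
    _, rows = _parse_rows(Path(path), (SPECTRUM_HEADER,))
    data = np.asarray(rows, dtype=float)
    return ImpedanceSpectrum(data[:, 0], data[:, 1], data[:, 2])


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write a spectrum with full float precision."""
    lines = [SPECTRUM_HEADER]
    for f, m, p in zip(spectrum.frequencies, spectrum.magnitudes, spectrum.phases):
        lines.append(f"{_fmt(f)},{_fmt(m)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


_DETECTOR_KEYS = {
    "sampling_rate", "measurement_frequency", "filter_order", "wn", "k",
    "debounce", "filter_enabled", "joint", "reference", "calibration_window",
}
_TOP_KEYS = {"detector", "joints", "output_dir", "verbosity"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: detector settings plus the joint table."""

    detector: DetectorConfig
    joints: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(JOINT_REFERENCE)
    )
    output_dir: str = "."
    verbosity: str = "info"


def load_config(path=None) -> RunConfig:
    """Load a JSON config file, merging user overrides over the defaults.

    With no file, returns pure defaults: first-order filter at wn = 0.04,
    k = 3, 33 S/s, debounce 10, and reference statistics for the right knee.
    Unknown keys raise a config error listing the valid keys.
    """
    raw: dict = {}
    if path is not None:
        raw = json.loads(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a JSON object")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    joints = dict(JOINT_REFERENCE)
    for joint, pair in raw.get("joints", {}).items():
        joints[joint] = (float(pair[0]), float(pair[1]))

    det_raw = dict(raw.get("detector", {}))
    unknown = set(det_raw) - _DETECTOR_KEYS
    if unknown:
        raise ValueError(
            f"unknown detector config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_DETECTOR_KEYS)}"
        )
    joint = det_raw.pop("joint", "right_knee")
    reference = det_raw.pop("reference", None)
    window = det_raw.pop("calibration_window", None)
    if reference is not None:
        reference = (float(reference[0]), float(reference[1]))
    elif window is None:
        if joint not in joints:
            raise ValueError(
                f"unknown joint {joint!r}; valid joints: {sorted(joints)}"
            )
        reference = joints[joint]
    if window is not None:
        window = (float(window[0]), float(window[1]))
    detector = DetectorConfig(reference=reference, calibration_window=window, **det_raw)
    return RunConfig(
        detector=detector,
        joints=joints,
        output_dir=str(raw.get("output_dir", ".")),
        verbosity=str(raw.get("verbosity", "info")),
    )
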