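"""Reference intra-articular impedance statistics per joint.

Mean and sample standard deviation (ohms) of the impedance magnitude measured
at 100 kHz with the needle tip resting in the intra-articular space of a
porcine model, n = 242 samples per joint.  The knees read lower than the
elbows because their larger synovial-fluid volume conducts better; the right
knee's larger spread reflects breathing/movement artifact during that
recording (about 5% of the mean).
"""

from __future__ import annotations

__all__ = ["JOINT_REFERENCE", "JOINT_SAMPLE_COUNT", "joint_reference"]

#: (mean ohms, sample SD ohms) per joint.
JOINT_REFERENCE: dict[str, tuple[float, float]] = {
    "right_knee": (1537.3, 88.5),
    "left_knee": (1367.2, 8.0),
    "right_elbow": (2012.5, 7.4),
    "left_elbow": (2001.8, 12.6),
}

#: Number of intra-articular samples behind each (mean, SD) pair.
JOINT_SAMPLE_COUNT: int = 242

#: Fraction of the right-knee mean attributable to breathing-artifact SD.
BREATHING_SD_FRACTION: float = 0.05


def joint_reference(joint: str) -> tuple[float, float]:
    """Return the (mean, SD) reference pair for *joint*.

    Raises
    ------
    ValueError
        If *joint* is not one of the four reference joints.
    """
    try:
        return JOINT_REFERENCE[joint]
    except KeyError:
        valid = ", ".join(sorted(JOINT_REFERENCE))
        raise ValueError(f"unknown joint {joint!r}; expected one of: {valid}") from None
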