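"""Shewhart control limits from intra-articular reference statistics.

Builds the k = 3 chart for each joint from the shipped (mean, SD) table and
shows the normal coverage the +/-3 sigma band implies.
"""

import numpy as np

from ianeedle import (
    ControlLimits,
    JOINT_REFERENCE,
    classify_samples,
    coverage_probability,
)

print("joint          mu (ohm)  sigma   LCL     CL      UCL")
for joint, (mu, sigma) in JOINT_REFERENCE.items():
    lim = ControlLimits(mu=mu, sigma=sigma, k=3.0)
    print(f"{joint:<14} {mu:8.1f} {sigma:6.1f} {lim.lcl:7.1f} {lim.cl:7.1f} {lim.ucl:7.1f}")

print(f"\nclosed-form coverage at k=3: {100 * coverage_probability(3.0):.2f}%")
rng = np.random.default_rng(0)
mu, sigma = JOINT_REFERENCE["right_knee"]
draws = rng.normal(mu, sigma, size=1_000_000)
frac = classify_samples(draws, ControlLimits(mu=mu, sigma=sigma)).mean()
print(f"Monte-Carlo in-control fraction (10^6 draws): {100 * frac:.2f}%")
print("(a sample outside the band means the needle tip is not in the joint space)")
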