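"""End-to-end needle-insertion detection on a simulated right-knee trace.

Simulates the reference insertion timeline (subcutaneous dwell, descent to
the joint cavity, intra-articular rest, contrast-dye injection), runs the
streaming detector, and prints when the in-space indicator would switch on
and off.
"""

from ianeedle import DetectorConfig, default_scenario, detect_trace, simulate_trace

scenario = default_scenario("right_knee", seed=11)
sim = simulate_trace(scenario)
print(f"simulated {len(sim.trace)} samples "
      f"({sim.trace.duration + 1 / 33:.0f} s at {sim.trace.sampling_rate:.0f} S/s)")

config = DetectorConfig.for_joint("right_knee")
limits = config.reference_limits()
print(f"limits: CL = {limits.cl:.1f} ohm, UCL = {limits.ucl:.1f}, LCL = {limits.lcl:.1f}")

result = detect_trace(sim.trace, config)
for entry, exit_ in result.events:
    print(f"in-space indicator ON  at t = {entry:6.2f} s "
          f"(needle reached the joint-fluid impedance level)")
    print(f"in-space indicator OFF at t = {exit_:6.2f} s "
          f"(dye rise pushed the magnitude past the UCL)")
print("true timeline: cavity entered 22.89 s, dye loading 22.98 s, sharp rise 27.98 s")
print("(the indicator leads cavity entry because the descending impedance already")
print(" sits at joint-fluid level during the final approach)")
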