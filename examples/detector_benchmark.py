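"""Per-sample accuracy benchmark of the detector on simulated insertions.

Runs 100 seeded right-knee scenario traces through the full pipeline and
scores every sample's in-space flag against the noiseless ground truth,
excluding a +/-0.5 s guard band around the true transitions.
"""

from ianeedle import DetectorConfig, default_scenario, evaluate_detector

config = DetectorConfig.for_joint("right_knee")
scenario = default_scenario("right_knee")
result = evaluate_detector(config, scenario, n_traces=100, guard_band=0.5, base_seed=1)

print(f"traces: 100, samples scored: {result.n_evaluated} "
      f"({result.n_excluded} inside guard bands)")
print(f"confusion: TP={result.tp} TN={result.tn} FP={result.fp} FN={result.fn}")
print(f"accuracy:    {100 * result.accuracy:.2f}%")
print(f"sensitivity: {100 * result.sensitivity:.2f}%")
print(f"specificity: {100 * result.specificity:.2f}%")
print("(accuracy >= 99.9% is the pipeline's headline operating point at 33 S/s)")
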