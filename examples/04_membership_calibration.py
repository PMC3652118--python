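"""Calibrate membership plateaus from per-condition sample statistics.

The nucleus-area sets were calibrated from per-condition means and
population variances: the 99% sigma-known confidence interval of each
condition's mean becomes the full-membership plateau of its fuzzy set.
This script reproduces those intervals and emits the resulting trapezoids.
"""

import cervidx as cx
from cervidx.calibration import variable_to_config

statistics = [
    cx.SampleSummary("small", n=5, mean=3536.71, variance=1_611_045.74, confidence=0.99),
    cx.SampleSummary("medium", n=5, mean=7658.24, variance=2_283_910.70, confidence=0.99),
    cx.SampleSummary("large", n=8, mean=13747.13, variance=17_225_203.65, confidence=0.99),
]

labeled = []
for summary in statistics:
    interval = cx.confidence_interval(summary)
    labeled.append((summary.label, interval))
    print(f"{summary.label:7s} (n={summary.n}): "
          f"{interval.lo:9.2f} < mean < {interval.hi:9.2f}")

variable = cx.intervals_to_membership(labeled, (0, 25000), name="nucleus_area")
print("\ncalibrated trapezoids (a, b, c, d):")
for fset in variable.sets:
    print(f"  {fset.label:7s} {fset.params}")

print("\nconfig fragment:")
print(variable_to_config(variable))

print("\nEach plateau [b, c] is the condition's confidence interval, so a "
      "field whose mean nucleus area matches a condition's calibration mean "
      "gets full membership in that condition's set.")
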