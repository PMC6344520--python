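"""Compute per-TR and scan-level motion metrics from realignment parameters.

Builds a short six-parameter series containing one clean head jerk,
computes the per-TR ENORM (L2) and framewise displacement (L1) and the
scan summary used as the modelling outcome.
"""

import numpy as np

from motionstack import MotionParams, enorm_series, fd_series, summarize_motion

values = np.zeros((6, 6))
values[3] = [0, 0, 0, 3, 4, 0]  # a 3mm + 4mm translation spike at TR 3

params = MotionParams(values=values, subject_id="demo")
print("per-TR ENORM:", enorm_series(params))
print("per-TR FD:   ", fd_series(params))

summary = summarize_motion(params)
print(f"mean ENORM = {summary.mean_enorm:.3f} mm/TR "
      f"(log = {summary.log_mean_enorm:.3f})")
print(f"mean FD    = {summary.mean_fd:.3f} mm/TR")

# The spike enters and leaves: two affected intervals. The 3-4-5 triangle
# makes the L2 norm 5 and the L1 norm 7 on each, so the scan means are
# 2*5/5 = 2 and 2*7/5 = 2.8. FD always dominates ENORM.
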