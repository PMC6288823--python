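"""Long-term root-angle phenotypes from traced polylines and skeletons.

Builds a few hand-made root traces (pixel coordinates, y increasing
downward), computes the average absolute angle — the net deviation of the
junction→tip vector from the downward vertical — and its signed variant,
tests for growth handedness, and scores pixel skeletons with the
direction index (down = 0 … up = 4).
"""

import numpy as np

from rootqtl import root_traits as rt

# three roots: plumb, slanted right, slanted left
traces = {
    "plumb": rt.RootTrace([(0, 0), (1, 40), (0, 80)]),
    "slant-right": rt.RootTrace([(0, 0), (20, 40), (55, 75)]),
    "slant-left": rt.RootTrace([(0, 0), (-15, 35), (-40, 80)]),
}

print("avgAbsAng (0° = plumb, 90° = horizontal):")
signed = []
for name, tr in traces.items():
    a, s = rt.avg_abs_angle(tr), rt.signed_net_angle(tr)
    signed.append(s)
    print(f"  {name:12s} |angle| = {a:6.2f}°   signed = {s:+7.2f}°")

p = rt.handedness_test(signed)
print(f"handedness sign test p = {p:.3f} "
      "(no evidence of a left/right growth preference)")

down = rt.Skeleton([(i, 0) for i in range(50)])
wavy = rt.Skeleton([(i, (i // 5) % 2) for i in range(50)])
print(f"direction index, straight-down skeleton: {rt.direction_index(down):.2f}")
print(f"direction index, slightly wavy skeleton: {rt.direction_index(wavy):.2f}")
print("(0 means every pixel step points with gravity; 4 would be straight up)")
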