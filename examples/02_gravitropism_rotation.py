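"""Short-term gravitropism: tip-angle kinetics after a 90° rotation.

Simulates saturating tip-angle responses for a fast and a slow genotype
(34 timepoints, 3.75 min apart), derives per-root swing rates, tests each
timepoint for a genotype difference with BH control over the whole
genotype × timepoint family, and reports runs of ≥3 consecutive
significant timepoints — the gravitropism-QTL calling rule.
"""

import numpy as np

from rootqtl import root_traits as rt, synthetic_data as sd, trait_qtl as tq

params = {
    "M82": (0.060, 40.0, 3.75),     # (rate /min, amplitude °, lag min): fast
    "IL-slow": (0.020, 30.0, 7.50),  # responds more slowly, as some ILs do
}
series = sd.simulate_tip_angle_series(params, n_roots=40, noise_sd=1.0, seed=7)

classes = [s.rotation_class for s in series if s.genotype == "M82"]
print(f"M82 roots rotated through/away from gravity: "
      f"{classes.count('through')}/{classes.count('away')}")

rates = rt.swing_rate_table(series)
matrix = tq.per_timepoint_tests(rates, reference="M82")
runs = tq.consecutive_runs(matrix, q_threshold=0.05, min_run=3)
for call in runs:
    print(f"{call.genotype}: swing rate differs from M82 at T{call.run_start}"
          f"–T{call.run_end} ({call.length} timepoints, {call.phase} phase, "
          f"{call.direction} than M82)")
print("A run of ≥3 consecutive significant timepoints is a gravitropism QTL;"
      " its phase places the effect early, middle, or late in the response.")
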