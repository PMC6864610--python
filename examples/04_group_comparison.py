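"""Two-group comparison with the exact Wilcoxon rank-sum test.

Simulates a cohort of five low-force-scale subjects ("P") and five
high-force-scale subjects ("T"), summarizes each subject's hand-rim
kinetics and compares the groups.  With five per group the exact null
distribution has 252 assignments, so the smallest attainable two-sided p
is 2/252 ~ 0.0079.
"""

import numpy as np
import pandas as pd

from rimdyn import compare_groups, detect_pushes, simulate_propulsion
from rimdyn.events_cycles import segment_cycles
from rimdyn.handrim_kinetics import summarize_handrim
from rimdyn.synthetic import group_params

rows = []
for group in ("P", "T"):
    for subject in range(5):
        p = group_params(group, subject, base_seed=0)
        trial = simulate_propulsion(p, 4 * p.cycle_duration + 0.4)
        pushes = detect_pushes(trial.rim.M[:, 2], 1.0, p.rim_rate)
        cycles = segment_cycles(pushes, trial.rim.n_samples, p.rim_rate)
        summ = [summarize_handrim(trial.rim, c) for c in cycles]
        rows.append({"group": group,
                     "Ftotmax": np.mean([s.Ftot_max for s in summ]),
                     "Feff": np.mean([s.Feff for s in summ])})

table = pd.DataFrame(rows)
for c in compare_groups(table, ["Ftotmax", "Feff"], alpha=0.05):
    mark = "*" if c.significant else " "
    print(f"{c.variable:8s} P median {c.summary_x[0]:6.2f} +/-IQR {c.summary_x[1]:5.2f}   "
          f"T median {c.summary_y[0]:6.2f} +/-IQR {c.summary_y[1]:5.2f}   "
          f"p = {c.p_value:.4f}{mark} ({c.method})")
print("\n* significant at alpha = 0.05; the groups were generated with")
print("  disjoint force scales, so both variables separate maximally.")
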