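"""Per-subject drift estimates and a two-group comparison.

Twelve subjects are followed over 12 timepoints each; the 'fast' group
drifts with magnitude 1.5, the 'slow' group with 0.5.  Each subject's
trajectory is reduced to a distance matrix, the drift regression is fitted
subject by subject, and the per-subject magnitudes are compared between
groups with a pooled-variance Student t-test.
"""

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from md3f import (
    SimulationScenario,
    StudyDesign,
    compare_group_drifts,
    distance_matrix,
    fit_per_subject,
    replicate_rng,
    simulate_trajectory,
)

groups = {"fast": 1.5, "slow": 0.5}
rows, positions = [], {}
for g_idx, (group, alpha) in enumerate(groups.items()):
    scenario = SimulationScenario(n=2, d=8, alpha=alpha)
    for i in range(6):
        subject = f"{group}{i + 1}"
        walk = simulate_trajectory(scenario, n_steps=11, dt=1.0,
                                   rng=replicate_rng(7, g_idx, i))
        for k, t in enumerate(walk.times):
            sid = f"{subject}.t{k}"
            rows.append({"sample": sid, "subject": subject, "time": t, "group": group})
            positions[sid] = walk.positions[k]

design = StudyDesign(pd.DataFrame(rows))
points = np.vstack([positions[s] for s in design.sample_ids])
dist = distance_matrix(squareform(pdist(points)), design.sample_ids)

fits = fit_per_subject(dist, design, mode="baseline", model="linear2")
print("per-subject drift estimates (true: fast=1.5, slow=0.5):")
for subject, fit in sorted(fits.fits.items()):
    print(f"  {subject:7s} alpha^ = {fit.alpha_hat:.3f}   p = {fit.slope_p:.3g}")

result = compare_group_drifts(fits, design)
print()
print(f"group means: {result.group_labels[0]} = {result.group_means[0]:.3f}, "
      f"{result.group_labels[1]} = {result.group_means[1]:.3f}")
print(f"Student t = {result.t_statistic:.2f}, p = {result.p_value:.2e}")
print()
print("Each subject gets its own drift magnitude; the t-test then asks whether")
print("the groups differ in how fast their profiles move in a directed way.")
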