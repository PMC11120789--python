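"""Estimate a drift magnitude from one simulated pre/post study.

One hundred subjects are observed twice: at baseline and at a subject-specific
follow-up time drawn from Exponential(1).  Their 20-dimensional profiles
follow a drift-diffusion process with true drift magnitude alpha = 1.5.
The fit regresses the time-scaled squared interpoint distance on the time
interval: the slope estimates alpha^2, and its t-test asks "is there any
directed change at all?".
"""

import numpy as np

from md3f import SimulationScenario, fit_pairs_arrays, simulate_prepost

scenario = SimulationScenario(n=100, d=20, alpha=1.5, time_rate=1.0, seed=2024)
sample = simulate_prepost(scenario)

fit = fit_pairs_arrays(sample.times, sample.distances(), model="linear2",
                       scaling="time_scaled")

print(f"true drift magnitude   alpha   = {scenario.alpha}")
print(f"estimated magnitude    alpha^  = {fit.alpha_hat:.4f}")
print(f"slope (estimates a^2)          = {fit.slope:.4f}  (true {scenario.alpha**2})")
print(f"intercept (diffusion, ~d)      = {fit.intercept:.4f}  (true {scenario.d})")
print(f"slope p-value                  = {fit.slope_p:.2e}")
print()
print("The slope recovers the squared drift magnitude; the intercept absorbs")
print("the per-unit-time diffusion contribution, which equals the number of")
print("dimensions for unit-variance coordinates.  A small p-value says the")
print("profiles move in a consistent direction, not just diffuse.")
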