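"""Type I error and power of the drift test, against a min-p alternative.

Under pure diffusion (alpha = 0) a valid test should reject ~5% of the
time.  The drift regression does; the univariate screen-and-adjust
alternative (uHolm) rejects far more often, because regressing each of the
100 noisy coordinates on time and taking the best-adjusted p-value
capitalizes on heteroscedastic chance.  With a real drift, power rises
with effect size.
"""

from md3f import run_rejection_grid, summarize_grid

null_cells = [(50, 100, 0.0)]
res_null = run_rejection_grid(null_cells, methods=("MD3Flinear2", "uHolm"),
                              replicates=500, level=0.05, seed=42)
print("null (alpha = 0, n = 50, d = 100) rejection at level 0.05:")
for _, row in res_null.iterrows():
    print(f"  {row['method']:12s} {row['rejection_fraction']:.3f}")

power_cells = [(50, 10, a) for a in (0.0, 0.5, 1.0, 2.0)]
res_power = run_rejection_grid(power_cells, methods=("MD3Flinear2",),
                               replicates=500, level=0.05, seed=42)
print("\npower of MD3Flinear2 at n = 50, d = 10:")
for _, row in res_power.iterrows():
    print(f"  alpha = {row['alpha']:3.1f}   rejection = {row['rejection_fraction']:.3f}")

print("\npivoted summary:")
print(summarize_grid(res_power).round(3).to_string())
print()
print("MD3Flinear2 sits near the nominal 0.05 under the null while uHolm is")
print("badly inflated; rejection then climbs toward 1 as the drift grows.")
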