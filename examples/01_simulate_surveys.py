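"""Generate a synthetic regional bat survey and inspect its structure.

Builds the default scenario — 190 grid cells drawn from a 4,500-cell
sampling frame, three annual seasons, four single-night visits — under
declining dynamics, and prints the design, the true occupancy trajectory,
and the realized detection rate.
"""

import numpy as np

import occutrend as ot

scenario = ot.ScenarioConfig(seed=1, preset="declining")
data, truth = ot.generate_dataset(scenario)

print(f"sites x seasons x visits: {data.n_sites} x {data.n_seasons} x {data.n_visits}")
print(f"years: {data.years}")
print("true psi trajectory (average conditions):",
      np.round(truth.psi_true, 3))
print(f"true growth rate: total {truth.lambda_total:.3f}, "
      f"annual {truth.lambda_annual:.3f}")
occ = truth.z_true.z.astype(bool)
det_rate = np.nanmean(data.y[occ])
print(f"per-visit detection rate at occupied site-seasons: {det_rate:.2f}")
print("naive detection-only occupancy (ever detected, year 1):",
      round(data.ever_detected[:, 0].mean(), 3),
      "vs true occupied fraction:", round(occ[:, 0].mean(), 3))
# The naive rate underestimates occupancy because detection is imperfect
# (~0.4 per visit); the model corrects for exactly this gap.
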