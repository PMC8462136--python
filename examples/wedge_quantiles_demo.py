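"""The wedge-shaped abundance-suitability relation via quantile regression.

Suitability caps the abundance a lake can attain without determining it:
the upper quantiles of frequency of occurrence rise steeply with
predicted suitability while the median barely moves. The 90th-minus-50th
quantile slope difference measures the wedge strength.
"""

import numpy as np

from milfoilsdm import (
    SimulationConfig,
    build_dataset,
    fit_sdm,
    generate_landscape,
    wedge_quantiles,
)
from milfoilsdm.evaluation import suitability_on_table

table = generate_landscape(SimulationConfig(seed=1))
ds = build_dataset(table, "PA")
model = fit_sdm(ds, seed=1, train_fraction=None)  # final full-data model

surveyed = table[table["surveyed"].astype(bool)]
suit = suitability_on_table(model, table)
fit = wedge_quantiles(suit, surveyed["freq_occ"].to_numpy())

print("quantile regression of frequency of occurrence on suitability:")
for tau in fit.taus:
    print(f"  tau = {tau:.2f}: slope {fit.slopes[tau]:6.3f}, "
          f"intercept {fit.intercepts[tau]:6.3f}")
print(f"wedge strength (q90 - q50 slope): {fit.wedge_strength:.3f}")

# Closed-form check on y ~ Uniform(0, x): the tau-quantile is tau*x,
# so the fitted slopes should approximate tau itself.
rng = np.random.default_rng(0)
x = rng.uniform(0, 1, 2000)
fit_u = wedge_quantiles(x, rng.uniform(0, x))
print("uniform wedge slopes:",
      {t: round(fit_u.slopes[t], 3) for t in fit_u.taus})
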