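"""Pool city x subperiod associations and separate the life-expectancy signal.

The reduced coefficients from the first stage are pooled in a multivariate
mixed-effects meta-regression (city random effect, ML). Forward-backward AIC
selection over candidate meta-predictors identifies life expectancy as the
vulnerability driver; factual BLUPs and fixed-LE counterfactual BLUPs give
per-city associations with and without the observed LE improvements.
"""

import numpy as np

from heatattrib import WorldConfig, simulate_world
from heatattrib.dlnm import fit_city_subperiods
from heatattrib.metareg import (
    compute_blups,
    counterfactual_blups,
    heterogeneity,
    select_model,
)

world = simulate_world(WorldConfig(n_cities=6), seed=11)
scheme = world["truth"].scheme

reduced = []
for city, temps in world["citytemp"].groupby("city"):
    morts = world["citymort"][world["citymort"]["city"] == city]
    red, _ = fit_city_subperiods(temps, morts, scheme)
    reduced.extend(red)

model, trace = select_model(
    reduced, world["metapred"], scheme,
    candidates=("le", "tmean_annual", "trange", "heat_alert_days",
                "mean_age", "pct_over65"),
)
selected = [c for c in model.data.columns
            if c not in ("intercept",) and not c.startswith("year_ns")]
het = heterogeneity(model)
print(f"selected meta-predictors: {selected}")
print(f"AIC {model.aic:.1f}, log-likelihood {model.loglik:.1f}, "
      f"Cochran Q {het.Q:.1f} (df {het.df}), I2 {het.I2:.1f}%")

blups = compute_blups(model)
cf = counterfactual_blups(model, blups, world["metapred"], predictor="le")
shift = np.linalg.norm(cf.theta - blups.theta, axis=1)
last = blups.subperiod == scheme.labels[-1]
print(f"\nmean |cfBLUP - BLUP| in the last subperiod: {shift[last].mean():.3f}"
      f" (zero in the first subperiod: {shift[blups.subperiod == scheme.labels[0]].max():.1e})")
print("\nFreezing LE at its 1993-1997 value shifts the last-subperiod "
      "coefficients back toward the early, more vulnerable associations; "
      "first-subperiod BLUPs are unchanged by construction.")
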