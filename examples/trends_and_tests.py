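"""Trend fits and factual-vs-counterfactual Wilcoxon comparisons.

Fits linear trends (per decade, with spline alternatives compared by AIC) to
annual warm-season temperatures and attributable fractions, and tests
whether city-specific trends differ between the factual world and the
9-member counterfactual temperature ensemble (15 + 135 trend estimates in
the full design; fewer cities here for speed).
"""

from heatattrib import WorldConfig, simulate_world
from heatattrib.pipeline import RunConfig, run_pipeline

world = simulate_world(WorldConfig(n_cities=6), seed=5)
cfg = RunConfig(n_mc=0, selection="fixed", fixed_predictors=("le",), seed=2,
                ensemble_trends=True)
res = run_pipeline(world["gmst"], world["citytemp"], world["citymort"],
                   world["metapred"], cfg)

print("aggregated trends (per decade):")
for _, row in res["trends"].iterrows():
    print(f"  {row['quantity']:<6} {row['temperature']:<13} "
          f"{row['association']:<7} {row['slope_per_decade']:+.3f} "
          f"({row['ci_lower']:+.3f}, {row['ci_upper']:+.3f}) "
          f"best fit: {row['best_family']}")

print("\nWilcoxon rank-sum tests, city trends factual vs counterfactual:")
for key, comp in res["comparisons"].items():
    print(f"  {comp.grouping:<35} n={comp.n_a}+{comp.n_b}  p={comp.p:.2g}")

print("\nTemperature trends separate sharply (warming is removed in the "
      "counterfactual); AF trends separate only when LE improvements are "
      "switched off, mirroring the role of declining vulnerability.")
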