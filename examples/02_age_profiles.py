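"""Sample one parameter set and disaggregate it to single years of age.

Each survey band contributes one knot at its midpoint; a natural cubic
spline through the knots (linear beyond them, clamped to [0,1]) gives a
use probability at every age, including ages 0-7 that no survey band
covers."""

import numpy as np

from youthads import (ParameterSet, RunConfig, build_age_profile,
                      observe_truth, sample_group_estimates)
from youthads.age_model import band_knots, ensure_child_minutes
from youthads.synthetic import (default_band_layout, default_truths,
                                synthetic_population)

population = synthetic_population()
layout = default_band_layout()
config = RunConfig(seed=3)
observed = observe_truth(default_truths()["photogram"], population, layout,
                         seed=3)

rng = np.random.default_rng(3)
minutes_bands = ensure_child_minutes(observed.minutes, config)
ps = ParameterSet(
    "photogram",
    prevalence_draws=sample_group_estimates(observed.use_prevalence, rng),
    minutes_draws=sample_group_estimates(minutes_bands, rng, kind="minutes"),
)
profile = build_age_profile(ps, observed.use_prevalence, minutes_bands, config)

knots = band_knots(observed.use_prevalence, config.age_max)
print("prevalence knots (band midpoint -> sampled value):")
for k, v in zip(knots, ps.prevalence_draws):
    print(f"  age {k:5.1f}: {v:.3f}")
print("\ninterpolated single-age profile (every 7th age):")
for a in range(0, 85, 7):
    print(f"  age {a:2d}: use probability {profile.p[a]:.3f}, "
          f"{profile.m[a]:5.1f} min/day among users")
print("\nAges below the youngest knot take the clamped linear")
print("extrapolation; the calibration step decides which sampled")
print("profiles are consistent with reported band user totals.")
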