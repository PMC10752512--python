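"""Calibrate one platform against its reported band user totals and
check how well the retained ensemble recovers the known truth.

Draws 3000 candidate parameter sets, keeps the 100 best-fitting, and
prints modeled vs true user totals per report band with the ensemble's
95% uncertainty interval."""

import numpy as np

from youthads import RunConfig, fit_platform, observe_truth
from youthads.synthetic import (default_band_layout, default_truths,
                                synthetic_population)

population = synthetic_population()
layout = default_band_layout()
truth = default_truths()["klips"]
observed = observe_truth(truth, population, layout, seed=11)

config = RunConfig(seed=11, n_candidates=3000, n_keep=100)
ensemble = fit_platform(observed, population, config)
print(f"fitted {config.n_candidates} candidates, kept {len(ensemble)}; "
      f"losses {ensemble.losses[0]:.4g} (best) to {ensemble.losses[-1]:.4g}")

print("\nband user totals, millions (truth vs ensemble mean [95% UI]):")
for band in layout.target_bands:
    member = [float((population.counts[band.lo:band.hi + 1]
                     * m.profile.p[band.lo:band.hi + 1]).sum())
              for m in ensemble.members]
    lo, hi = np.percentile(member, [2.5, 97.5])
    t = truth.band_users(population, band)
    flag = "in" if lo <= t <= hi else "OUT of"
    print(f"  ages {band.label:>5}: truth {t/1e6:6.2f}  "
          f"model {np.mean(member)/1e6:6.2f} [{lo/1e6:6.2f}, {hi/1e6:6.2f}] "
          f"- truth {flag} UI")
print("\nThe interval width reflects survey sampling error filtered")
print("through the requirement to match reported user totals.")
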