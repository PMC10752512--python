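"""Generate a synthetic study dataset and compare what the 'surveys'
observe with the underlying truth.

Writes the five input CSVs plus truth.json to ./scratch_example_data and
prints, for one platform, the exact population-weighted band prevalence
next to the noisy observed estimate — the difference is the survey
sampling error the model later has to see through."""

from pathlib import Path

from youthads import observe_truth
from youthads.synthetic import (default_band_layout, default_truths,
                                synthetic_population, write_synthetic_dataset)

out = Path("scratch_example_data")
paths = write_synthetic_dataset(out, seed=7)
print(f"wrote {len(paths)} files to {out}/:", ", ".join(p.name for p in paths.values()))

population = synthetic_population()
layout = default_band_layout()
truth = default_truths()["snappy"]
observed = observe_truth(truth, population, layout, seed=7)

print("\nsnappy platform, prevalence by survey band (truth vs observed):")
p = truth.prevalence(population.ages)
for est in observed.use_prevalence:
    lo, hi = est.band.lo, est.band.hi
    w = population.counts[lo:hi + 1]
    exact = (w * p[lo:hi + 1]).sum() / w.sum()
    print(f"  ages {est.band.label:>5}: truth {exact:.3f}  observed "
          f"{est.estimate:.3f}  (±{est.margin95:.3f} at 95%)")
print(f"\ntotal annual ad revenue implied by truth: "
      f"${observed.total_revenue/1e6:.1f}M")
print("User totals per report band are exact calibration targets;")
print("prevalence/minutes estimates carry survey sampling noise.")
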