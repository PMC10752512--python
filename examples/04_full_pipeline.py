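"""Run the whole study on the default synthetic platforms and print the
headline outputs: youth users, youth-attributable ad revenue, and the
share of each platform's revenue that comes from ages 0-17.

A smaller candidate count than the default keeps this demo quick; use
RunConfig(n_candidates=10000) (or the `youthads run` CLI) for production
settings."""

from youthads import RunConfig, observe_truth, run_pipeline
from youthads.synthetic import (default_band_layout, default_truths,
                                synthetic_population)

population = synthetic_population()
layout = default_band_layout()
config = RunConfig(seed=1, n_candidates=2000, n_keep=100)
observed = [observe_truth(t, population, layout, seed=1)
            for t in default_truths().values()]

result = run_pipeline(config, population, observed)

users = result.users_by_band.set_index(["platform", "band"])
revenue = result.revenue_by_band.set_index(["platform", "band"])
share = result.share_by_band.set_index(["platform", "band"])

print(f"{'platform':>10} {'users 0-17 (M)':>20} {'revenue 0-17 ($M)':>22} "
      f"{'share 0-17':>12}")
for o in observed:
    pid = o.platform_id
    u = users.loc[(pid, "0-17")]
    r = revenue.loc[(pid, "0-17")]
    s = share.loc[(pid, "0-17"), "mean"]
    print(f"{pid:>10} {u['mean']/1e6:7.2f} [{u['ui_lo']/1e6:6.2f},"
          f"{u['ui_hi']/1e6:6.2f}] {r['mean']/1e6:8.1f} "
          f"[{r['ui_lo']/1e6:7.1f},{r['ui_hi']/1e6:7.1f}] {100*s:9.1f}%")

total = revenue.xs("0-17", level="band")["mean"].sum()
print(f"\ntotal modeled ad revenue from ages 0-17: ${total/1e6:.1f}M/year")
print("Means are additive across bands (0-12 + 13-17 = 0-17); the")
print("percentile UI bounds are not and must be read per band.")
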