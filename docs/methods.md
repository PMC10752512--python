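# Methods

## Model

For each platform the model produces, by single year of age
`a = 0..age_max` (default 84, top age open-ended), the number of users
`U(a) = pop(a) · p(a)` and the annual ad revenue attributed to that age

```
R(a) = R_total · U(a) m(a) / Σ_b U(b) m(b)
```

where `p(a)` is the probability of platform use, `m(a)` the mean
minutes/day among users, `pop(a)` the census count, and `R_total` the
platform's total annual ad revenue. The allocation embodies a single
substantive assumption: **revenue per minute of platform use is constant
by age**. Nothing else ties revenue to age, so any age pattern in `R(a)`
comes entirely from the user and minutes curves. The 365 days/year
annualization cancels in the allocation ratio; it appears only in the
implied revenue-per-minute diagnostic and in the synthetic generator's
closed-form total revenue, once on each side, so all shares are
annualization-free.

`p(a)` and `m(a)` are not observed. Surveys report band-level estimates
with a ± 95%-CI sampling margin. The model treats each band estimate as
`Normal(estimate, margin95/1.96)` truncated to the legal range, draws one
joint realization of all bands (a *parameter set*), places each draw as a
knot at its band midpoint (open top band: midpoint of its lower edge and
`age_max`), and interpolates with a **natural cubic spline** — zero second
derivative at the boundary knots, continued linearly beyond them, which is
C¹ because the boundary curvature is already zero. Prevalence is clamped
to [0, 1] and minutes to [0, ∞) after interpolation. Prevalence and
minutes are interpolated independently on their own band layouts; `m` is
minutes *among users*, so non-users contribute no person-minutes by
construction. A platform whose minutes table covers adults only receives a
0–17 band at `child_minutes_fallback` (default 5 min/day, margin 0),
mirroring the convention used when a platform is too small to appear in
children's screen-time rankings.

## Calibration and uncertainty

Sampled parameter sets are confronted with the externally reported user
totals per age band (the calibration targets):

```
L(θ) = Σ_targets ((modeled_band_users(θ) − reported) / reported)²
```

A band with a zero reported total is scored as `(modeled/ref)²` with
`ref` the mean of the nonzero targets, so degenerate tables stay finite.
The fit is a seeded **best-of-N random search**: `n_candidates` (default
10 000) parameter sets are drawn from the sampling distributions,
scored, and the `n_keep = 100` lowest-loss sets retained. Candidate `i`
of platform `pid` uses the counter-based substream
`SeedSequence((seed, crc32(pid), i))`, making fits bit-reproducible,
independent of platform order, and trivially parallelizable; ties are
broken by candidate index. Random search is deliberately minimal: it
keeps the survey sampling distributions as the sole source of
uncertainty, and `fit_platform` accepts a `sampler` hook so an annealing
or CMA-style proposal scheme can be swapped in without changing any
contract. Increasing `n_candidates` with the same seed can only improve
the best loss (candidates are a prefix of a longer stream).

Every downstream quantity (band users, band revenue, share of total) is
computed per retained member; reports give the arithmetic mean and the
2.5th/97.5th percentiles (**95% uncertainty interval**) across members,
using type-7 linear interpolation between order statistics (recorded in
the run manifest). Means are linear, so mean(0–12) + mean(13–17) =
mean(0–17) to float precision; percentile bounds are order statistics and
must never be summed across bands. The mean is not constrained to lie
inside the UI.

## Synthetic data

The real inputs are proprietary, so the generator produces platforms with
known curves and observes them exactly the way the public sources would:

- **Prevalence truth**: `p(a) = pmax · σ((a−a_on)/w_on) ·
  σ((a_off−a)/w_off)` — a smooth adoption bump with logistic onset and
  decline. **Minutes truth**: piecewise-linear over stated knots.
  **Revenue truth**: constant rate × total person-minutes × 365.
- **Observation**: band estimate = population-weighted mean of the truth
  over the band + truncated Gaussian noise with SD = margin95/1.96; user
  totals per report band and total revenue are exact from truth.
- **Band geometry** mirrors the sources: youth survey bands 8–12 and
  13–17 (margin 3.2%), adult bands 18–29 (7.3%), 30–49 (5.2%), 50–64 and
  65+ (5.8%); one child (0–17) and one adult (18+) minutes band at
  margin95 = 5 min/day (the sources state no minutes margin; 5 min/day is
  a realistic reporting error for 15–60 min/day magnitudes); user-total
  bands 0–11, 12–17 and decade bands to 65+. Ages 0–7 are covered by no
  survey band and are constrained only through the 0–11 user total.
- **Population**: a smooth deterministic pyramid, ≈4 M per year of age
  with a gentle cohort ripple and logistic old-age decline (total ≈300 M),
  ages above 84 accumulated into 84.
- The six default platforms span the qualitative regimes of real ones
  (early-childhood video platform, adolescent-skewed apps, adult-skewed
  networks); their magnitudes are fixtures, not estimates.

What the generator does **not** emulate: correlated sampling errors across
bands, survey non-response or frame bias, year-to-year drift between the
sources (2021 surveys vs 2022 revenue), within-band age structure in the
reported user totals, or non-user impressions. Passing tests therefore
demonstrate that the pipeline recovers truth *under the stated observation
model*, not that the sources themselves are unbiased.

## Numerical choices and problem sizes

- Splines: `scipy.interpolate.CubicSpline(bc_type="natural")`, evaluated
  for all candidates of a platform in one vectorized call; linear
  extrapolation is applied from the boundary value and first derivative.
  With two knots the natural spline is the straight line; a single minutes
  band yields a constant curve.
- Truncated normal draws: `scipy.stats.truncnorm` with per-band bounds; a
  zero margin returns the point estimate exactly.
- Selection: stable argsort of losses, so ties resolve to the lowest
  candidate index and results are platform-order-independent.
- Degenerate inputs are typed errors, never coercions: duplicate or
  non-contiguous ages, proportions outside [0, 1], overlapping bands,
  missing revenue, all-zero targets, zero person-minutes,
  `n_candidates < n_keep`, empty ensembles.
- Default study size (used by the test suite and the acceptance script):
  6 platforms × 5000 candidates, keep 100, ages 0–84 — about 15 s on one
  CPU; the production default of 10 000 candidates roughly doubles that.
  Examples use 1500–3000 candidates to stay interactive.

## Known limitations

- **Ages below the youngest survey band are weakly identified.** Linear
  extrapolation from the 8–12/13–17 knots cannot represent a steep
  childhood onset; for such curves the calibrated 0–11 totals carry a
  structural bias of order 20% even though they are pulled toward the
  reported totals, and the same bias would affect a real-data run. The
  0–12 estimates should be read with this in mind; 13–17 and adult bands
  are directly anchored by survey knots.
- Best-of-N random search resolves the loss surface only to the sampling
  SD of the survey estimates divided by the effective number of
  candidates; with 5000 candidates over six prevalence dimensions the
  best member matches band totals to ~4–5% even when the truth is exactly
  representable. The UI width, not the best member, is the quantity with
  a calibration guarantee (≈90% empirical coverage of true band totals at
  the default settings).
- The ensemble conditions on point values of the reported user totals and
  total revenue; uncertainty in those market-research figures is not
  propagated because the sources publish no error bounds for them.
- Revenue attribution covers modeled users only; logged-out or
  unregistered viewing contributes no person-minutes.
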