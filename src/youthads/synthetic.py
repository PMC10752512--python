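"""Synthetic ground truth and survey-style observations of it.

The real inputs (market-research user totals and revenue, survey
prevalence) are proprietary, so end-to-end testing uses synthetic
platforms with *known* age curves:

* prevalence by age is a product of a logistic rise and a logistic
  decline, ``p(a) = pmax * sigmoid((a - a_on)/w_on) *
  sigmoid((a_off - a)/w_off)`` — a smooth unimodal "adoption bump" that
  rises through childhood/adolescence and declines with age;
* minutes/day among users is piecewise-linear over stated knots;
* revenue per person-minute is a constant, so the implied total annual
  revenue is ``rpm * sum_a pop_a p(a) m(a) * 365``.

:func:`observe_truth` then emulates what the surveys and market reports
would publish about those curves: band-level means with truncated
Gaussian sampling noise (SD = margin95/1.96) for prevalence and minutes,
*exact* band user totals (the calibration targets), and the exact total
revenue. Because the generator records the truth, calibration and
uncertainty quantification can be scored against it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .age_model import Z95
from .tables import (AgeBand, AgeGroupEstimate, PlatformInputs,
                     PopulationTable, UserTotal, ValidationError,
                     write_band_table, write_inputs_config, write_population,
                     write_revenue, write_user_totals)

__all__ = [
    "LogisticBumpCurve", "PiecewiseLinearCurve", "TruthSpec", "BandLayout",
    "make_truth", "observe_truth", "default_band_layout", "default_truths",
    "synthetic_population", "write_synthetic_dataset",
]

DAYS_PER_YEAR = 365.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class LogisticBumpCurve:
    """Prevalence-by-age curve: logistic onset at ``a_on`` (width
    ``w_on`` years) times logistic decline at ``a_off`` (width ``w_off``);
    ``pmax`` bounds the peak. Bounded in [0, pmax] for all ages."""

    pmax: float
    a_on: float
    w_on: float
    a_off: float
    w_off: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pmax <= 1.0:
            raise ValidationError(f"pmax {self.pmax} outside [0, 1]")
        if self.w_on <= 0 or self.w_off <= 0:
            raise ValidationError("logistic widths must be > 0")

    def __call__(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        return (self.pmax * _sigmoid((a - self.a_on) / self.w_on)
                * _sigmoid((self.a_off - a) / self.w_off))


@dataclass(frozen=True)
class PiecewiseLinearCurve:
    """Minutes-by-age curve, linear between knots and flat beyond them."""

    knot_ages: tuple[float, ...]
    knot_values: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.knot_ages, dtype=float)
        v = np.asarray(self.knot_values, dtype=float)
        if x.size != v.size or x.size < 1:
            raise ValidationError("piecewise curve: bad knots")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("piecewise curve: knot ages must increase")
        if np.any(v < 0):
            raise ValidationError("piecewise curve: negative minutes")

    def __call__(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        return np.interp(a, self.knot_ages, self.knot_values)


@dataclass(frozen=True)
class TruthSpec:
    """Known generating curves for one synthetic platform."""

    platform_id: str
    prevalence_curve: LogisticBumpCurve
    minutes_curve: PiecewiseLinearCurve
    revenue_per_minute: float

    def __post_init__(self) -> None:
        if self.revenue_per_minute <= 0:
            raise ValidationError("revenue_per_minute must be > 0")

    def prevalence(self, ages) -> np.ndarray:
        return self.prevalence_curve(ages)

    def minutes(self, ages) -> np.ndarray:
        return self.minutes_curve(ages)

    def users_by_age(self, population: PopulationTable) -> np.ndarray:
        return population.counts * self.prevalence(population.ages)

    def band_users(self, population: PopulationTable, band: AgeBand) -> float:
        users = self.users_by_age(population)
        return float(users[band.lo:band.hi + 1].sum())

    def total_revenue(self, population: PopulationTable) -> float:
        daily_minutes = (self.users_by_age(population)
                         * self.minutes(population.ages)).sum()
        return self.revenue_per_minute * daily_minutes * DAYS_PER_YEAR

    def to_dict(self) -> dict:
        c = self.prevalence_curve
        return {
            "platform_id": self.platform_id,
            "prevalence": {"pmax": c.pmax, "a_on": c.a_on, "w_on": c.w_on,
                           "a_off": c.a_off, "w_off": c.w_off},
            "minutes": {"knot_ages": list(self.minutes_curve.knot_ages),
                        "knot_values": list(self.minutes_curve.knot_values)},
            "revenue_per_minute": self.revenue_per_minute,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthSpec":
        return make_truth(
            d["platform_id"],
            prevalence=d["prevalence"],
            minutes_knots=list(zip(d["minutes"]["knot_ages"],
                                   d["minutes"]["knot_values"])),
            revenue_per_minute=d["revenue_per_minute"],
        )


def make_truth(platform_id: str, *, prevalence: Mapping[str, float],
               minutes_knots: Sequence[tuple[float, float]],
               revenue_per_minute: float, seed: int | None = None) -> TruthSpec:
    """Build a validated :class:`TruthSpec`; deterministic in its
    parameters (``seed`` is accepted for interface symmetry and recorded
    nowhere because nothing here is random)."""
    knots = tuple(float(a) for a, _ in minutes_knots)
    values = tuple(float(v) for _, v in minutes_knots)
    return TruthSpec(
        platform_id=platform_id,
        prevalence_curve=LogisticBumpCurve(**dict(prevalence)),
        minutes_curve=PiecewiseLinearCurve(knots, values),
        revenue_per_minute=float(revenue_per_minute),
    )


@dataclass(frozen=True)
class BandLayout:
    """Survey/report band geometry used to observe a truth: prevalence
    and minutes bands with their 95%-CI margins, and the age bands of the
    reported user totals (the calibration targets)."""

    prevalence: tuple[AgeGroupEstimate, ...]
    minutes: tuple[AgeGroupEstimate, ...]
    target_bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "prevalence", tuple(self.prevalence))
        object.__setattr__(self, "minutes", tuple(self.minutes))
        object.__setattr__(self, "target_bands", tuple(self.target_bands))


def default_band_layout(age_max: int = 84) -> BandLayout:
    """The band geometry of the public sources: a children's-media survey
    covering ages 8-17 (sampling margin 3.2% for the full sample), an
    adult survey with bands 18-29 (7.3%), 30-49 (5.2%), 50-64 and 65+
    (5.8% each); one child and one adult minutes band; market-report user
    totals on 0-11, 12-17 and decade-ish adult bands. Ages 0-7 are covered
    by no survey band and are constrained only through the 0-11 user
    total. The ``estimate`` fields in the layout are placeholders: band
    margins and geometry are the layout, values come from the truth."""
    def pband(lo, hi, margin, src, open_ended=False):
        return AgeGroupEstimate(AgeBand(lo, age_max if open_ended else hi,
                                        open_ended), 0.0, margin, src)
    prevalence = (
        pband(8, 12, 0.032, "youth survey"),
        pband(13, 17, 0.032, "youth survey"),
        pband(18, 29, 0.073, "adult survey"),
        pband(30, 49, 0.052, "adult survey"),
        pband(50, 64, 0.058, "adult survey"),
        pband(65, None, 0.058, "adult survey", open_ended=True),
    )
    minutes = (
        AgeGroupEstimate(AgeBand(0, 17), 0.0, 5.0, "child screen-time report"),
        AgeGroupEstimate(AgeBand(18, age_max, True), 0.0, 5.0,
                         "adult market report"),
    )
    targets = (AgeBand(0, 11), AgeBand(12, 17), AgeBand(18, 24),
               AgeBand(25, 34), AgeBand(35, 44), AgeBand(45, 54),
               AgeBand(55, 64), AgeBand(65, age_max, True))
    return BandLayout(prevalence, minutes, targets)


def synthetic_population(age_max: int = 84) -> PopulationTable:
    """A smooth, deterministic population pyramid with U.S.-like scale:
    roughly 4 million per single year of age, a gentle cohort ripple, and
    a logistic decline in the oldest ages; total ≈ 300 million."""
    ages = np.arange(age_max + 1)
    base = 4.0e6 * (0.97 + 0.03 * np.cos(ages / 8.0))
    old_age_decline = _sigmoid((72.0 - ages) / 6.0)
    counts = np.round(base * (0.25 + 0.75 * old_age_decline))
    return PopulationTable(ages=ages, counts=counts)


def _pop_weighted_band_mean(curve_values: np.ndarray,
                            population: PopulationTable,
                            band: AgeBand) -> float:
    w = population.counts[band.lo:band.hi + 1]
    v = curve_values[band.lo:band.hi + 1]
    if w.size == 0:
        raise ValidationError(f"band {band.label}: no ages in range")
    if w.sum() <= 0:
        return float(v.mean())
    return float((w * v).sum() / w.sum())


def _truncated_noise(rng: np.random.Generator, mean: float, margin95: float,
                     lo: float, hi: float) -> float:
    if margin95 == 0:
        return mean
    from scipy.stats import truncnorm
    sd = margin95 / Z95
    return float(truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd,
                               loc=mean, scale=sd, random_state=rng))


def observe_truth(truth: TruthSpec, population: PopulationTable,
                  layout: BandLayout, seed: int) -> PlatformInputs:
    """Emulate the published tables for one synthetic platform.

    Prevalence and minutes band estimates are the population-weighted
    means of the truth curve over the band plus truncated Gaussian
    sampling noise with SD = margin95/1.96 (truncated to [0,1] and
    [0, inf) respectively; a zero margin reproduces the exact mean).
    User totals per target band and the total revenue are computed
    exactly from the truth. Bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence((seed, zlib.crc32(truth.platform_id.encode()))))
    ages = population.ages
    p_true = truth.prevalence(ages)
    m_true = truth.minutes(ages)

    prevalence = tuple(
        AgeGroupEstimate(
            b.band,
            min(1.0, max(0.0, _truncated_noise(
                rng, _pop_weighted_band_mean(p_true, population, b.band),
                b.margin95, 0.0, 1.0))),
            b.margin95, b.source_label)
        for b in layout.prevalence)
    minutes = tuple(
        AgeGroupEstimate(
            b.band,
            max(0.0, _truncated_noise(
                rng, _pop_weighted_band_mean(m_true, population, b.band),
                b.margin95, 0.0, np.inf)),
            b.margin95, b.source_label)
        for b in layout.minutes)
    totals = tuple(UserTotal(band, truth.band_users(population, band))
                   for band in layout.target_bands)
    return PlatformInputs(
        platform_id=truth.platform_id,
        use_prevalence=prevalence,
        minutes=minutes,
        group_user_totals=totals,
        total_revenue=truth.total_revenue(population),
    )


def default_truths() -> dict[str, TruthSpec]:
    """Six synthetic platforms spanning the qualitative regimes of real
    ones: a video platform used heavily by young children, two
    adolescent-skewed apps, a broad young-adult app, and two adult-skewed
    networks (one small, exercising the child-minutes fallback scale).
    Magnitudes are test fixtures, not estimates of any real platform."""
    spec = {
        "bluebird": dict(  # small, adult-skewed microblog
            prevalence=dict(pmax=0.35, a_on=15, w_on=3.0, a_off=60, w_off=12.0),
            minutes_knots=[(8, 5), (18, 25), (35, 30), (84, 20)],
            revenue_per_minute=2.0e-5),
        "facegram": dict(  # large, older-skewed network
            prevalence=dict(pmax=0.75, a_on=16, w_on=3.0, a_off=75, w_off=12.0),
            minutes_knots=[(8, 10), (18, 25), (40, 35), (84, 30)],
            revenue_per_minute=3.0e-5),
        "photogram": dict(  # young-adult photo app
            prevalence=dict(pmax=0.70, a_on=13, w_on=2.5, a_off=55, w_off=10.0),
            minutes_knots=[(8, 35), (16, 55), (30, 40), (84, 20)],
            revenue_per_minute=2.5e-5),
        "snappy": dict(  # adolescent-skewed messaging app
            prevalence=dict(pmax=0.65, a_on=12, w_on=2.0, a_off=45, w_off=8.0),
            minutes_knots=[(8, 50), (16, 70), (30, 35), (84, 15)],
            revenue_per_minute=1.0e-5),
        "klips": dict(  # short-video app, adolescent-skewed
            prevalence=dict(pmax=0.68, a_on=11, w_on=2.0, a_off=50, w_off=9.0),
            minutes_knots=[(8, 70), (16, 95), (30, 50), (84, 25)],
            revenue_per_minute=1.5e-5),
        "vidtube": dict(  # video platform watched from early childhood
            prevalence=dict(pmax=0.90, a_on=4, w_on=2.0, a_off=70, w_off=12.0),
            minutes_knots=[(5, 60), (13, 80), (25, 45), (50, 30), (84, 20)],
            revenue_per_minute=2.0e-5),
    }
    return {pid: make_truth(pid, **kw) for pid, kw in spec.items()}


def write_synthetic_dataset(out_dir: Path | str, seed: int,
                            age_max: int = 84,
                            truths: Mapping[str, TruthSpec] | None = None,
                            layout: BandLayout | None = None) -> dict[str, Path]:
    """Emit the five input CSVs, the YAML run configuration referencing
    them, and ``truth.json`` recording the generating curves for later
    recovery scoring. Returns the written paths keyed by table name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = dict(truths if truths is not None else default_truths())
    layout = layout if layout is not None else default_band_layout(age_max)
    population = synthetic_population(age_max)

    observed = {pid: observe_truth(t, population, layout, seed)
                for pid, t in truths.items()}
    paths = {
        "population": write_population(population, out_dir / "population.csv"),
        "prevalence": write_band_table(
            {pid: o.use_prevalence for pid, o in observed.items()},
            out_dir / "prevalence.csv"),
        "minutes": write_band_table(
            {pid: o.minutes for pid, o in observed.items()},
            out_dir / "minutes.csv"),
        "user_totals": write_user_totals(
            {pid: o.group_user_totals for pid, o in observed.items()},
            out_dir / "user_totals.csv"),
        "revenue": write_revenue(
            {pid: o.total_revenue for pid, o in observed.items()},
            out_dir / "revenue.csv"),
    }
    paths["config"] = write_inputs_config(
        out_dir / "inputs.yaml",
        run={"seed": seed, "age_max": age_max},
        population="population.csv", prevalence="prevalence.csv",
        minutes="minutes.csv", user_totals="user_totals.csv",
        revenue="revenue.csv")
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(
        {pid: t.to_dict() for pid, t in truths.items()},
        indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths
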