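"""From group-level survey estimates to single-year-of-age profiles.

Survey sources report platform use as band-level proportions (and
minutes/day among users) with a ± 95%-CI sampling margin. One *parameter
set* is a joint draw of all band values from truncated normal sampling
distributions, ``SD = margin95 / 1.96``. Each draw is placed as a knot at
its band midpoint and interpolated with a natural cubic spline (zero
second derivative at the boundary knots, linear continuation beyond them)
to yield a use probability and a minutes/day value at every single year
of age. Probabilities are clamped to [0, 1] and minutes to [0, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import truncnorm

from .tables import (AgeGroupEstimate, PopulationTable, RunConfig,
                     ValidationError)

__all__ = [
    "ParameterSet",
    "AgeProfile",
    "sample_group_estimates",
    "spline_interpolate",
    "band_knots",
    "build_age_profile",
    "ensure_child_minutes",
    "users_by_age",
]

#: 97.5th standard-normal quantile used to convert a 95%-CI half-width
#: into a sampling standard deviation.
Z95 = 1.96


@dataclass(frozen=True)
class ParameterSet:
    """One joint draw of all group-level inputs for a platform."""

    platform_id: str
    prevalence_draws: np.ndarray
    minutes_draws: np.ndarray
    rng_state_label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalence_draws, dtype=float)
        m = np.asarray(self.minutes_draws, dtype=float)
        object.__setattr__(self, "prevalence_draws", p)
        object.__setattr__(self, "minutes_draws", m)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError(
                f"{self.platform_id}: prevalence draw outside [0, 1]")
        if np.any(m < 0):
            raise ValidationError(f"{self.platform_id}: negative minutes draw")


@dataclass(frozen=True)
class AgeProfile:
    """Use probability ``p`` and minutes/day among users ``m`` at every
    single year of age 0..age_max."""

    platform_id: str
    p: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "m", m)
        if p.shape != m.shape or p.ndim != 1:
            raise ValidationError("profile: p and m must be 1-D, same length")
        if np.any((p < 0) | (p > 1)) or np.any(m < 0):
            raise ValidationError("profile: values outside legal range")

    @property
    def age_max(self) -> int:
        return self.p.size - 1


def sample_group_estimates(bands: Sequence[AgeGroupEstimate],
                           rng: np.random.Generator | int,
                           kind: str = "proportion") -> np.ndarray:
    """Draw one value per band from ``Normal(estimate, margin95/1.96)``
    truncated to the estimate's legal range: [0, 1] for proportions,
    [0, inf) for minutes. A zero margin returns the point estimate.
    Deterministic for a given generator state."""
    if kind not in ("proportion", "minutes"):
        raise ValidationError(f"unknown estimate kind {kind!r}")
    rng = np.random.default_rng(rng)
    lo, hi = (0.0, 1.0) if kind == "proportion" else (0.0, np.inf)
    mu = np.array([b.estimate for b in bands], dtype=float)
    sd = np.array([b.margin95 for b in bands], dtype=float) / Z95
    out = mu.copy()
    noisy = sd > 0
    if np.any(noisy):
        a = (lo - mu[noisy]) / sd[noisy]
        b = (hi - mu[noisy]) / sd[noisy]
        out[noisy] = truncnorm.rvs(a, b, loc=mu[noisy], scale=sd[noisy],
                                   random_state=rng)
    return out


def spline_interpolate(knot_ages: Sequence[float],
                       knot_values: np.ndarray,
                       ages: Sequence[float]) -> np.ndarray:
    """Natural cubic spline through ``(knot_ages, knot_values)`` evaluated
    at ``ages``; linear beyond the boundary knots (the natural boundary
    condition makes the boundary curvature zero, so the linear
    continuation is C1).

    ``knot_values`` may be 2-D with shape ``(n_knots, n_sets)`` to
    interpolate many parameter sets in one call; the result then has
    shape ``(len(ages), n_sets)``.
    """
    x = np.asarray(knot_ages, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("spline: need at least 2 knots")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("spline: knot ages must be strictly increasing")
    y = np.asarray(knot_values, dtype=float)
    if y.shape[0] != x.size:
        raise ValidationError("spline: knot_values length mismatch")
    a = np.atleast_1d(np.asarray(ages, dtype=float))

    cs = CubicSpline(x, y, axis=0, bc_type="natural")
    out = cs(a)
    left, right = a < x[0], a > x[-1]
    for mask, edge in ((left, x[0]), (right, x[-1])):
        if mask.any():
            y0, d0 = cs(edge), cs(edge, 1)
            offs = a[mask] - edge
            out[mask] = y0 + (offs[:, None] * d0 if y.ndim == 2 else offs * d0)
    return out


def band_knots(bands: Sequence[AgeGroupEstimate], age_max: int) -> np.ndarray:
    """Knot ages for a band layout: the band midpoint, with an open-ended
    top band centred between its lower edge and ``age_max``."""
    knots = np.array([
        (b.band.lo + (age_max if b.band.open_ended else b.band.hi)) / 2.0
        for b in bands], dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValidationError("band layout: knot ages not strictly increasing "
                              "(are bands sorted and non-overlapping?)")
    return knots


def _curve(knots: np.ndarray, draws: np.ndarray, ages: np.ndarray,
           lo: float, hi: float) -> np.ndarray:
    if knots.size == 1:  # a single band gives a constant curve
        draws = np.asarray(draws, dtype=float)
        base = np.ones_like(ages, dtype=float)
        vals = base[:, None] * draws[0] if draws.ndim == 2 else base * draws[0]
    else:
        vals = spline_interpolate(knots, draws, ages)
    return np.clip(vals, lo, hi)


def ensure_child_minutes(minutes: Sequence[AgeGroupEstimate],
                         config: RunConfig) -> tuple[AgeGroupEstimate, ...]:
    """Prepend a 0-17 minutes band at the configured fallback value when a
    platform's minutes table covers adults only."""
    from .tables import AgeBand  # local import to keep module load order simple
    if min(b.band.lo for b in minutes) >= 18:
        fallback = AgeGroupEstimate(AgeBand(0, 17),
                                    config.child_minutes_fallback, 0.0,
                                    "assumed (no child data)")
        return (fallback, *minutes)
    return tuple(minutes)


def build_age_profile(ps: ParameterSet,
                      prevalence_bands: Sequence[AgeGroupEstimate],
                      minutes_bands: Sequence[AgeGroupEstimate],
                      config: RunConfig) -> AgeProfile:
    """Interpolate one parameter set into an :class:`AgeProfile` on ages
    0..age_max. Prevalence and minutes are splined independently on their
    own band layouts; ages outside a layout take the boundary-linear
    extrapolation, clamped to the legal range."""
    if len(prevalence_bands) != ps.prevalence_draws.shape[0]:
        raise ValidationError("prevalence draws do not match band layout")
    if len(minutes_bands) != ps.minutes_draws.shape[0]:
        raise ValidationError("minutes draws do not match band layout")
    ages = np.arange(config.age_max + 1, dtype=float)
    p = _curve(band_knots(prevalence_bands, config.age_max),
               ps.prevalence_draws, ages, 0.0, 1.0)
    m = _curve(band_knots(minutes_bands, config.age_max),
               ps.minutes_draws, ages, 0.0, np.inf)
    return AgeProfile(platform_id=ps.platform_id, p=p, m=m)


def users_by_age(profile: AgeProfile, population: PopulationTable) -> np.ndarray:
    """Number of platform users at each single year of age:
    ``users_a = population_a * p_a``."""
    if profile.p.size != population.counts.size:
        raise ValidationError(
            f"profile covers ages 0-{profile.age_max} but population covers "
            f"0-{population.age_max}")
    return population.counts * profile.p
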