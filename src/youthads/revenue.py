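"""Proportional allocation of annual advertising revenue across ages.

Because platforms publish no age breakdown of revenue, revenue per minute
of platform use is assumed constant by age: a platform's total annual
revenue is allocated across single years of age in proportion to daily
person-minutes (users at that age × mean minutes/day among users at that
age). The 365× annualization cancels in the allocation ratio and appears
only in the implied revenue-per-minute diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .age_model import AgeProfile, users_by_age
from .tables import AgeBand, PopulationTable, ValidationError

__all__ = ["RevenueTable", "allocate_revenue", "band_aggregate",
           "implied_revenue_per_minute"]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class RevenueTable:
    """Per-age (and optionally per-band) users, person-minutes and
    allocated annual revenue for one platform."""

    platform_id: str
    total_revenue: float
    per_age: pd.DataFrame          # age, users, person_minutes, revenue
    per_band: pd.DataFrame | None = None  # band, users, revenue, share_of_total

    @property
    def age_max(self) -> int:
        return int(self.per_age["age"].iloc[-1])


def allocate_revenue(profile: AgeProfile, population: PopulationTable,
                     total_revenue: float) -> RevenueTable:
    """Allocate ``total_revenue`` (USD/year) across ages proportionally to
    daily person-minutes; conservation is exact up to float rounding."""
    if total_revenue <= 0:
        raise ValidationError("total_revenue must be > 0")
    users = users_by_age(profile, population)
    person_minutes = users * profile.m
    weight_sum = person_minutes.sum()
    if weight_sum <= 0:
        raise ValidationError(
            f"{profile.platform_id}: no modeled usage (zero person-minutes); "
            "cannot allocate revenue")
    revenue = total_revenue * person_minutes / weight_sum
    per_age = pd.DataFrame({
        "age": population.ages,
        "users": users,
        "person_minutes": person_minutes,
        "revenue": revenue,
    })
    return RevenueTable(platform_id=profile.platform_id,
                        total_revenue=float(total_revenue), per_age=per_age)


def band_aggregate(table: RevenueTable,
                   bands: Sequence[AgeBand]) -> RevenueTable:
    """Aggregate the per-age table over reporting bands; each band's
    users/revenue are sums of its ages, ``share_of_total`` its fraction of
    the platform's total revenue."""
    rows = []
    for band in bands:
        if band.hi > table.age_max or band.lo < 0:
            raise ValidationError(
                f"reporting band {band.label} outside age range "
                f"0-{table.age_max}")
        sel = table.per_age["age"].between(band.lo, band.hi)
        users = float(table.per_age.loc[sel, "users"].sum())
        revenue = float(table.per_age.loc[sel, "revenue"].sum())
        rows.append((band.label, users, revenue,
                     revenue / table.total_revenue))
    per_band = pd.DataFrame(rows, columns=["band", "users", "revenue",
                                           "share_of_total"])
    return RevenueTable(platform_id=table.platform_id,
                        total_revenue=table.total_revenue,
                        per_age=table.per_age, per_band=per_band)


def implied_revenue_per_minute(table: RevenueTable) -> float:
    """Diagnostic: USD per person-minute implied by the allocation
    (total annual revenue over annual person-minutes)."""
    annual_minutes = table.per_age["person_minutes"].sum() * DAYS_PER_YEAR
    return table.total_revenue / annual_minutes
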