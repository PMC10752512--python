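"""Ensemble summaries and pipeline orchestration.

Every reported quantity (band user count, band revenue, revenue share) is
computed once per retained ensemble member; the report gives the
arithmetic mean and a 95% uncertainty interval (UI) formed by the 2.5th
and 97.5th percentiles of the member values. Percentiles use linear
interpolation between closest order statistics (the "type 7" convention),
which is recorded in the run manifest. UIs are percentile statistics: the
means are additive across disjoint bands, the UI bounds are not and must
never be summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import FittedEnsemble, fit_platform
from .revenue import allocate_revenue, band_aggregate
from .tables import (AgeBand, PlatformInputs, PopulationTable, RunConfig,
                     ValidationError, write_outputs)

__all__ = ["SummaryStats", "summarize", "PipelineResult", "run_pipeline"]

log = logging.getLogger("youthads")


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    ui_lo: float
    ui_hi: float


def summarize(member_values: Sequence[float], ui_lo_pct: float = 2.5,
              ui_hi_pct: float = 97.5) -> SummaryStats:
    """Mean and percentile UI of one quantity across the ensemble.

    The mean and the percentiles are independent statistics: the mean may
    lie outside [ui_lo, ui_hi] for skewed ensembles, but ui_lo <= ui_hi
    always. Invariant under permutation of the members."""
    v = np.asarray(member_values, dtype=float)
    if v.size == 0:
        raise ValidationError("summarize: empty ensemble")
    if not 0 <= ui_lo_pct < ui_hi_pct <= 100:
        raise ValidationError("summarize: bad percentile bounds")
    lo, hi = np.percentile(v, [ui_lo_pct, ui_hi_pct])  # linear / type 7
    return SummaryStats(mean=float(v.mean()), ui_lo=float(lo), ui_hi=float(hi))


@dataclass(frozen=True)
class PipelineResult:
    """Full output of one run: fitted ensembles plus tidy summary tables
    (one row per platform × reporting band) for users, revenue and
    revenue share."""

    config: RunConfig
    ensembles: dict[str, FittedEnsemble]
    users_by_band: pd.DataFrame
    revenue_by_band: pd.DataFrame
    share_by_band: pd.DataFrame

    def platform_summary(self, platform_id: str, quantity: str) -> pd.DataFrame:
        frame = {"users": self.users_by_band, "revenue": self.revenue_by_band,
                 "share": self.share_by_band}[quantity]
        return frame[frame["platform"] == platform_id]


def _member_band_values(ensemble: FittedEnsemble, population: PopulationTable,
                        total_revenue: float, bands: Sequence[AgeBand]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-member band users / revenue / share, shape (n_members, n_bands)."""
    users = np.empty((len(ensemble), len(bands)))
    revenue = np.empty_like(users)
    for k, member in enumerate(ensemble.members):
        table = band_aggregate(
            allocate_revenue(member.profile, population, total_revenue), bands)
        users[k] = table.per_band["users"].to_numpy()
        revenue[k] = table.per_band["revenue"].to_numpy()
    return users, revenue, revenue / total_revenue


def run_pipeline(config: RunConfig, population: PopulationTable,
                 platforms: Sequence[PlatformInputs],
                 out_dir=None,
                 input_digests: Mapping[str, str] | None = None
                 ) -> PipelineResult:
    """Fit, allocate and summarize every platform.

    For each platform: draw and score candidate parameter sets, keep the
    best ``n_keep``, allocate total revenue over ages for every retained
    member, aggregate to the reporting bands, and summarize the member
    values into means and UIs. If ``out_dir`` is given, the three summary
    CSVs and the JSON manifest are written there."""
    if population.age_max != config.age_max:
        raise ValidationError(
            f"population covers ages 0-{population.age_max} but config "
            f"age_max is {config.age_max}")
    bands = config.youth_bands
    ensembles: dict[str, FittedEnsemble] = {}
    rows_u, rows_r, rows_s = [], [], []
    for inputs in platforms:
        pid = inputs.platform_id
        log.info("fitting %s (%d candidates, keeping %d)", pid,
                 config.n_candidates, config.n_keep)
        try:
            ens = fit_platform(inputs, population, config)
            users, revenue, share = _member_band_values(
                ens, population, inputs.total_revenue, bands)
        except ValidationError as exc:
            raise ValidationError(f"platform {pid}: {exc}") from exc
        ensembles[pid] = ens
        for j, band in enumerate(bands):
            for rows, values in ((rows_u, users[:, j]),
                                 (rows_r, revenue[:, j]),
                                 (rows_s, share[:, j])):
                s = summarize(values, config.ui_lo, config.ui_hi)
                rows.append((pid, band.label, s.mean, s.ui_lo, s.ui_hi))
        log.info("%s: best loss %.3g, 0-17 mean share %.1f%%", pid,
                 ens.losses[0] if len(ens) else float("nan"),
                 100 * rows_s[-1][2])

    cols = ["platform", "band", "mean", "ui_lo", "ui_hi"]
    result = PipelineResult(
        config=config,
        ensembles=ensembles,
        users_by_band=pd.DataFrame(rows_u, columns=cols),
        revenue_by_band=pd.DataFrame(rows_r, columns=cols),
        share_by_band=pd.DataFrame(rows_s, columns=cols),
    )
    if out_dir is not None:
        write_outputs({"users": result.users_by_band,
                       "revenue": result.revenue_by_band,
                       "share": result.share_by_band},
                      out_dir, config, input_digests)
    return result
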